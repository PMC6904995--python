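"""Assembly of the three feature regimes.

For a segment of window length L over the five property tracks:

  * ``C`` — composition combination: per-track symbol frequencies over the
    non-dummy positions, concatenated (20 + 3 + 6 + 3 + 2 = 34 columns);
  * ``P`` — position combination: for each track, the 2L-dimensional
    log-odds profile against the positive and negative PWSMs (10L columns);
  * ``R`` — refined combination: the (ID_pos, ID_neg) increment-of-diversity
    pair per track followed by the (S_pos, S_neg) PWSM score pair per track
    (20 columns, independent of L).

Everything trainable — diversity sources, PWSMs, the background, and the
per-feature min-max scaler — is fitted on training segments only; a fitted
extractor is a pure function of its training rows.  Scaled test values may
fall outside [0, 1] and are deliberately not clipped.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .alphabets import ALPHABETS, DUMMY, TRACKS
from .diversity import DiversitySource, build_source, count_windows, id_features_matrix
from .pwsm import PWSM, empirical_background, encode_windows
from .windowing import Segment

MODES = ("C", "P", "R")


def composition_features(segment: Segment) -> np.ndarray:
    """34-vector of per-track symbol frequencies over non-'X' positions.

    A track window that is entirely padding contributes an all-zero block;
    otherwise each block sums to 1.
    """
    return _composition_matrix([segment])[0]


def _composition_matrix(segments: Sequence[Segment]) -> np.ndarray:
    blocks = []
    for track in TRACKS:
        alphabet = ALPHABETS[track]
        counts = count_windows([s.track_windows[track] for s in segments], alphabet)
        counts = counts[:, :-1].astype(float)  # drop dummy column
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(totals > 0, counts / totals, 0.0)
        blocks.append(freqs)
    return np.concatenate(blocks, axis=1)


def composition_feature_names() -> List[str]:
    names = []
    for track in TRACKS:
        for sym in ALPHABETS[track].symbols[:-1]:
            names.append(f"comp_{track}_{sym}")
    return names


def position_feature_names(length: int) -> List[str]:
    names = []
    for track in TRACKS:
        for cls in ("pos", "neg"):
            names.extend(f"pwsm_{track}_{cls}_i{i}" for i in range(length))
    return names


def refined_feature_names() -> List[str]:
    names = [f"id_{track}_{cls}" for track in TRACKS for cls in ("pos", "neg")]
    names += [f"score_{track}_{cls}" for track in TRACKS for cls in ("pos", "neg")]
    return names


def feature_names(mode: str, length: int) -> List[str]:
    if mode == "C":
        return composition_feature_names()
    if mode == "P":
        return position_feature_names(length)
    if mode == "R":
        return refined_feature_names()
    raise ValueError(f"unknown feature mode {mode!r}")


class FeatureExtractor:
    """Fold-local feature builder for one regime, one window length.

    ``fit`` sees training segments only; ``transform`` maps any segments to
    the scaled numeric matrix used by the classifier.
    """

    def __init__(self, mode: str, length: int):
        if mode not in MODES:
            raise ValueError(f"feature mode must be one of {MODES}, got {mode!r}")
        self.mode = mode
        self.length = length
        self.sources: Dict[str, Dict[str, DiversitySource]] = {}
        self.matrices: Dict[str, Dict[str, PWSM]] = {}
        self.backgrounds: Dict[str, np.ndarray] = {}
        self.scaler: MinMaxScaler | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, train_segments: Sequence[Segment]) -> "FeatureExtractor":
        if not train_segments:
            raise ValueError("cannot fit on an empty training set")
        pos = [s for s in train_segments if s.positive]
        neg = [s for s in train_segments if not s.positive]
        if self.mode in ("P", "R"):
            if not pos or not neg:
                raise ValueError("both classes required to fit PWSM/ID features")
            for track in TRACKS:
                alphabet = ALPHABETS[track]
                all_windows = [s.track_windows[track] for s in train_segments]
                bg = empirical_background(all_windows, alphabet)
                self.backgrounds[track] = bg
                self.matrices[track] = {
                    "pos": PWSM.from_windows(
                        [s.track_windows[track] for s in pos], alphabet, bg
                    ),
                    "neg": PWSM.from_windows(
                        [s.track_windows[track] for s in neg], alphabet, bg
                    ),
                }
                if self.mode == "R":
                    self.sources[track] = {
                        "pos": build_source(
                            [s.track_windows[track] for s in pos], alphabet
                        ),
                        "neg": build_source(
                            [s.track_windows[track] for s in neg], alphabet
                        ),
                    }
        raw = self._raw_matrix(train_segments)
        self.scaler = MinMaxScaler(clip=False).fit(raw)
        return self

    # -- transforming ------------------------------------------------------

    def _raw_matrix(self, segments: Sequence[Segment]) -> np.ndarray:
        if self.mode == "C":
            return _composition_matrix(segments)
        if self.mode == "P":
            blocks = []
            for track in TRACKS:
                enc = encode_windows(
                    [s.track_windows[track] for s in segments], ALPHABETS[track]
                )
                blocks.append(self.matrices[track]["pos"].profile(enc))
                blocks.append(self.matrices[track]["neg"].profile(enc))
            return np.concatenate(blocks, axis=1)
        # refined: 10 ID columns then 10 S columns
        id_blocks, s_blocks = [], []
        for track in TRACKS:
            alphabet = ALPHABETS[track]
            windows = [s.track_windows[track] for s in segments]
            counts = count_windows(windows, alphabet)
            id_blocks.append(
                id_features_matrix(
                    counts, self.sources[track]["pos"], self.sources[track]["neg"]
                )
            )
            enc = encode_windows(windows, alphabet)
            s_blocks.append(
                np.column_stack(
                    [
                        self.matrices[track]["pos"].score(enc),
                        self.matrices[track]["neg"].score(enc),
                    ]
                )
            )
        return np.concatenate(id_blocks + s_blocks, axis=1)

    def transform(self, segments: Sequence[Segment]) -> np.ndarray:
        if self.scaler is None:
            raise RuntimeError("extractor is not fitted")
        return self.scaler.transform(self._raw_matrix(segments))

    def fit_transform(self, train_segments: Sequence[Segment]) -> np.ndarray:
        return self.fit(train_segments).transform(train_segments)

    @property
    def names(self) -> List[str]:
        return feature_names(self.mode, self.length)

    # -- audit -------------------------------------------------------------

    def state_hash(self) -> str:
        """SHA-256 over every trained array; equal iff trained state equal."""
        if self.scaler is None:
            raise RuntimeError("extractor is not fitted")
        h = hashlib.sha256()
        h.update(f"{self.mode}:{self.length}".encode())
        for track in TRACKS:
            if track in self.backgrounds:
                h.update(self.backgrounds[track].tobytes())
            if track in self.matrices:
                for cls in ("pos", "neg"):
                    m = self.matrices[track][cls]
                    h.update(m.counts.tobytes())
                    h.update(m.logodds.tobytes())
                    h.update(m.conservation.tobytes())
            if track in self.sources:
                for cls in ("pos", "neg"):
                    h.update(self.sources[track][cls].counts.tobytes())
        h.update(np.asarray(self.scaler.data_min_).tobytes())
        h.update(np.asarray(self.scaler.data_max_).tobytes())
        return h.hexdigest()


@dataclass
class FeatureMatrix:
    """A named feature matrix for archiving (rows = segments)."""

    mode: str
    names: List[str]
    values: np.ndarray

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, columns=self.names).to_csv(path, index=False)


def build_feature_matrix(extractor: FeatureExtractor,
                         segments: Sequence[Segment]) -> FeatureMatrix:
    return FeatureMatrix(
        mode=extractor.mode,
        names=extractor.names,
        values=extractor.transform(segments),
    )
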