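"""Increment of diversity (ID) over symbol-count vectors.

The diversity of a count vector X = [n_1, ..., n_s] with total N is

    D(X) = N ln N - sum_i n_i ln n_i         (0 ln 0 = 0)

and the increment of diversity between two sources is

    ID(X, Y) = D(X + Y) - D(X) - D(Y)

a non-negative, symmetric dissimilarity that vanishes exactly when the two
count vectors are proportional.  Here it compresses a segment's per-track
symbol composition into two scalars: its ID against the pooled positive
training source and against the pooled negative one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .alphabets import ALPHABETS, TrackAlphabet


def _as_counts(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "counts", x), dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return arr


def _check_same_alphabet(x, y) -> None:
    ax = getattr(x, "alphabet", None)
    ay = getattr(y, "alphabet", None)
    if ax is not None and ay is not None and ax != ay:
        raise ValueError(f"alphabet mismatch: {ax.name} vs {ay.name}")
    cx, cy = _as_counts(x), _as_counts(y)
    if cx.shape != cy.shape:
        raise ValueError("count vectors have different lengths")


@dataclass(frozen=True)
class DiversitySource:
    """A pooled symbol-count vector over one track's alphabet."""

    alphabet: TrackAlphabet
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.alphabet.size,):
            raise ValueError("counts length must equal alphabet size")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_json(self) -> str:
        return json.dumps(
            {"alphabet": self.alphabet.name, "counts": self.counts.tolist()}
        )

    @classmethod
    def from_json(cls, payload: str) -> "DiversitySource":
        obj = json.loads(payload)
        return cls(ALPHABETS[obj["alphabet"]], np.asarray(obj["counts"]))


def diversity(source) -> float:
    """D(X) = N ln N - sum n_i ln n_i, with 0 ln 0 = 0.  Always >= 0."""
    counts = _as_counts(source)
    total = counts.sum()
    return float(xlogy(total, total) - xlogy(counts, counts).sum())


def mixed_diversity(x, y) -> float:
    """Diversity of the pooled source X + Y."""
    _check_same_alphabet(x, y)
    return diversity(_as_counts(x) + _as_counts(y))


def increment_of_diversity(x, y) -> float:
    """ID(X, Y) = D(X+Y) - D(X) - D(Y); small when X and Y are similar."""
    _check_same_alphabet(x, y)
    return mixed_diversity(x, y) - diversity(x) - diversity(y)


def id_feature_pair(segment_counts, positive_source, negative_source):
    """The two ID features of one segment's track composition.

    Over the five tracks this yields the 10-dimensional ID block.
    """
    return (
        increment_of_diversity(segment_counts, positive_source),
        increment_of_diversity(segment_counts, negative_source),
    )


def count_windows(windows, alphabet: TrackAlphabet) -> np.ndarray:
    """Per-segment symbol counts: (n_segments, A) integer matrix.

    Counts include the dummy 'X' so padded edge segments are well-defined.
    """
    enc = np.asarray([alphabet.encode(w) for w in windows], dtype=np.intp)
    counts = np.zeros((enc.shape[0], alphabet.size), dtype=np.int64)
    np.add.at(counts, (np.arange(enc.shape[0])[:, None], enc), 1)
    return counts


def build_source(windows, alphabet: TrackAlphabet) -> DiversitySource:
    """Pool whole-segment counts of one class into a standard source."""
    if len(windows) == 0:
        return DiversitySource(alphabet, np.zeros(alphabet.size, dtype=np.int64))
    return DiversitySource(alphabet, count_windows(windows, alphabet).sum(axis=0))


def id_features_matrix(
    segment_counts: np.ndarray,
    positive_source: DiversitySource,
    negative_source: DiversitySource,
) -> np.ndarray:
    """Vectorized (ID_pos, ID_neg) for many segments at once: (n, 2)."""
    counts = np.asarray(segment_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    out = np.empty((counts.shape[0], 2))
    for col, src in ((0, positive_source), (1, negative_source)):
        s = src.counts.astype(float)[None, :]
        if counts.shape[1] != s.shape[1]:
            raise ValueError("count vectors have different lengths")
        mixed = counts + s
        n_tot = counts.sum(axis=1)
        m_tot = s.sum()
        d_x = xlogy(n_tot, n_tot) - xlogy(counts, counts).sum(axis=1)
        d_y = xlogy(m_tot, m_tot) - xlogy(s, s).sum()
        d_mix = xlogy(n_tot + m_tot, n_tot + m_tot) - xlogy(mixed, mixed).sum(axis=1)
        out[:, col] = d_mix - d_x - d_y
    return out
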