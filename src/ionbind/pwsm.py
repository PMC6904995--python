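"""Position weight scoring matrices (PWSM) with pseudocounts and
conservation weights.

For one class's training windows of length L over an alphabet of A symbols
(the 20 amino acids plus the dummy 'X' on the amino track; the smaller
property alphabets on the other tracks), the observed probability at
position i is smoothed with a sqrt-N pseudocount,

    p[i][j] = (n[i][j] + sqrt(N_i)/A) / (N_i + sqrt(N_i)),

the matrix element is the log-odds against a background distribution,

    m[i][j] = ln(p[i][j] / p_o[j]),

and the conservation weight of position i is the negentropy rescaled to
[0, 100]:

    C_i = (100 / ln A) * (sum_j p[i][j] ln p[i][j] + ln A).

A window w = (j_1 ... j_L) is scored with the min-max-normalized,
conservation-weighted sum

    S = sum_i C_i (m[i][j_i] - m_i,min) / sum_i C_i (m_i,max - m_i,min),

bounded in [0, 1].  The 2L-dimensional position profile (m_pos then m_neg
row lookups) and the (S_pos, S_neg) pair are the two downstream uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .alphabets import ALPHABETS, TrackAlphabet


def empirical_background(windows, alphabet: TrackAlphabet) -> np.ndarray:
    """Pooled symbol frequencies over all positions of all windows.

    Zero entries are floored at 1/(10*A*total) and the vector renormalized,
    so log-odds stay finite for symbols absent from training.
    """
    counts = np.zeros(alphabet.size, dtype=np.int64)
    for w in windows:
        for s in w:
            counts[alphabet.index(s)] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot build a background from empty training windows")
    freqs = counts / total
    floor = 1.0 / (10.0 * alphabet.size * total)
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum()


def encode_windows(windows, alphabet: TrackAlphabet) -> np.ndarray:
    """(n, L) integer symbol-index matrix for a list of equal-length windows."""
    enc = np.asarray([alphabet.encode(w) for w in windows], dtype=np.intp)
    if enc.ndim != 2:
        raise ValueError("windows must all have the same length")
    return enc


@dataclass
class PWSM:
    """One class's position weight scoring matrix for one track."""

    alphabet: TrackAlphabet
    counts: np.ndarray        # (L, A) integer symbol counts per position
    background: np.ndarray    # (A,) background probabilities p_o
    probs: np.ndarray         # (L, A) pseudocounted probabilities p[i][j]
    logodds: np.ndarray       # (L, A) m[i][j]
    conservation: np.ndarray  # (L,) C_i in [0, 100]
    row_max: np.ndarray       # (L,) m_i,max
    row_min: np.ndarray       # (L,) m_i,min

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_counts(cls, counts, alphabet: TrackAlphabet, background) -> "PWSM":
        counts = np.asarray(counts, dtype=np.int64)
        background = np.asarray(background, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != alphabet.size:
            raise ValueError("counts must be (L, A) for the track alphabet")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if background.shape != (alphabet.size,) or np.any(background <= 0):
            raise ValueError("background must be strictly positive over the alphabet")
        n_i = counts.sum(axis=1, keepdims=True).astype(float)
        if np.any(n_i == 0):
            raise ValueError("every position needs at least one observation")
        pseudo = np.sqrt(n_i) / alphabet.size
        probs = (counts + pseudo) / (n_i + np.sqrt(n_i))
        logodds = np.log(probs / background[None, :])
        a = alphabet.size
        conservation = (100.0 / np.log(a)) * (
            xlogy(probs, probs).sum(axis=1) + np.log(a)
        )
        conservation = np.clip(conservation, 0.0, 100.0)  # guard FP dust at bounds
        return cls(
            alphabet=alphabet,
            counts=counts,
            background=background,
            probs=probs,
            logodds=logodds,
            conservation=conservation,
            row_max=logodds.max(axis=1),
            row_min=logodds.min(axis=1),
        )

    @classmethod
    def from_windows(cls, windows, alphabet: TrackAlphabet, background) -> "PWSM":
        """Build from one class's training windows (>= 1, equal length)."""
        if len(windows) == 0:
            raise ValueError("cannot build a PWSM from an empty training set")
        enc = encode_windows(windows, alphabet)
        length = enc.shape[1]
        counts = np.zeros((length, alphabet.size), dtype=np.int64)
        np.add.at(counts, (np.arange(length)[None, :], enc), 1)
        return cls.from_counts(counts, alphabet, background)

    def profile(self, encoded: np.ndarray) -> np.ndarray:
        """Row lookups m[i][j_i]: (n, L) for (n, L) encoded windows."""
        encoded = np.asarray(encoded, dtype=np.intp)
        if encoded.shape[-1] != self.length:
            raise ValueError("window length does not match matrix length")
        if np.any(encoded < 0) or np.any(encoded >= self.alphabet.size):
            raise ValueError("symbol index outside alphabet")
        return self.logodds[np.arange(self.length), encoded]

    def score(self, encoded: np.ndarray) -> np.ndarray:
        """Score S in [0, 1] for each encoded window."""
        looked = self.profile(np.atleast_2d(encoded))
        denom = float((self.conservation * (self.row_max - self.row_min)).sum())
        if denom <= 0:
            raise ValueError(
                "uninformative matrix: every position is uniform, S undefined"
            )
        num = (self.conservation[None, :] * (looked - self.row_min[None, :])).sum(axis=1)
        return num / denom

    def to_json(self) -> str:
        return json.dumps(
            {
                "alphabet": self.alphabet.name,
                "counts": self.counts.tolist(),
                "background": self.background.tolist(),
                "logodds": self.logodds.tolist(),
                "conservation": self.conservation.tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "PWSM":
        obj = json.loads(payload)
        pwsm = cls.from_counts(
            np.asarray(obj["counts"]),
            ALPHABETS[obj["alphabet"]],
            np.asarray(obj["background"]),
        )
        # derived fields are recomputed; verify against the stored ones
        if not np.allclose(pwsm.logodds, np.asarray(obj["logodds"])):
            raise ValueError("stored log-odds disagree with recomputation")
        if not np.allclose(pwsm.conservation, np.asarray(obj["conservation"])):
            raise ValueError("stored conservation disagrees with recomputation")
        return pwsm


def position_profile(window: str, pwsm_pos: PWSM, pwsm_neg: PWSM) -> np.ndarray:
    """2L-dimensional profile: positive-matrix lookups then negative-matrix."""
    enc = np.asarray(pwsm_pos.alphabet.encode(window), dtype=np.intp)
    return np.concatenate([pwsm_pos.profile(enc), pwsm_neg.profile(enc)])


def pwsm_score(window: str, pwsm: PWSM) -> float:
    """Score one window string against one matrix."""
    enc = np.asarray(pwsm.alphabet.encode(window), dtype=np.intp)
    return float(pwsm.score(enc)[0])
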