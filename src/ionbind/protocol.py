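"""Balanced-undersampling KNN protocol.

The classifier is plain Euclidean k-nearest-neighbours with odd k (odd k
cannot tie a binary majority vote; distance ties are broken toward the
lower training-row index, which makes every prediction deterministic).
Because negatives vastly outnumber positives, every experiment first
draws a balanced set: all positives plus an equal-sized random sample of
negatives.  The protocol repeats this ``n_resamples`` times (default 10)
and averages stratified five-fold cross-validation results; the optimal k
for a configuration is the per-resample argmax-MCC k averaged over the
resamples and rounded to the nearest odd integer, and the optimal window
length is the argmax of the resample-averaged MCC of the position-
combination features over the window grid.

All trainable state (diversity sources, PWSMs, scaler) is rebuilt inside
every fold from that fold's training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .evaluation import EvalResult, confusion_counts, metrics
from .features import FeatureExtractor
from .io import ProteinRecord
from .windowing import WINDOW_GRID, Segment, segments_from_records

DEFAULT_K_GRID = tuple(range(1, 152, 2))


@dataclass(frozen=True)
class KnnConfig:
    """Protocol knobs: k grid, resample and fold counts, root seed."""

    k: Optional[int] = None
    k_grid: Tuple[int, ...] = DEFAULT_K_GRID
    n_resamples: int = 10
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if any(k % 2 == 0 or k < 1 for k in self.k_grid):
            raise ValueError("k grid must contain odd positive integers")
        if list(self.k_grid) != sorted(set(self.k_grid)):
            raise ValueError("k grid must be strictly increasing")
        if self.k is not None and self.k % 2 == 0:
            raise ValueError("k must be odd")


def _child_seeds(seed: int, n: int, tag: int = 0) -> np.ndarray:
    """Deterministic per-stage seeds derived from one root seed."""
    state = np.random.SeedSequence([seed, tag]).generate_state(n)
    return (state & 0x7FFFFFFF).astype(np.int64)


def undersample_negatives(segments: Sequence[Segment], seed: int) -> List[Segment]:
    """All positives plus an equal-count random negative subset."""
    positives = [s for s in segments if s.positive]
    negatives = [s for s in segments if not s.positive]
    if len(negatives) < len(positives):
        raise ValueError(
            f"cannot balance: {len(negatives)} negatives < {len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(negatives), size=len(positives), replace=False)
    return positives + [negatives[i] for i in sorted(chosen)]


def _sorted_train_labels(train_x: np.ndarray, train_y: np.ndarray,
                         test_x: np.ndarray) -> np.ndarray:
    """Training labels sorted by distance (ties -> lower row index) per test row."""
    dist = cdist(test_x, train_x, metric="sqeuclidean")
    order = np.argsort(dist, axis=1, kind="stable")
    return train_y[order]


def _predict_from_sorted(sorted_labels: np.ndarray, k: int) -> np.ndarray:
    votes = sorted_labels[:, :k].sum(axis=1)
    return votes * 2 > k


def knn_predict(train_x: np.ndarray, train_y, test_x: np.ndarray,
                k: int) -> np.ndarray:
    """Majority vote among the k Euclidean-nearest training rows."""
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    train_y = np.asarray(train_y, dtype=bool)
    if k % 2 == 0 or k < 1:
        raise ValueError("k must be a positive odd integer")
    if k > train_x.shape[0]:
        raise ValueError(f"k={k} exceeds the training-set size {train_x.shape[0]}")
    return _predict_from_sorted(_sorted_train_labels(train_x, train_y, test_x), k)


# -- cross-validation ------------------------------------------------------


@dataclass(frozen=True)
class CVResult:
    """One five-fold run: pooled-count metrics plus the per-fold results."""

    pooled: EvalResult
    folds: Tuple[EvalResult, ...]

    @property
    def fold_mean(self) -> Dict[str, float]:
        """Mean of per-fold metrics (the 'average of five experiments')."""
        return {
            name: float(np.mean([getattr(f, attr) for f in self.folds]))
            for name, attr in (("Sn", "sn"), ("Sp", "sp"), ("Acc", "acc"),
                               ("FPR", "fpr"), ("MCC", "mcc"))
        }


def _fold_indices(labels: np.ndarray, n_folds: int, seed: int):
    n_pos = int(labels.sum())
    if n_pos < n_folds or (len(labels) - n_pos) < n_folds:
        raise ValueError("every fold needs at least one segment of each class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def _fold_confusions_over_grid(
    segments: Sequence[Segment], mode: str, length: int,
    k_grid: Sequence[int], seed: int, n_folds: int,
) -> np.ndarray:
    """(n_k, n_folds, 4) confusion counts, sweeping the whole k grid at once."""
    segments = list(segments)
    labels = np.array([s.positive for s in segments], dtype=bool)
    folds = _fold_indices(labels, n_folds, seed)
    out = np.zeros((len(k_grid), len(folds), 4), dtype=np.int64)
    for f, (train_idx, test_idx) in enumerate(folds):
        train = [segments[i] for i in train_idx]
        test = [segments[i] for i in test_idx]
        extractor = FeatureExtractor(mode, length).fit(train)
        train_x = extractor.transform(train)
        test_x = extractor.transform(test)
        sorted_labels = _sorted_train_labels(train_x, labels[train_idx], test_x)
        for j, k in enumerate(k_grid):
            if k > len(train):
                raise ValueError(f"k={k} exceeds fold training size {len(train)}")
            pred = _predict_from_sorted(sorted_labels, k)
            out[j, f] = confusion_counts(labels[test_idx], pred)
    return out


def cross_validate(segments: Sequence[Segment], mode: str, length: int,
                   k: int, seed: int, n_folds: int = 5) -> CVResult:
    """Stratified n-fold CV of one balanced set at one k.

    Metrics are reported both from the summed fold confusion counts
    (``pooled``) and as the mean of per-fold metrics (``fold_mean``).
    """
    conf = _fold_confusions_over_grid(segments, mode, length, [k], seed, n_folds)[0]
    folds = tuple(metrics(*row) for row in conf)
    return CVResult(pooled=metrics(*conf.sum(axis=0)), folds=folds)


# -- optimal-k selection ---------------------------------------------------


def optimal_k_from_curve(k_grid: Sequence[int], mcc: Sequence[float]) -> int:
    """Argmax-MCC k; ties resolved toward the smaller k."""
    best_k, best = None, -np.inf
    for k, v in zip(k_grid, mcc):
        if v > best:
            best_k, best = k, v
    return best_k


def average_optimal_k(optima: Sequence[int]) -> int:
    """Mean of per-resample optima, rounded to the nearest odd integer
    (a half-way mean rounds toward the smaller odd value)."""
    m = float(np.mean(optima))
    lower = 2 * int(np.floor((m - 1) / 2)) + 1
    upper = lower + 2
    return lower if (m - lower) <= (upper - m) else upper


@dataclass(frozen=True)
class KSelection:
    k: int
    per_resample: Tuple[int, ...]
    curves: Tuple[Tuple[float, ...], ...]  # pooled-count MCC per k, per resample
    k_grid: Tuple[int, ...]


def select_optimal_k(segments: Sequence[Segment], mode: str, length: int,
                     config: KnnConfig) -> KSelection:
    """The resampled optimal-k protocol.

    Each of ``n_resamples`` balanced undersamples gets a full CV sweep over
    the k grid; the per-resample argmax-MCC values are averaged.
    """
    sample_seeds = _child_seeds(config.seed, config.n_resamples, tag=1)
    fold_seeds = _child_seeds(config.seed, config.n_resamples, tag=2)
    optima, curves = [], []
    for r in range(config.n_resamples):
        balanced = undersample_negatives(segments, int(sample_seeds[r]))
        max_train = len(balanced) - -(-len(balanced) // config.n_folds)
        grid = [k for k in config.k_grid if k <= max_train]
        conf = _fold_confusions_over_grid(
            balanced, mode, length, grid, int(fold_seeds[r]), config.n_folds
        )
        mcc = [metrics(*conf[j].sum(axis=0)).mcc for j in range(len(grid))]
        optima.append(optimal_k_from_curve(grid, mcc))
        curves.append(tuple(mcc))
    return KSelection(
        k=average_optimal_k(optima),
        per_resample=tuple(optima),
        curves=tuple(curves),
        k_grid=tuple(config.k_grid),
    )


# -- the 10-resample protocol at a fixed k ---------------------------------


@dataclass(frozen=True)
class ProtocolResult:
    """n_resamples balanced CV runs at one (mode, L, k)."""

    mode: str
    length: int
    k: int
    resamples: Tuple[CVResult, ...]

    @property
    def mean_metrics(self) -> Dict[str, float]:
        """Arithmetic mean of the per-resample pooled metrics."""
        return {
            name: float(np.mean([getattr(r.pooled, attr) for r in self.resamples]))
            for name, attr in (("Sn", "sn"), ("Sp", "sp"), ("Acc", "acc"),
                               ("FPR", "fpr"), ("MCC", "mcc"))
        }


def run_protocol(segments: Sequence[Segment], mode: str, length: int,
                 k: int, config: KnnConfig) -> ProtocolResult:
    """Average n_resamples balanced five-fold CV runs at a fixed k."""
    sample_seeds = _child_seeds(config.seed, config.n_resamples, tag=1)
    fold_seeds = _child_seeds(config.seed, config.n_resamples, tag=2)
    results = []
    for r in range(config.n_resamples):
        balanced = undersample_negatives(segments, int(sample_seeds[r]))
        results.append(
            cross_validate(balanced, mode, length, k, int(fold_seeds[r]),
                           config.n_folds)
        )
    return ProtocolResult(mode=mode, length=length, k=k, resamples=tuple(results))


# -- optimal window length -------------------------------------------------


@dataclass(frozen=True)
class WindowSelection:
    length: int
    rows: Tuple[dict, ...]  # per-L: L, optimal k, mean metrics


def select_optimal_window(
    records: Sequence[ProteinRecord], ligand_code: str, config: KnnConfig,
    window_grid: Sequence[int] = WINDOW_GRID, mode: str = "P",
) -> WindowSelection:
    """Sweep the window grid with position-combination features.

    For each L: select the optimal k, rerun the resampled protocol at that
    k, and record the mean metrics; the L with the highest mean MCC wins
    (ties toward the smaller window).
    """
    rows = []
    for length in window_grid:
        segments = segments_from_records(records, ligand_code, length)
        selection = select_optimal_k(segments, mode, length, config)
        result = run_protocol(segments, mode, length, selection.k, config)
        rows.append({"L": length, "k": selection.k, **result.mean_metrics})
    best = max(rows, key=lambda r: (r["MCC"], -r["L"]))
    return WindowSelection(length=best["L"], rows=tuple(rows))


# -- independent test ------------------------------------------------------


@dataclass(frozen=True)
class IndependentTestResult:
    result: EvalResult
    train_chains: Tuple[str, ...]
    test_chains: Tuple[str, ...]
    train_summary: Dict[str, int]
    test_summary: Dict[str, int]


def split_chains(records: Sequence[ProteinRecord], split_seed: int,
                 train_fraction: float = 0.8):
    """Chain-level shuffle split; no chain contributes to both sides."""
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(records))
    n_train = int(round(train_fraction * len(records)))
    train = [records[i] for i in sorted(order[:n_train])]
    test = [records[i] for i in sorted(order[n_train:])]
    return train, test


def independent_test(
    records: Sequence[ProteinRecord], ligand_code: str, mode: str,
    length: int, k: int, config: KnnConfig, split_seed: int,
) -> IndependentTestResult:
    """Train on 80% of chains, evaluate on the full held-out 20%.

    Training uses ``n_resamples`` balanced undersamples of the training-side
    segments; each trains its own extractor and KNN reference set, and test
    segments take the majority vote of the ensemble (a tie counts as
    negative).  The test side stays imbalanced, exactly as prediction on a
    new chain would be.
    """
    train_recs, test_recs = split_chains(records, split_seed)
    train_segments = segments_from_records(train_recs, ligand_code, length)
    test_segments = segments_from_records(test_recs, ligand_code, length)
    test_labels = np.array([s.positive for s in test_segments], dtype=bool)
    if not test_labels.any():
        raise ValueError("held-out test side has no positive segments")

    sample_seeds = _child_seeds(config.seed, config.n_resamples, tag=3)
    votes = np.zeros(len(test_segments), dtype=np.int64)
    for r in range(config.n_resamples):
        balanced = undersample_negatives(train_segments, int(sample_seeds[r]))
        labels = np.array([s.positive for s in balanced], dtype=bool)
        extractor = FeatureExtractor(mode, length).fit(balanced)
        votes += knn_predict(
            extractor.transform(balanced), labels,
            extractor.transform(test_segments), k,
        )
    pred = votes * 2 > config.n_resamples
    tp, fp, tn, fn = confusion_counts(test_labels, pred)

    def _summary(segs):
        pos = sum(s.positive for s in segs)
        return {"chains": 0, "positives": pos, "negatives": len(segs) - pos}

    tr, te = _summary(train_segments), _summary(test_segments)
    tr["chains"], te["chains"] = len(train_recs), len(test_recs)
    return IndependentTestResult(
        result=metrics(tp, fp, tn, fn),
        train_chains=tuple(r.chain_id for r in train_recs),
        test_chains=tuple(r.chain_id for r in test_recs),
        train_summary=tr,
        test_summary=te,
    )


def predict_residues(
    train_records: Sequence[ProteinRecord], target_records: Sequence[ProteinRecord],
    ligand_code: str, mode: str, length: int, k: int, config: KnnConfig,
):
    """Per-residue predictions for new chains from a resampled ensemble.

    Returns rows of (chain_id, 1-based position, predicted label, vote
    fraction over the ensemble).
    """
    train_segments = segments_from_records(train_records, ligand_code, length)
    target_segments = segments_from_records(target_records, ligand_code, length)
    sample_seeds = _child_seeds(config.seed, config.n_resamples, tag=3)
    votes = np.zeros(len(target_segments), dtype=np.int64)
    for r in range(config.n_resamples):
        balanced = undersample_negatives(train_segments, int(sample_seeds[r]))
        labels = np.array([s.positive for s in balanced], dtype=bool)
        extractor = FeatureExtractor(mode, length).fit(balanced)
        votes += knn_predict(
            extractor.transform(balanced), labels,
            extractor.transform(target_segments), k,
        )
    rows = []
    for seg, v in zip(target_segments, votes):
        frac = v / config.n_resamples
        rows.append(
            {
                "chain_id": seg.chain_id,
                "position": seg.center_index + 1,
                "predicted": "positive" if 2 * v > config.n_resamples else "negative",
                "vote_fraction": frac,
            }
        )
    return rows
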