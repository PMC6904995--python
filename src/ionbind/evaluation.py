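"""Confusion-count bookkeeping and the five evaluation metrics.

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total (all as percent),
FPR = FP/(TN+FP) = 100% - Sp, and Matthew's correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

A metric whose denominator is zero is reported as 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd


def confusion_counts(true_labels, predicted_labels) -> Tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for binary labels (positive == truthy)."""
    t = np.asarray(true_labels, dtype=bool)
    p = np.asarray(predicted_labels, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("true and predicted label vectors differ in length")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    return tp, fp, tn, fn


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts plus the five derived metrics (Sn/Sp/Acc/FPR in %)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sn: float
    sp: float
    acc: float
    fpr: float
    mcc: float
    flags: tuple = ()

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "Sn": self.sn, "Sp": self.sp, "Acc": self.acc,
            "FPR": self.fpr, "MCC": self.mcc, "flags": list(self.flags),
        }

    def __str__(self) -> str:
        return (
            f"Sn={self.sn:.1f}% Sp={self.sp:.1f}% Acc={self.acc:.1f}% "
            f"FPR={self.fpr:.1f}% MCC={self.mcc:.3f}"
        )


def metrics(tp: int, fp: int, tn: int, fn: int) -> EvalResult:
    """Evaluate the five metrics from confusion counts."""
    tp, fp, tn, fn = int(tp), int(fp), int(tn), int(fn)  # exact big-int products
    for name, v in (("TP", tp), ("FP", fp), ("TN", tn), ("FN", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name} denominator zero; reported as 0")
            return 0.0
        return 100.0 * num / den

    sn = ratio(tp, tp + fn, "Sn")
    sp = ratio(tn, tn + fp, "Sp")
    acc = 100.0 * (tp + tn) / total
    fpr = ratio(fp, tn + fp, "FPR")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        flags.append("MCC denominator zero; reported as 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return EvalResult(tp, fp, tn, fn, sn, sp, acc, fpr, mcc, tuple(flags))


def evaluate(true_labels, predicted_labels) -> EvalResult:
    """Convenience: confusion counts then metrics."""
    return metrics(*confusion_counts(true_labels, predicted_labels))


def write_metrics_table(rows: Iterable[dict], path) -> None:
    """TSV with the usual result-table columns (L, k, Sn, Sp, Acc, FPR, MCC).

    Percentages are written to one decimal place, MCC to three.
    """
    frame = pd.DataFrame(list(rows))
    cols = [c for c in ("ligand", "feature", "L", "k", "Sn", "Sp", "Acc", "FPR", "MCC")
            if c in frame.columns]
    frame = frame[cols]
    for c in ("Sn", "Sp", "Acc", "FPR"):
        if c in frame:
            frame[c] = frame[c].map(lambda v: f"{v:.1f}")
    if "MCC" in frame:
        frame["MCC"] = frame["MCC"].map(lambda v: f"{v:.3f}")
    frame.to_csv(path, sep="\t", index=False)
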