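"""Soft-vote ensembling and the binary-classification evaluation suite.

Threshold metrics follow the standard confusion-count formulas:

    Sn  = TP / (TP + FN)                 (sensitivity / recall)
    Sp  = TN / (TN + FP)                 (specificity)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    Pre = TP / (TP + FP)                 (precision)
    F1  = 2 * Pre * Sn / (Pre + Sn)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Any metric with a zero denominator is reported as 0 and flagged with a
warning rather than NaN, so heavily imbalanced toy runs still produce
reports. AUROC is the trapezoidal area under the ROC curve; AUPRC is the
step-wise (average-precision) area, not the trapezoidal PR interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """The eight evaluation metrics at a stated decision threshold."""

    Sn: float
    Sp: float
    Acc: float
    Pre: float
    F1: float
    MCC: float
    AUROC: float
    AUPRC: float
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def soft_vote(prob_lists: Sequence[Sequence[float]]) -> np.ndarray:
    """Ensemble by element-wise arithmetic mean of member probabilities."""
    if len(prob_lists) < 2:
        raise ValueError("soft vote needs at least two probability vectors")
    arrs = [np.asarray(p, dtype=float) for p in prob_lists]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("probability vectors must have equal length")
    stacked = np.stack(arrs)
    if np.any(stacked < 0) or np.any(stacked > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return stacked.mean(axis=0)


def confusion_at_threshold(
    y_true: Sequence[int], p: Sequence[float], t: float = 0.5
) -> ConfusionCounts:
    """Tally the confusion table; predicted positive iff p >= t."""
    y = np.asarray(y_true)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must align")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0/1")
    if not 0 <= t <= 1:
        raise ValueError("threshold must be in [0, 1]")
    pred = p >= t
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, Acc, Pre, F1, MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    sn = _safe_div(c.TP, c.TP + c.FN, "Sn")
    sp = _safe_div(c.TN, c.TN + c.FP, "Sp")
    acc = (c.TP + c.TN) / c.total
    pre = _safe_div(c.TP, c.TP + c.FP, "Pre")
    f1 = _safe_div(2 * pre * sn, pre + sn, "F1")
    mcc_den = sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = _safe_div(c.TP * c.TN - c.FP * c.FN, mcc_den, "MCC")
    return {"Sn": sn, "Sp": sp, "Acc": acc, "Pre": pre, "F1": f1, "MCC": mcc}


def auroc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal area under the ROC curve; equals the probability a
    random positive outscores a random negative, ties counted 1/2."""
    y = np.asarray(y_true)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Step-wise area under the precision-recall curve,
    sum over descending-score thresholds of (R_i - R_{i-1}) * P_i."""
    y = np.asarray(y_true)
    if np.sum(y == 1) == 0:
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def evaluate(
    y_true: Sequence[int], probs: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Full eight-metric report at the given decision threshold."""
    c = confusion_at_threshold(y_true, probs, threshold)
    m = classification_metrics(c)
    return MetricsReport(
        **m, AUROC=auroc(y_true, probs), AUPRC=auprc(y_true, probs),
        threshold=threshold,
    )


def write_report(
    reports: dict[str, MetricsReport], path: str | Path
) -> None:
    """Evaluation report CSV: one row per predictor (plus the ensemble)."""
    cols = ["Sn", "Sp", "Acc", "Pre", "F1", "MCC", "AUROC", "AUPRC",
            "threshold"]
    with open(path, "w") as fh:
        fh.write("predictor," + ",".join(cols) + "\n")
        for name, rep in reports.items():
            d = rep.as_dict()
            fh.write(name + "," + ",".join(f"{d[c]:.6f}" for c in cols) + "\n")


def write_curve_points(
    y_true: Sequence[int], scores: Sequence[float], path: str | Path
) -> None:
    """Dump ROC and PR curve points as CSV for plotting."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y, s)
    pre, rec, _ = precision_recall_curve(y, s)
    with open(path, "w") as fh:
        fh.write("curve,x,y\n")
        for x, yy in zip(fpr, tpr):
            fh.write(f"roc,{x:.6f},{yy:.6f}\n")
        for x, yy in zip(rec, pre):
            fh.write(f"prc,{x:.6f},{yy:.6f}\n")
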