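"""Confusion-matrix metrics and rank-based ROC/AUC.

Sensitivity, specificity, accuracy, F1 and the Matthews correlation
coefficient are computed directly from TP/FP/FN/TN. Any metric whose
denominator is zero returns 0 by convention so reports stay total on
degenerate folds (e.g. no positive calls).

AUC is the rank statistic: the probability that a random positive outscores
a random negative, ties counted half — identical to the normalized
Mann-Whitney U. The ROC curve is the threshold sweep over the distinct
decision values, plotted as (1 - Sp, Sn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .types import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have the same length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


@dataclass
class MetricReport:
    sn: float
    sp: float
    acc: float
    f1: float
    mcc: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "Sn": self.sn,
            "Sp": self.sp,
            "Acc": self.acc,
            "F1": self.f1,
            "MCC": self.mcc,
            "TP": self.counts.tp,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
            "TN": self.counts.tn,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Sn, Sp, Acc, F1 and MCC from confusion counts (0 on empty denominators)."""
    if counts.total <= 0:
        raise ValidationError("confusion counts are empty")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    acc = _ratio(tn + tp, counts.total)
    precision = _ratio(tp, tp + fp)
    recall = sn
    f1 = _ratio(2 * precision * recall, precision + recall)
    mcc_den = np.sqrt(float(tp + fp) * (fn + tn) * (tp + fn) * (tn + fp))
    mcc = (tn * tp - fp * fn) / mcc_den if mcc_den > 0 else 0.0
    return MetricReport(sn=sn, sp=sp, acc=acc, f1=f1, mcc=mcc, counts=counts)


def compute_auc(decision_values, labels) -> tuple[float, np.ndarray]:
    """Rank-based AUC and the ROC polyline.

    Returns ``(auc, roc)`` where ``roc`` is an array of (1 - Sp, Sn) points
    starting at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.shape != y.shape:
        raise ValidationError("decision values and labels must align")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks: ties count half
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, scores)
    roc = np.column_stack([fpr, tpr])
    return float(auc), roc


@dataclass
class EvalReport:
    """Aggregate held-out evaluation: metrics, AUC, ROC and per-sample scores."""

    metrics: MetricReport
    auc: float
    roc: np.ndarray
    decision_values: np.ndarray
    n_fits: int = 0
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = self.metrics.as_dict()
        d["AUC"] = self.auc
        d["n_fits"] = self.n_fits
        d.update(self.extras)
        return d
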