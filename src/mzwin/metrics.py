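"""Binary-classification evaluation metrics.

Positive = disease, negative = health throughout.  The seven reported
quantities are precision, specificity, sensitivity (= recall), Matthews
correlation coefficient, accuracy, F1 and a rank-based AUC:

    AUC = (sum of positive ranks - M(M+1)/2) / (M * N)

with ranks ascending over the pooled scores and mid-ranks for ties,
which makes the statistic the exact Mann-Whitney U estimator.  Metric
cells whose denominator is 0 are reported as 0 and flagged degenerate
rather than raising, so sweep loops survive tiny validation folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "compute_metrics",
           "auc_rank", "full_report"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    precision: float
    specificity: float
    sensitivity: float
    mcc: float
    accuracy: float
    f1: float
    auc: float | None = None
    degenerate: bool = False  # some 0/0 cell was reported as 0

    def to_dict(self) -> dict:
        d = {"precision": self.precision, "specificity": self.specificity,
             "sensitivity": self.sensitivity, "mcc": self.mcc,
             "accuracy": self.accuracy, "f1": self.f1}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with 1 = disease (positive), 0 = health."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Precision, specificity, sensitivity, MCC, accuracy and F1 from counts."""
    degenerate = False
    precision, d = _ratio(c.tp, c.tp + c.fp); degenerate |= d
    specificity, d = _ratio(c.tn, c.tn + c.fp); degenerate |= d
    sensitivity, d = _ratio(c.tp, c.tp + c.fn); degenerate |= d
    accuracy, d = _ratio(c.tp + c.tn, c.total); degenerate |= d

    mcc_den = math.sqrt((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc, d = _ratio(c.tp * c.tn - c.fp * c.fn, mcc_den); degenerate |= d
    f1, d = _ratio(2 * precision * sensitivity, precision + sensitivity); degenerate |= d
    return MetricReport(precision=precision, specificity=specificity,
                        sensitivity=sensitivity, mcc=mcc, accuracy=accuracy,
                        f1=f1, degenerate=degenerate)


def auc_rank(scores, labels) -> float:
    """Rank-formula AUC over positive-class scores, mid-ranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    m = int(np.sum(labels == 1))
    n = int(np.sum(labels == 0))
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # ascending, average ties
    pos_rank_sum = float(ranks[labels == 1].sum())
    return (pos_rank_sum - m * (m + 1) / 2) / (m * n)


def full_report(y_true, y_pred, scores=None) -> MetricReport:
    """Confusion-based metrics plus rank AUC when scores are given."""
    rep = compute_metrics(confusion(y_true, y_pred))
    if scores is not None:
        rep.auc = auc_rank(scores, y_true)
    return rep
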