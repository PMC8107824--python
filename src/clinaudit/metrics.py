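"""Threshold-based classification metrics, ROC curves and AUC.

Conventions: a record is predicted positive when its score is greater than
or equal to the threshold (boundary inclusive); quartiles use linear
interpolation between order statistics (type 7); MCC and F1 return 0 on
degenerate denominators so resampling audit loops never crash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import DegenerateCurveError


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCCurve:
    """Empirical ROC as parallel arrays over descending thresholds.

    ``thresholds[0]`` is +inf (the all-negative anchor at (0, 0)); the curve
    ends at (1, 1).  Tied scores collapse into a single threshold.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    group_label: str | None = None

    def point_at_threshold(self, threshold: float) -> tuple[float, float]:
        """Achieved (fpr, tpr) of the rule score >= threshold."""
        idx = int(np.sum(self.thresholds >= threshold)) - 1
        idx = max(idx, 0)
        return float(self.fpr[idx]), float(self.tpr[idx])

    def to_csv(self, path) -> None:
        pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr}).to_csv(path, index=False)


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if scores.size == 0:
        raise ValueError("empty input")
    return scores, labels


def confusion_counts(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion table of the rule score >= threshold."""
    scores, labels = _as_arrays(scores, labels)
    predicted = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(predicted & (labels == 1))),
        fp=int(np.sum(predicted & (labels == 0))),
        tn=int(np.sum(~predicted & (labels == 0))),
        fn=int(np.sum(~predicted & (labels == 1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("accuracy undefined for zero records")
    return (c.tp + c.tn) / c.total


def f1_score(c: ConfusionCounts) -> float:
    denominator = 2 * c.tp + c.fp + c.fn
    if denominator == 0:
        return 0.0
    return 2 * c.tp / denominator


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def roc_curve(scores, labels, group_label: str | None = None) -> ROCCurve:
    """Empirical step ROC over all distinct score thresholds."""
    scores, labels = _as_arrays(scores, labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateCurveError("ROC needs both classes present")
    fpr, tpr, thresholds = _skm.roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(
        thresholds=np.asarray(thresholds, dtype=float),
        fpr=np.asarray(fpr, dtype=float),
        tpr=np.asarray(tpr, dtype=float),
        group_label=group_label,
    )


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve.

    Equal to the rank-pair statistic P(score+ > score-) with half credit for
    ties, because tied scores collapse to a single curve point and the
    trapezoid across it splits the tied block evenly.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_score(scores, labels) -> float:
    """AUC straight from scores; convenience for tight audit loops."""
    scores, labels = _as_arrays(scores, labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateCurveError("AUC needs both classes present")
    return float(_skm.roc_auc_score(labels, scores))


@dataclass
class IQRSummary:
    median: float
    q1: float
    q3: float
    iqr: float


def iqr_summary(samples) -> IQRSummary:
    """Median and interquartile range with type-7 (linear) quartiles."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("iqr_summary of empty collection")
    q1, med, q3 = np.percentile(samples, [25, 50, 75])
    return IQRSummary(median=float(med), q1=float(q1), q3=float(q3), iqr=float(q3 - q1))
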