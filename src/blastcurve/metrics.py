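"""Classifier evaluation: ROC curves and AUC, macro F1, confusion matrices
with row percentages, fold-averaged ROC curves, and boxplot summaries for
learning curves.

Thin, typed wrappers over scikit-learn with the conventions fixed: ROC-AUC
is the Mann-Whitney probability (ties count one half), F1 is macro-averaged
(motivated by imbalanced test sets), fold-mean ROC curves are vertically
averaged on a common false-positive-rate grid, and boxplot statistics use
linearly interpolated quartiles with 1.5*IQR whisker fences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "RocCurve",
    "ConfusionMatrix",
    "CurveSummary",
    "MetricError",
    "roc_auc",
    "roc_curve",
    "mean_roc",
    "f1_macro",
    "confusion",
    "summarize_box",
]


class MetricError(ValueError):
    """Metric undefined for the given inputs (e.g. single-class labels)."""


@dataclass
class RocCurve:
    """Empirical ROC curve: descending thresholds, monotone FPR/TPR, AUC."""

    thresholds: np.ndarray
    false_positive_rate: np.ndarray
    true_positive_rate: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.false_positive_rate) < -1e-12) or np.any(
            np.diff(self.true_positive_rate) < -1e-12
        ):
            raise MetricError("ROC curve must be monotone non-decreasing")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise MetricError(
            f"ROC requires both classes present; got classes {classes.tolist()}"
        )
    return (labels == classes.max()).astype(int)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve of positive-class scores.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half (the Mann-Whitney statistic), which is
    identical to the trapezoidal area under the empirical ROC curve.
    """
    y = _check_binary(np.asarray(labels))
    return float(_skm.roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC curve from positive-class scores and binary labels."""
    y = _check_binary(np.asarray(labels))
    fpr, tpr, thr = _skm.roc_curve(y, np.asarray(scores, dtype=float))
    return RocCurve(
        thresholds=thr,
        false_positive_rate=fpr,
        true_positive_rate=tpr,
        auc=float(np.trapezoid(tpr, fpr)),
    )


def mean_roc(curves: list[RocCurve], grid_size: int = 101) -> tuple[RocCurve, float]:
    """Vertically averaged ROC over folds on a common FPR grid.

    Returns (mean curve, mean of the individual AUCs).  The mean curve's own
    ``auc`` (area under the averaged curve) generally differs slightly from
    the mean-of-AUCs; both are reported because summary statistics in the
    literature use either convention.
    """
    if not curves:
        raise MetricError("need at least one ROC curve")
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for c in curves:
        # vertical jumps share an FPR value: keep the upper envelope, then
        # interpolate the piecewise-linear curve on the common grid
        fpr, tpr = c.false_positive_rate, c.true_positive_rate
        uniq, inverse = np.unique(fpr, return_inverse=True)
        upper = np.zeros_like(uniq, dtype=float)
        np.maximum.at(upper, inverse, tpr)
        tprs.append(np.interp(grid, uniq, upper))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    curve = RocCurve(
        thresholds=np.full(grid_size, np.nan),
        false_positive_rate=grid,
        true_positive_rate=mean_tpr,
        auc=float(np.trapezoid(mean_tpr, grid)),
    )
    return curve, float(np.mean([c.auc for c in curves]))


def f1_macro(pred, true) -> float:
    """Unweighted mean over classes of 2PR/(P+R); empty classes score 0."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.size == 0 or pred.shape != true.shape:
        raise MetricError("predictions and truth must be equal-length, non-empty")
    return float(_skm.f1_score(true, pred, average="macro", zero_division=0))


@dataclass
class ConfusionMatrix:
    """Counts (rows = true class) with row percentages and per-class totals.

    ``row_percent`` rows sum to 100 for non-empty classes and are NaN
    (flagged, not silently 0) for classes absent from the truth.
    """

    class_order: list[str]
    counts: np.ndarray
    row_percent: np.ndarray = field(init=False)
    per_class_n: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.per_class_n = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.row_percent = 100.0 * self.counts / self.per_class_n[:, None]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


def confusion(pred, true, class_order: list[str]) -> ConfusionMatrix:
    """Confusion matrix over an explicit class ordering."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    known = set(class_order)
    for name, arr in (("prediction", pred), ("truth", true)):
        unknown = set(arr.tolist()) - known
        if unknown:
            raise MetricError(f"unknown {name} label(s): {sorted(unknown)}")
    counts = _skm.confusion_matrix(true, pred, labels=class_order)
    return ConfusionMatrix(class_order=list(class_order), counts=counts)


@dataclass
class CurveSummary:
    """Boxplot statistics for one group of values (one training-set size)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def summarize_box(values) -> CurveSummary:
    """Median, linearly interpolated quartiles, 1.5*IQR whiskers, outliers.

    Whiskers are the extreme data points inside [q1 - 1.5*IQR, q3 + 1.5*IQR];
    points beyond the fences are listed as outliers.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise MetricError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return CurveSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )
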