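"""Figures: learning-curve boxplots, fold-averaged ROC curves, confusion
matrices with per-class totals, and relevance-map renderings."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .interpret import RelevanceMap
from .metrics import ConfusionMatrix, RocCurve

__all__ = [
    "plot_learning_curve",
    "plot_roc",
    "plot_confusion",
    "render_relevance",
]


def plot_learning_curve(records, ax=None, metric_label: str | None = None):
    """Boxplot of metric values per training-set size (whiskers at 1.5 IQR)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sizes = sorted(records["train_size"].unique())
    groups = [records.loc[records["train_size"] == s, "metric_value"].to_numpy() for s in sizes]
    ax.boxplot(groups, tick_labels=[str(s) for s in sizes], whis=1.5)
    ax.set_xlabel("training images")
    ax.set_ylabel(metric_label or records["metric_name"].iloc[0])
    ax.set_ylim(0.0, 1.05)
    return ax


def plot_roc(curves: list[RocCurve], mean_curve: RocCurve | None = None, ax=None):
    """Per-fold ROC curves (thin) with an optional fold-mean curve (thick)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for c in curves:
        ax.plot(c.false_positive_rate, c.true_positive_rate, color="0.7", lw=0.8)
    if mean_curve is not None:
        ax.plot(
            mean_curve.false_positive_rate,
            mean_curve.true_positive_rate,
            color="C0",
            lw=2,
            label=f"mean (AUC {mean_curve.auc:.2f})",
        )
        ax.legend(loc="lower right")
    ax.plot([0, 1], [0, 1], ls="--", color="0.5", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    return ax


def plot_confusion(cm: ConfusionMatrix, ax=None):
    """Row-percentage heatmap with per-class image counts on the right."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    pct = np.nan_to_num(cm.row_percent)
    im = ax.imshow(pct, cmap="Blues", vmin=0, vmax=100)
    n = len(cm.class_order)
    for i in range(n):
        for j in range(n):
            if cm.per_class_n[i] > 0:
                ax.text(
                    j, i, f"{cm.row_percent[i, j]:.0f}",
                    ha="center", va="center",
                    color="white" if pct[i, j] > 50 else "black", fontsize=8,
                )
        ax.text(n - 0.3, i, f" n={cm.per_class_n[i]}", va="center", fontsize=8)
    ax.set_xticks(range(n), cm.class_order, rotation=45, ha="right")
    ax.set_yticks(range(n), cm.class_order)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    plt.colorbar(im, ax=ax, shrink=0.8, label="% of true class")
    return ax


def render_relevance(rmap: RelevanceMap, image: np.ndarray | None = None, ax=None):
    """Render a relevance map: diverging red/blue for signed LRP values,
    monotone brightness for saliency; optional image underlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if image is not None:
        ax.imshow(image, alpha=0.6)
    v = rmap.values
    if rmap.method == "lrp":
        lim = np.abs(v).max() or 1.0
        ax.imshow(v, cmap="bwr", vmin=-lim, vmax=lim, alpha=0.7)
    else:
        ax.imshow(v, cmap="gray", vmin=0.0, vmax=v.max() or 1.0, alpha=0.7)
    ax.set_axis_off()
    ax.set_title(f"{rmap.method} (class {rmap.target_class})", fontsize=9)
    return ax
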