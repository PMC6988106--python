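"""Surface-node evaluation metrics and correlation analysis.

Scar quantification is scored on the projected LA surface: per-node
confusion counts give Dice of the scar label, accuracy, sensitivity and
specificity, and the generalized Dice

    GDice = 2 * sum_k |S_k^auto ∩ S_k^manual|
            / sum_k (|S_k^auto| + |S_k^manual|),

the label-weighted overlap over both classes (k in {normal, scar}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MetricsReport", "surface_metrics", "correlation_report", "voxel_dice"]


@dataclass
class MetricsReport:
    dice_scar: float
    gdice: float
    accuracy: float
    sensitivity: float  # NaN when there are no truth-positive nodes
    specificity: float  # NaN when there are no truth-negative nodes
    n_nodes: int
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("dice_scar", "gdice", "accuracy", "sensitivity",
                 "specificity", "n_nodes", "tp", "fp", "tn", "fn")}


def voxel_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Dice overlap of two binary volumes (debugging aid)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def surface_metrics(pred, truth) -> MetricsReport:
    """Confusion-count metrics over surface nodes for binary label vectors."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1D label vectors")
    for arr in (pred, truth):
        if set(np.unique(arr)) - {0, 1}:
            raise ValueError("labels must be binary")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    n = len(pred)
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / n
    # generalized Dice over both labels: overlap and sizes per label
    inter = tp + tn
    sizes = (tp + fp) + (tp + fn) + (tn + fn) + (tn + fp)  # |S1a|+|S1m|+|S0a|+|S0m|
    gdice = 2 * inter / sizes if sizes else 1.0
    return MetricsReport(dice, gdice, acc, sens, spec, n, tp, fp, tn, fn)


def correlation_report(dice_la, dice_scar) -> tuple[float, float, float]:
    """(Pearson, Spearman, R^2 of OLS of dice_scar on dice_la)."""
    x = np.asarray(dice_la, dtype=float)
    y = np.asarray(dice_scar, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for zero-variance inputs")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    r_squared = float(stats.linregress(x, y).rvalue ** 2)
    return pearson, spearman, r_squared
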