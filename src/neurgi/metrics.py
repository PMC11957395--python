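"""Evaluation metrics and Gini-impurity accounting, as pure functions.

These implement the standard binary-classification formulas directly:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)        accuracy = (TP + TN) / n
    F1  = 2 PR / (P + R)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

ROC AUC is trapezoidal integration over all score thresholds (equivalently the
tie-corrected Mann-Whitney concordance probability); PR AUC uses step-wise
interpolation (precision held at each threshold over its recall increment).

Node impurity uses G(t) = 1 - sum_i p_i^2 and the split decrease
dG = G(t) - (n_L/n) G(t_L) - (n_R/n) G(t_R); a feature's mean decrease Gini
sums its node-fraction-weighted dG over all splits and trees and divides by
the tree count (a constant divisor, so it is a ranking over features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "confusion_metrics",
    "roc_auc",
    "pr_auc",
    "gini_impurity",
    "split_decrease",
    "tree_mean_decrease_gini",
    "forest_mean_decrease_gini",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The five headline metrics plus their ingredients for one model/fold."""

    auc: float
    auc_pr: float
    acc: float
    mcc: float
    f1: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float

    def mean_of_five(self) -> float:
        return (self.auc + self.auc_pr + self.acc + self.mcc + self.f1) / 5.0


def confusion_counts(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    if not set(np.unique(y)) <= {0, 1} or not set(np.unique(p)) <= {0, 1}:
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_counts(
    c: ConfusionCounts, auc: float = float("nan"), auc_pr: float = float("nan")
) -> MetricReport:
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    acc = (tp + tn) / c.n
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    # MCC is 0 by convention when any marginal is empty.
    mcc = _safe_div(tp * tn - fp * fn, np.sqrt(denom)) if denom > 0 else 0.0
    f1 = _safe_div(2 * prec * sens, prec + sens)
    return MetricReport(
        auc=auc, auc_pr=auc_pr, acc=acc, mcc=float(mcc), f1=f1,
        sensitivity=sens, specificity=spec, precision=prec, recall=sens,
    )


def confusion_metrics(labels: np.ndarray, predictions: np.ndarray) -> MetricReport:
    """ACC / MCC / F1 / sensitivity / specificity / precision / recall
    from binary labels and binary predictions (AUCs are NaN here — they need
    continuous scores)."""
    return metrics_from_counts(confusion_counts(labels, predictions))


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration over thresholds.

    Equals the probability that a random positive outscores a random negative,
    with half credit for ties (Mann-Whitney convention).
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    # cumulative TP/FP at each distinct threshold (ties grouped)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], y_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def pr_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve with step-wise interpolation.

    Sums precision at each distinct threshold times the recall gained there
    (no linear interpolation between PR points). Constant scores give the
    positive prevalence.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise ValueError("PR AUC needs at least one positive")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], y_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    precision = tps / (tps + fps)
    recall = tps / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * d_recall))


def gini_impurity(class_proportions: np.ndarray) -> float:
    """G(t) = 1 - sum_i p_i^2 for class proportions at a node."""
    p = np.asarray(class_proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    return float(1.0 - np.sum(p**2))


def split_decrease(
    parent: np.ndarray, left: np.ndarray, right: np.ndarray
) -> float:
    """Impurity decrease dG = G(t) - (n_L/n) G(t_L) - (n_R/n) G(t_R).

    Arguments are per-class sample counts; left and right must partition the
    parent exactly.
    """
    parent = np.asarray(parent, dtype=float)
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if not np.array_equal(left + right, parent):
        raise ValueError("children do not partition the parent counts")
    n = parent.sum()
    n_l, n_r = left.sum(), right.sum()
    if n == 0 or n_l == 0 or n_r == 0:
        raise ValueError("empty node in split")
    g = gini_impurity(parent / n)
    g_l = gini_impurity(left / n_l)
    g_r = gini_impurity(right / n_r)
    return float(g - (n_l / n) * g_l - (n_r / n) * g_r)


def _tree_split_records(tree) -> list[tuple[int, float, float]]:
    """(feature_index, dG, node_fraction) for every internal node of a tree.

    ``node_fraction`` is the node's share of the tree's root samples, the
    weight the forest importance uses.
    """
    t = tree.tree_
    # recent sklearn stores classifier node values as class proportions,
    # older versions as counts; normalize to counts either way
    as_proportions = np.allclose(t.value.sum(axis=2), 1.0)

    def counts(node: int) -> np.ndarray:
        v = t.value[node][0]
        if as_proportions:
            v = v * t.weighted_n_node_samples[node]
        return np.round(v)

    root_n = t.weighted_n_node_samples[0]
    records: list[tuple[int, float, float]] = []
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        dg = split_decrease(counts(node), counts(left), counts(right))
        frac = float(t.weighted_n_node_samples[node] / root_n)
        records.append((int(t.feature[node]), dg, frac))
    return records


def tree_mean_decrease_gini(tree, n_features: int) -> np.ndarray:
    """Per-feature decrease-Gini total from one fitted decision tree.

    Each split contributes its impurity decrease dG weighted by the node's
    sample fraction, summed per splitting feature; a feature never selected
    in any split scores 0.
    """
    out = np.zeros(n_features)
    for feat, dg, frac in _tree_split_records(tree):
        out[feat] += frac * dg
    return out


def forest_mean_decrease_gini(forest, n_features: int) -> np.ndarray:
    """Per-feature mean decrease Gini over a fitted forest.

    The node-fraction-weighted decrease from each feature is summed across
    all nodes and trees and divided by the number of trees — the divisor is
    a constant, so rankings are unaffected by how often a feature splits.
    """
    total = np.zeros(n_features)
    for tree in forest.estimators_:
        total += tree_mean_decrease_gini(tree, n_features)
    return total / len(forest.estimators_)
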