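"""Balanced training-set construction, the cross-validated forest ensemble,
gene scoring, feature importance and importance-driven ablation.

Training follows the published protocol: the reliable negatives are
under-sampled with per-gene-type stratification to match the positive set
exactly; k-fold cross-validation fits one random forest per fold (Gini
criterion, ``m_try`` features per split, ``n_trees`` trees); the final score
of a gene outside the training set is the mean positive-vote fraction over
the k fold models. Ablation ranks features by relative mean decrease Gini of
the baseline ensemble and removes them from the bottom up, keeping the depth
that maximizes the mean of AUC, AUC-PR, ACC, MCC and F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .config import RunConfig
from .metrics import (
    MetricReport,
    confusion_counts,
    forest_mean_decrease_gini,
    metrics_from_counts,
    pr_auc,
    roc_auc,
)
from .types import GeneFeatureTable, ValidationError

__all__ = [
    "stratified_undersample",
    "ForestEnsemble",
    "train_ensemble",
    "score_genes",
    "ensemble_importance",
    "AblationResult",
    "feature_ablation",
]

logger = logging.getLogger("neurgi")


def stratified_undersample(
    negatives: set[str] | frozenset[str],
    positives: set[str] | frozenset[str],
    strata: pd.Series,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Sample negatives so each gene-type stratum matches the positive counts.

    Returns (positives, sampled_negatives), both sorted for determinism, with
    ``len(sampled) == len(positives)``. A stratum short of negatives is topped
    up from the 'other' stratum, then from any remaining negatives (logged).
    """
    rng = np.random.default_rng(seed)
    pos = sorted(positives)
    neg = sorted(negatives)
    if set(pos) & set(negatives):
        raise ValidationError("positives and negatives overlap")
    pos_counts = strata.loc[pos].value_counts().to_dict()
    neg_by_stratum: dict[str, list[str]] = {}
    for g in neg:
        neg_by_stratum.setdefault(str(strata.loc[g]), []).append(g)

    sampled: list[str] = []
    shortfall = 0
    for stratum, want in sorted(pos_counts.items()):
        pool = neg_by_stratum.get(stratum, [])
        take = min(want, len(pool))
        if take:
            chosen = rng.choice(np.array(pool), size=take, replace=False).tolist()
            sampled.extend(chosen)
            neg_by_stratum[stratum] = [g for g in pool if g not in set(chosen)]
        shortfall += want - take
    if shortfall:
        logger.warning("stratified undersample: topping up %d genes across strata", shortfall)
        spare = neg_by_stratum.get("other", [])
        take = min(shortfall, len(spare))
        if take:
            chosen = rng.choice(np.array(spare), size=take, replace=False).tolist()
            sampled.extend(chosen)
            neg_by_stratum["other"] = [g for g in spare if g not in set(chosen)]
            shortfall -= take
        if shortfall:
            remaining = sorted(set(neg) - set(sampled))
            if shortfall > len(remaining):
                raise ValidationError("not enough negatives to balance the positives")
            sampled.extend(rng.choice(np.array(remaining), size=shortfall, replace=False).tolist())
    return pos, sorted(sampled)


@dataclass
class ForestEnsemble:
    """The k cross-validation forests whose averaged vote is the gene score."""

    fold_models: list[RandomForestClassifier]
    retained_features: list[str]
    config: RunConfig
    fold_metrics: list[MetricReport] = field(default_factory=list)
    oof_scores: pd.Series | None = None  # out-of-fold scores of training genes

    @property
    def k(self) -> int:
        return len(self.fold_models)

    def mean_metrics(self) -> dict[str, float]:
        keys = ("auc", "auc_pr", "acc", "mcc", "f1")
        return {k: float(np.mean([getattr(m, k) for m in self.fold_metrics])) for k in keys}


def _fold_report(y_true: np.ndarray, proba: np.ndarray) -> MetricReport:
    pred = (proba > 0.5).astype(int)
    counts = confusion_counts(y_true, pred)
    base = metrics_from_counts(counts)
    return MetricReport(
        auc=roc_auc(y_true, proba),
        auc_pr=pr_auc(y_true, proba),
        acc=base.acc, mcc=base.mcc, f1=base.f1,
        sensitivity=base.sensitivity, specificity=base.specificity,
        precision=base.precision, recall=base.recall,
    )


def train_ensemble(
    table: GeneFeatureTable,
    labels: pd.Series,
    config: RunConfig,
    seed_stage: str = "train",
) -> ForestEnsemble:
    """Fit k stratified-CV random forests and evaluate each held-out fold.

    ``labels`` is a binary Series over a (balanced) subset of the table's
    genes. Each fold's forest uses ``config.n_trees`` trees with
    ``config.m_try`` candidate features per split and the Gini criterion.
    """
    genes = list(labels.index)
    if table.has_nan():
        raise ValidationError("feature table has NaN; impute first")
    y = labels.to_numpy(dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("labels must contain both classes")
    if config.m_try > len(table.feature_names):
        raise ValidationError(
            f"m_try={config.m_try} exceeds feature count {len(table.feature_names)}"
        )
    min_class = min(int((y == 1).sum()), int((y == 0).sum()))
    if config.k_folds > min_class:
        raise ValidationError("k_folds exceeds the minority class size")

    x = table.features.loc[genes].to_numpy(dtype=float)
    splitter = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=config.stage_seed(seed_stage, 0)
    )
    models: list[RandomForestClassifier] = []
    reports: list[MetricReport] = []
    oof = pd.Series(np.nan, index=pd.Index(genes, name="gene_id"), dtype=float)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(x, y)):
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.m_try,
            criterion="gini",
            random_state=config.stage_seed(seed_stage, fold + 1),
            n_jobs=1,
        )
        forest.fit(x[train_idx], y[train_idx])
        proba = forest.predict_proba(x[test_idx])[:, 1]
        oof.iloc[test_idx] = proba
        reports.append(_fold_report(y[test_idx], proba))
        models.append(forest)
    return ForestEnsemble(
        fold_models=models,
        retained_features=list(table.feature_names),
        config=config,
        fold_metrics=reports,
        oof_scores=oof,
    )


def score_genes(ensemble: ForestEnsemble, table: GeneFeatureTable) -> pd.Series:
    """Mean positive-class vote fraction over the k fold models, in [0, 1]."""
    missing = set(ensemble.retained_features) - set(table.feature_names)
    if missing:
        raise ValidationError(f"table lacks trained features: {sorted(missing)}")
    x = table.features[ensemble.retained_features].to_numpy(dtype=float)
    votes = np.mean(
        [m.predict_proba(x)[:, 1] for m in ensemble.fold_models], axis=0
    )
    return pd.Series(votes, index=table.features.index, name="score")


def ensemble_importance(ensemble: ForestEnsemble) -> pd.DataFrame:
    """Mean decrease Gini per feature, averaged over fold models.

    Returns a DataFrame with ``mean_decrease_gini`` and ``relative_importance``
    (normalized to sum to 1), indexed by feature name.
    """
    n_feat = len(ensemble.retained_features)
    mdg = np.mean(
        [forest_mean_decrease_gini(m, n_feat) for m in ensemble.fold_models], axis=0
    )
    total = mdg.sum()
    rel = mdg / total if total > 0 else np.full(n_feat, 1.0 / n_feat)
    return pd.DataFrame(
        {"mean_decrease_gini": mdg, "relative_importance": rel},
        index=pd.Index(ensemble.retained_features, name="feature"),
    )


@dataclass
class AblationResult:
    trace: pd.DataFrame            # rows: removal depth 0..D; metric columns + mean
    removed_order: list[str]       # bottom-ranked first
    selected_depth: int
    selected_features: list[str]
    model: ForestEnsemble          # refit at the selected depth


def feature_ablation(
    table: GeneFeatureTable,
    labels: pd.Series,
    config: RunConfig,
    rerank: bool = False,
) -> AblationResult:
    """Importance-driven backward feature elimination.

    Trains the baseline ensemble on all features, ranks features ascending by
    relative mean decrease Gini, then removes the bottom feature one depth at
    a time, retraining and recording AUC, AUC-PR, ACC, MCC, F1 and their mean
    on held-out folds. Stops when a removal would leave fewer than ``m_try``
    features. The depth maximizing the five-metric mean wins; ties break
    toward fewer features. ``rerank=True`` recomputes the ranking from each
    refit instead of reusing the baseline order.
    """
    if len(table.feature_names) < 2:
        raise ValidationError("ablation needs >= 2 features")
    current = table
    baseline = train_ensemble(current, labels, config, seed_stage="ablate0")
    ranking = ensemble_importance(baseline)["relative_importance"].sort_values(
        kind="mergesort"
    )

    rows = [{"depth": 0, "removed": "", **baseline.mean_metrics()}]
    rows[0]["mean"] = float(np.mean([rows[0][k] for k in ("auc", "auc_pr", "acc", "mcc", "f1")]))
    ensembles = [baseline]
    removed: list[str] = []
    depth = 0
    while len(current.feature_names) - 1 >= config.m_try:
        if rerank:
            ranking = ensemble_importance(ensembles[-1])["relative_importance"].sort_values(
                kind="mergesort"
            )
            victim = str(ranking.index[0])
        else:
            remaining_rank = ranking[~ranking.index.isin(removed)]
            victim = str(remaining_rank.index[0])
        depth += 1
        removed.append(victim)
        current = current.subset_features(
            [f for f in current.feature_names if f != victim]
        )
        ens = train_ensemble(current, labels, config, seed_stage=f"ablate{depth}")
        row = {"depth": depth, "removed": victim, **ens.mean_metrics()}
        row["mean"] = float(np.mean([row[k] for k in ("auc", "auc_pr", "acc", "mcc", "f1")]))
        rows.append(row)
        ensembles.append(ens)

    trace = pd.DataFrame(rows).set_index("depth")
    best = trace["mean"].to_numpy()
    # argmax with ties broken toward the deepest removal (fewest features)
    selected = int(np.flatnonzero(best >= best.max() - 1e-12)[-1])
    chosen = ensembles[selected]
    logger.info(
        "ablation: selected depth %d of %d (mean metric %.4f, %d features kept)",
        selected, depth, best[selected], len(chosen.retained_features),
    )
    return AblationResult(
        trace=trace,
        removed_order=removed,
        selected_depth=selected,
        selected_features=list(chosen.retained_features),
        model=chosen,
    )
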