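"""End-to-end orchestration: feature table -> spy labeling -> balanced
training -> cross-validated forest -> scoring -> mixture classification.

:func:`run_pipeline` chains every stage under one :class:`~neurgi.config.RunConfig`
and returns a :class:`PipelineReport` whose bookkeeping identities (set sizes,
class-count partition) are asserted before it is returned.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .classify import classify_scores, derive_thresholds, find_score_peaks, fit_gmm
from .config import RunConfig
from .io import provenance_header, write_feature_table
from .model import AblationResult, feature_ablation, score_genes, stratified_undersample, train_ensemble
from .pulearn import label_reliable_negatives
from .synthetic import SyntheticSpec, generate_feature_table
from .types import GeneFeatureTable, ValidationError

__all__ = ["PipelineReport", "run_pipeline", "run_synthetic_pipeline"]

logger = logging.getLogger("neurgi")


@dataclass
class PipelineReport:
    """Provenance-stamped summary of one pipeline run."""

    config: RunConfig
    set_sizes: dict[str, int]
    balanced_n: int
    rn_threshold: float
    fold_metrics: list[dict[str, float]]
    mean_metrics: dict[str, float]
    ablation_selected_depth: int | None
    ablation_removed: list[str]
    retained_features: list[str]
    thresholds: tuple[float, float] | None
    class_counts: dict[str, int]
    n_scored: int
    peaks: list[float]
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        s = self.set_sizes
        if s["Us"] != s["U"] + s["spies"]:
            raise ValidationError("Us size must equal U + spies")
        if s["Ps"] != s["P"] - s["spies"]:
            raise ValidationError("Ps size must equal P - spies")
        if self.class_counts and sum(self.class_counts.values()) != self.n_scored:
            raise ValidationError("class counts must partition the scored genes")

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config.to_dict(),
            "set_sizes": self.set_sizes,
            "balanced_n": self.balanced_n,
            "rn_threshold": self.rn_threshold,
            "fold_metrics": self.fold_metrics,
            "mean_metrics": self.mean_metrics,
            "ablation_selected_depth": self.ablation_selected_depth,
            "ablation_removed": self.ablation_removed,
            "retained_features": self.retained_features,
            "thresholds": list(self.thresholds) if self.thresholds else None,
            "class_counts": self.class_counts,
            "n_scored": self.n_scored,
            "peaks": self.peaks,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def run_pipeline(
    table: GeneFeatureTable,
    positives: set[str] | frozenset[str],
    config: RunConfig,
    ablate: bool = False,
    out_dir: str | Path | None = None,
) -> tuple[PipelineReport, pd.Series]:
    """Run spy labeling, balanced training, scoring and classification.

    Returns the report and the per-gene scores of all genes outside the
    balanced training set. With ``ablate=True`` the importance-driven
    feature ablation selects the retained feature set before final scoring.
    Output files (scores, classes, report) are written when ``out_dir`` is
    given.
    """
    timings: dict[str, float] = {}

    def _clock(stage: str, start: float) -> None:
        timings[stage] = round(time.perf_counter() - start, 3)

    t0 = time.perf_counter()
    spy = label_reliable_negatives(table, positives, config)
    _clock("pu_label", t0)
    sets = spy.sets

    t0 = time.perf_counter()
    pos_list, neg_list = stratified_undersample(
        sets.reliable_negatives, sets.positives, table.gene_type,
        config.stage_seed("undersample"),
    )
    labels = pd.Series(
        np.r_[np.ones(len(pos_list), dtype=int), np.zeros(len(neg_list), dtype=int)],
        index=pd.Index(pos_list + neg_list, name="gene_id"),
    )
    _clock("undersample", t0)

    t0 = time.perf_counter()
    ablation: AblationResult | None = None
    if ablate:
        ablation = feature_ablation(table, labels, config)
        ensemble = ablation.model
        scoring_table = table.subset_features(ensemble.retained_features)
    else:
        ensemble = train_ensemble(table, labels, config)
        scoring_table = table
    _clock("train", t0)

    t0 = time.perf_counter()
    training_genes = set(labels.index)
    external = [g for g in table.gene_ids if g not in training_genes]
    scores = score_genes(ensemble, scoring_table.subset_genes(external))
    _clock("score", t0)

    t0 = time.perf_counter()
    thresholds: tuple[float, float] | None = None
    class_counts: dict[str, int] = {}
    peaks: list[float] = []
    if len(scores) >= 10 * config.gmm_components:
        peaks = [float(p) for p in find_score_peaks(scores.to_numpy())]
        gmm = fit_gmm(
            scores.to_numpy(), components=config.gmm_components,
            seed=config.stage_seed("gmm"),
        )
        thresholds = derive_thresholds(gmm)
        result = classify_scores(scores, thresholds)
        class_counts = result.counts()
    else:
        logger.warning("too few scored genes (%d) for mixture classification", len(scores))
    _clock("classify", t0)

    report = PipelineReport(
        config=config,
        set_sizes=sets.sizes(),
        balanced_n=len(labels),
        rn_threshold=spy.threshold,
        fold_metrics=[
            {"auc": m.auc, "auc_pr": m.auc_pr, "acc": m.acc, "mcc": m.mcc, "f1": m.f1}
            for m in ensemble.fold_metrics
        ],
        mean_metrics=ensemble.mean_metrics(),
        ablation_selected_depth=None if ablation is None else ablation.selected_depth,
        ablation_removed=[] if ablation is None else ablation.removed_order[: (ablation.selected_depth or 0)],
        retained_features=list(ensemble.retained_features),
        thresholds=thresholds,
        class_counts=class_counts,
        n_scored=len(scores),
        peaks=peaks,
        stage_seconds=timings,
    )
    report.validate()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = provenance_header(config)
        score_df = scores.sort_values(ascending=False).to_frame()
        (out / "scores.tsv").write_text(
            header + score_df.to_csv(sep="\t", float_format="%.12g"), encoding="utf-8"
        )
        if thresholds is not None:
            result = classify_scores(scores, thresholds)
            (out / "classes.tsv").write_text(
                header + result.classes.to_frame().to_csv(sep="\t"), encoding="utf-8"
            )
        report.to_json(out / "report.json")
    return report, scores


def run_synthetic_pipeline(
    spec: SyntheticSpec,
    config: RunConfig,
    ablate: bool = False,
    out_dir: str | Path | None = None,
) -> tuple[PipelineReport, pd.Series, pd.Series]:
    """Generate the synthetic cohort and run the full pipeline on it.

    Returns (report, scores, latent truth) so callers can measure recovery
    of the generator's hidden labels.
    """
    data = generate_feature_table(spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(data.table, out / "features.tsv", config)
    report, scores = run_pipeline(
        data.table, data.labeled_positives, config, ablate=ablate, out_dir=out_dir
    )
    return report, scores, data.truth
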