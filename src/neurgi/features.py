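"""Per-gene feature extraction.

Four feature categories feed the prioritizer:

* expression dynamics — Spearman correlation with the differentiation axis
  (two-sided test), expression range, OLS slope and its p-value, and the
  cell-specificity index Tau;
* physiological — GWAS SNP-count encodings (0 / 1 / 2-capped);
* pathological — binary phenotype membership plus passthrough disease indices
  (DSI, DPI, number of diseases, pLI);
* conservation — base-length-weighted mean phastCons over the gene body.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ConservationTrack,
    ExpressionByGroup,
    GeneFeatureTable,
    GwasAnnotation,
    ValidationError,
)

__all__ = [
    "DynamicsFeatures",
    "dynamics_features",
    "dynamics_frame",
    "tau_specificity",
    "encode_snp_count",
    "encode_binary_phenotype",
    "mean_conservation",
    "assemble_feature_table",
]


@dataclass(frozen=True)
class DynamicsFeatures:
    """Expression-dynamics features for one gene.

    ``range_raw`` is max - min of the profile; ``range_scaled`` divides it by
    the cohort-wide maximum raw range so the column lies in [0, 1].
    """

    spearman_cor: float
    spearman_p: float
    range_raw: float
    range_scaled: float
    slope: float
    fit_p: float


def dynamics_features(
    profile: ExpressionByGroup, max_range: float | None = None
) -> DynamicsFeatures:
    """Correlation, range and linear-trend features of one expression profile.

    Spearman correlation and its two-sided p-value relate expression to the
    ordering variable; slope and fit p-value come from ordinary least squares
    of expression on order. A constant profile has an undefined rank
    correlation and is reported as cor 0, p 1, slope 0.

    ``max_range`` is the cohort-wide maximum raw range used to scale this
    gene's range into [0, 1]; when None the gene's own range is used (so any
    non-flat profile scales to 1).
    """
    y = profile.values
    x = profile.order
    if len(y) < 3:
        raise ValidationError(f"{profile.gene_id}: need >= 3 points for dynamics features")
    if np.unique(x).size < 2:
        raise ValidationError(f"{profile.gene_id}: constant order vector")

    rng_raw = float(np.max(y) - np.min(y))
    if np.all(y == y[0]):
        cor, p, slope, fit_p = 0.0, 1.0, 0.0, 1.0
    else:
        res = stats.spearmanr(y, x, alternative="two-sided")
        cor = float(res.statistic)
        p = float(res.pvalue)
        if not np.isfinite(cor):  # ties collapsing a vector to constant ranks
            cor, p = 0.0, 1.0
        ols = stats.linregress(x, y)
        slope = float(ols.slope)
        fit_p = float(ols.pvalue) if np.isfinite(ols.pvalue) else 1.0

    denom = rng_raw if max_range is None else max_range
    scaled = 0.0 if denom == 0 else rng_raw / denom
    return DynamicsFeatures(
        spearman_cor=cor,
        spearman_p=p,
        range_raw=rng_raw,
        range_scaled=scaled,
        slope=slope,
        fit_p=fit_p,
    )


def dynamics_frame(
    profiles: Sequence[ExpressionByGroup], prefix: str = ""
) -> pd.DataFrame:
    """Dynamics features for a cohort of profiles, range scaled cohort-wide.

    Returns a DataFrame indexed by gene_id with columns
    ``{prefix}spearman_cor``, ``{prefix}spearman_p``, ``{prefix}range``,
    ``{prefix}slope``, ``{prefix}fit_p``.
    """
    raw = [dynamics_features(p) for p in profiles]
    max_range = max((f.range_raw for f in raw), default=0.0)
    rows = {}
    for profile, feat in zip(profiles, raw):
        scaled = 0.0 if max_range == 0 else feat.range_raw / max_range
        rows[profile.gene_id] = {
            f"{prefix}spearman_cor": feat.spearman_cor,
            f"{prefix}spearman_p": feat.spearman_p,
            f"{prefix}range": scaled,
            f"{prefix}slope": feat.slope,
            f"{prefix}fit_p": feat.fit_p,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def tau_specificity(profile: ExpressionByGroup) -> float:
    """Cell-specificity index Tau = sum(1 - x_i) / (N - 1).

    ``x_i`` is expression normalized to the profile maximum over the N groups.
    Tau is 0 for a flat (housekeeping) profile and 1 for a profile expressed
    in exactly one group.
    """
    v = profile.values
    vmax = float(np.max(v))
    if vmax <= 0:
        raise ValidationError(f"{profile.gene_id}: all-zero profile, Tau undefined")
    x = v / vmax
    n = len(v)
    return float(np.sum(1.0 - x) / (n - 1))


def encode_snp_count(annotation: GwasAnnotation, gene_id: str) -> int:
    """SNP-count encoding: 0 for none, 1 for one, 2 for two or more.

    Counts of two and above share the top code; only 0/1/2 are distinguished.
    """
    return min(annotation.snp_count(gene_id), 2)


def encode_binary_phenotype(member_set: Iterable[str], gene_id: str) -> int:
    """1 if the gene belongs to the phenotype gene set, else 0."""
    return int(gene_id in set(member_set))


def _merge_intervals(intervals: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of intervals per chromosome (unstranded aggregation)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: list[tuple[str, int, int]] = []
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def mean_conservation(
    track: ConservationTrack,
    gene_intervals: Sequence[tuple[str, int, int]],
    unscored: str = "zero",
) -> float:
    """Base-length-weighted mean conservation over the gene body.

    Gene intervals are unioned per chromosome first. Each score record
    contributes value x (bases overlapping the gene). Bases of the gene with
    no score record count 0 with full weight under ``unscored="zero"``
    (the phastCons convention that unscored means unaligned), or are dropped
    from the denominator under ``unscored="exclude"``.
    """
    if unscored not in ("zero", "exclude"):
        raise ValueError(f"unscored must be 'zero' or 'exclude', got {unscored!r}")
    if not gene_intervals:
        raise ValidationError("gene has no intervals")
    merged = _merge_intervals(gene_intervals)
    gene_len = sum(e - s for _, s, e in merged)
    if gene_len == 0:
        raise ValidationError("zero-length gene intervals")

    weighted_sum = 0.0
    covered = 0
    for chrom, gs, ge in merged:
        for rchrom, rs, re_, value in track.records:
            if rchrom != chrom:
                continue
            lo, hi = max(gs, rs), min(ge, re_)
            if lo < hi:
                weighted_sum += value * (hi - lo)
                covered += hi - lo
    if unscored == "zero":
        return weighted_sum / gene_len
    if covered == 0:
        raise ValidationError("no scored bases overlap the gene (unscored='exclude')")
    return weighted_sum / covered


def assemble_feature_table(
    parts: Mapping[str, pd.Series],
    gene_universe: Sequence[str],
    categories: Mapping[str, str],
    gene_type: Mapping[str, str] | pd.Series | None = None,
) -> GeneFeatureTable:
    """Outer-join named feature columns over a gene universe.

    Genes absent from a column get NaN (to be handled by imputation).
    A column containing ids outside the universe is an error.
    """
    universe = pd.Index(list(gene_universe), name="gene_id")
    if universe.has_duplicates:
        raise ValidationError("gene_universe contains duplicates")
    cols = {}
    for name, series in parts.items():
        if name not in categories:
            raise ValidationError(f"feature {name!r} missing from category map")
        outside = set(series.index) - set(universe)
        if outside:
            raise ValidationError(
                f"feature {name!r} has gene ids outside the universe: {sorted(outside)[:5]}"
            )
        cols[name] = series.reindex(universe).astype(float)
    features = pd.DataFrame(cols, index=universe)
    if gene_type is None:
        gtype = pd.Series("other", index=universe)
    else:
        gtype = pd.Series(gene_type).reindex(universe).fillna("other").astype(str)
    return GeneFeatureTable(
        features=features,
        gene_type=gtype,
        categories={n: categories[n] for n in features.columns},
    )
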