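"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV (tab-separated, '.' decimal, UTF-8, mandatory header) or
newline-delimited gene lists. Outputs carry a ``#``-prefixed provenance header
embedding the run configuration and seed. BED is 0-based half-open; bedGraph
records carry (chrom, start, end, value).
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .types import (
    ConservationTrack,
    ExpressionByGroup,
    GeneFeatureTable,
    GwasAnnotation,
    ValidationError,
)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "impute_missing",
    "read_gene_list",
    "write_gene_list",
    "read_expression_profiles",
    "read_gwas_annotation",
    "read_bed",
    "read_bedgraph",
    "provenance_header",
]

logger = logging.getLogger("neurgi")

GENE_ID_COL = "gene_id"
GENE_TYPE_COL = "gene_type"
_FLOAT_FMT = "%.12g"  # lossless round trip at 12 significant digits


def provenance_header(config: RunConfig | None = None, **extra: object) -> str:
    """Comment block stamped onto every TSV output."""
    lines = ["# neurgi output"]
    if config is not None:
        for key, value in sorted(config.to_dict().items()):
            lines.append(f"# config.{key} = {value}")
    for key, value in sorted(extra.items()):
        lines.append(f"# {key} = {value}")
    return "\n".join(lines) + "\n"


def read_feature_table(
    path: str | Path, schema: Mapping[str, str]
) -> GeneFeatureTable:
    """Read a gene feature table from TSV.

    The file must have a ``gene_id`` first column, a ``gene_type`` column, and
    one numeric column per feature named in ``schema`` (feature -> category).
    Lines starting with ``#`` are provenance comments and are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.columns[0] != GENE_ID_COL:
        raise ValidationError(f"first column must be {GENE_ID_COL!r}, got {df.columns[0]!r}")
    if GENE_TYPE_COL not in df.columns:
        raise ValidationError(f"missing {GENE_TYPE_COL!r} column")
    if df[GENE_ID_COL].duplicated().any():
        dups = df.loc[df[GENE_ID_COL].duplicated(), GENE_ID_COL].tolist()
        raise ValidationError(f"duplicate gene ids in {path}: {dups[:5]}")
    feature_cols = [c for c in df.columns if c not in (GENE_ID_COL, GENE_TYPE_COL)]
    unknown = set(feature_cols) - set(schema)
    if unknown:
        raise ValidationError(f"features not in schema: {sorted(unknown)}")
    df = df.set_index(GENE_ID_COL)
    return GeneFeatureTable(
        features=df[feature_cols].astype(float),
        gene_type=df[GENE_TYPE_COL].astype(str),
        categories={f: schema[f] for f in feature_cols},
    )


def write_feature_table(
    table: GeneFeatureTable, path: str | Path, config: RunConfig | None = None
) -> None:
    out = table.features.copy()
    out.insert(0, GENE_TYPE_COL, table.gene_type)
    buf = _io.StringIO()
    buf.write(provenance_header(config))
    out.to_csv(buf, sep="\t", float_format=_FLOAT_FMT, index_label=GENE_ID_COL)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


DEFAULT_IMPUTE_POLICY = {
    "expression": "median",
    "physiological": "zero",
    "pathological": "zero",
    "conservation": "median",
}


def impute_missing(
    table: GeneFeatureTable, policy: Mapping[str, str] | None = None
) -> GeneFeatureTable:
    """Fill NaN cells per feature category.

    ``policy`` maps each category to ``"zero"`` or ``"median"`` (column median
    of the observed values). The default zero-fills count/binary encodings,
    where absence from the source annotation means "no association", and
    median-fills continuous columns.
    """
    policy = dict(DEFAULT_IMPUTE_POLICY if policy is None else policy)
    unknown_rules = {v for v in policy.values() if v not in ("zero", "median")}
    if unknown_rules:
        raise ValidationError(f"unknown imputation rules: {sorted(unknown_rules)}")
    unknown_cats = set(policy) - set(table.categories.values()) - {
        "expression", "physiological", "pathological", "conservation"
    }
    if unknown_cats:
        raise ValidationError(f"unknown categories in policy: {sorted(unknown_cats)}")

    features = table.features.copy()
    n_imputed = 0
    for col in features.columns:
        category = table.categories[col]
        if category not in policy:
            raise ValidationError(f"no imputation rule for category {category!r}")
        mask = features[col].isna()
        if not mask.any():
            continue
        if policy[category] == "zero":
            fill = 0.0
        else:
            observed = features.loc[~mask, col]
            if observed.empty:
                raise ValidationError(f"feature {col!r} is all-NaN; median undefined")
            fill = float(observed.median())
        features.loc[mask, col] = fill
        n_imputed += int(mask.sum())
    if n_imputed:
        logger.info("imputed %d missing cells", n_imputed)
    return GeneFeatureTable(
        features=features, gene_type=table.gene_type.copy(), categories=dict(table.categories)
    )


def read_gene_list(path: str | Path) -> list[str]:
    genes: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")


def read_expression_profiles(
    matrix_path: str | Path, order_path: str | Path
) -> list[ExpressionByGroup]:
    """Read a genes x samples TSV plus a sidecar (sample, order) TSV.

    The order file maps each sample/group label to its position on the
    differentiation axis (stage rank or pseudotime).
    """
    mat = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    order_df = pd.read_csv(order_path, sep="\t", comment="#")
    if order_df.shape[1] < 2:
        raise ValidationError("order file needs (sample, order) columns")
    order_map = dict(zip(order_df.iloc[:, 0].astype(str), order_df.iloc[:, 1].astype(float)))
    missing = [c for c in mat.columns if c not in order_map]
    if missing:
        raise ValidationError(f"samples without an order value: {missing[:5]}")
    order = np.array([order_map[c] for c in mat.columns], dtype=float)
    labels = [str(c) for c in mat.columns]
    return [
        ExpressionByGroup(
            gene_id=str(gene), values=row.to_numpy(float), group_labels=labels, order=order
        )
        for gene, row in mat.iterrows()
    ]


def read_gwas_annotation(path: str | Path) -> dict[str, GwasAnnotation]:
    """Read long-format (phenotype, gene_id, snp_id) TSV into per-phenotype maps."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"phenotype", "gene_id", "snp_id"}
    if not required <= set(df.columns):
        raise ValidationError(f"GWAS annotation needs columns {sorted(required)}")
    out: dict[str, GwasAnnotation] = {}
    for phenotype, group in df.groupby("phenotype", sort=True):
        out[str(phenotype)] = GwasAnnotation.from_records(
            str(phenotype), zip(group["gene_id"], group["snp_id"])
        )
    return out


def read_bed(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a BED file (0-based half-open); returns name -> intervals.

    Uses columns chrom, start, end, name; additional columns are ignored.
    """
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValidationError(f"BED line needs >= 4 columns: {line!r}")
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        if start >= end:
            raise ValidationError(f"empty BED interval: {line!r}")
        intervals.setdefault(name, []).append((chrom, start, end))
    return intervals


def read_bedgraph(path: str | Path) -> ConservationTrack:
    records: list[tuple[str, int, int, float]] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end, value = line.split("\t")[:4]
        records.append((chrom, int(start), int(end), float(value)))
    return ConservationTrack(records)
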