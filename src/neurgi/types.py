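"""Domain containers shared across the pipeline.

The central object is :class:`GeneFeatureTable`: a genes x features matrix
with a per-gene functional stratum (enzyme / membrane protein / RBP / TF /
other) and a per-feature category (expression dynamics, physiological,
pathological, conservation). :class:`LabeledSets` tracks the bookkeeping of
the positive-unlabeled labeling stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENE_TYPES",
    "FEATURE_CATEGORIES",
    "GeneFeatureTable",
    "LabeledSets",
    "ExpressionByGroup",
    "GwasAnnotation",
    "ConservationTrack",
]

GENE_TYPES = ("enzyme", "membrane_protein", "rbp", "tf", "other")
FEATURE_CATEGORIES = ("expression", "physiological", "pathological", "conservation")


class ValidationError(ValueError):
    """An input violates a container invariant."""


@dataclass
class GeneFeatureTable:
    """Genes x numeric-features matrix plus gene-type stratum and feature schema.

    Attributes
    ----------
    features
        DataFrame indexed by unique gene_id; all columns numeric (NaN allowed
        before imputation).
    gene_type
        Series indexed like ``features``, values in :data:`GENE_TYPES`.
    categories
        Maps every feature column to one of :data:`FEATURE_CATEGORIES`.
    """

    features: pd.DataFrame
    gene_type: pd.Series
    categories: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.features.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if not self.gene_type.index.equals(idx):
            raise ValidationError("gene_type index does not match feature index")
        bad_types = set(self.gene_type.unique()) - set(GENE_TYPES)
        if bad_types:
            raise ValidationError(f"unknown gene types: {sorted(bad_types)}")
        missing = set(self.features.columns) - set(self.categories)
        if missing:
            raise ValidationError(f"features without a category: {sorted(missing)}")
        extra = set(self.categories) - set(self.features.columns)
        if extra:
            raise ValidationError(f"category entries with no column: {sorted(extra)}")
        bad_cat = {c for c in self.categories.values() if c not in FEATURE_CATEGORIES}
        if bad_cat:
            raise ValidationError(f"unknown categories: {sorted(bad_cat)}")
        non_numeric = [
            c for c in self.features.columns
            if not pd.api.types.is_numeric_dtype(self.features[c])
        ]
        if non_numeric:
            raise ValidationError(f"non-numeric feature columns: {non_numeric}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def n_genes(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def has_nan(self) -> bool:
        return bool(self.features.isna().any().any())

    def subset_genes(self, gene_ids: Sequence[str]) -> "GeneFeatureTable":
        gene_ids = list(gene_ids)
        missing = set(gene_ids) - set(self.features.index)
        if missing:
            raise KeyError(f"gene ids not in table: {sorted(missing)[:5]}")
        return GeneFeatureTable(
            features=self.features.loc[gene_ids].copy(),
            gene_type=self.gene_type.loc[gene_ids].copy(),
            categories=dict(self.categories),
        )

    def subset_features(self, names: Sequence[str]) -> "GeneFeatureTable":
        names = list(names)
        missing = set(names) - set(self.features.columns)
        if missing:
            raise KeyError(f"features not in table: {sorted(missing)}")
        return GeneFeatureTable(
            features=self.features[names].copy(),
            gene_type=self.gene_type.copy(),
            categories={n: self.categories[n] for n in names},
        )

    def matrix(self, gene_ids: Sequence[str] | None = None) -> np.ndarray:
        df = self.features if gene_ids is None else self.features.loc[list(gene_ids)]
        return df.to_numpy(dtype=float)

    def equals(self, other: "GeneFeatureTable", rtol: float = 0.0) -> bool:
        if self.categories != other.categories:
            return False
        if not self.gene_type.equals(other.gene_type):
            return False
        if rtol == 0.0:
            return self.features.equals(other.features)
        a, b = self.features.to_numpy(float), other.features.to_numpy(float)
        if a.shape != b.shape or list(self.features.columns) != list(other.features.columns):
            return False
        return bool(np.allclose(a, b, rtol=rtol, equal_nan=True))


@dataclass(frozen=True)
class LabeledSets:
    """Gene-id bookkeeping for the spy-based positive-unlabeled stage.

    Invariants: spies are a subset of the positives, residual positives are
    the rest, the spy-augmented unlabeled pool is the disjoint union of the
    unlabeled genes and the spies, and reliable negatives come from the
    original unlabeled pool only.
    """

    positives: frozenset[str]
    unlabeled: frozenset[str]
    spies: frozenset[str] = frozenset()
    reliable_negatives: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.positives & self.unlabeled:
            raise ValidationError("positives and unlabeled overlap")
        if not self.spies <= self.positives:
            raise ValidationError("spies must be a subset of positives")
        if not self.reliable_negatives <= self.unlabeled:
            raise ValidationError("reliable negatives must come from the unlabeled set")

    @property
    def residual_positives(self) -> frozenset[str]:
        """P \\ spies (the Ps set)."""
        return self.positives - self.spies

    @property
    def spy_augmented_unlabeled(self) -> frozenset[str]:
        """U + spies (the Us set)."""
        return self.unlabeled | self.spies

    def sizes(self) -> dict[str, int]:
        return {
            "P": len(self.positives),
            "U": len(self.unlabeled),
            "spies": len(self.spies),
            "Ps": len(self.residual_positives),
            "Us": len(self.spy_augmented_unlabeled),
            "RN": len(self.reliable_negatives),
        }


@dataclass
class ExpressionByGroup:
    """One gene's expression across ordered groups (stages or pseudotime bins).

    ``order`` is the regression axis: consecutive stage ranks starting at 1,
    or an externally computed pseudotime.
    """

    gene_id: str
    values: np.ndarray
    group_labels: list[str]
    order: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.order = np.asarray(self.order, dtype=float)
        n = len(self.values)
        if n < 2:
            raise ValidationError(f"{self.gene_id}: need >= 2 observations, got {n}")
        if len(self.group_labels) != n or len(self.order) != n:
            raise ValidationError(f"{self.gene_id}: values/labels/order length mismatch")
        if np.any(self.values < 0):
            raise ValidationError(f"{self.gene_id}: negative expression values")

    @property
    def n_groups(self) -> int:
        return len(self.values)


@dataclass
class GwasAnnotation:
    """Per-gene SNP lists for one physiological phenotype."""

    phenotype: str
    snps_by_gene: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, phenotype: str, records: Iterable[tuple[str, str]]
    ) -> "GwasAnnotation":
        """Build from (gene_id, snp_id) pairs; duplicate SNPs per gene collapse."""
        by_gene: dict[str, set[str]] = {}
        for gene_id, snp_id in records:
            by_gene.setdefault(gene_id, set()).add(snp_id)
        return cls(phenotype, {g: frozenset(s) for g, s in by_gene.items()})

    def snp_count(self, gene_id: str) -> int:
        return len(self.snps_by_gene.get(gene_id, ()))


@dataclass
class ConservationTrack:
    """Per-base conservation scores as bedGraph-style records.

    Records are (chrom, start, end, value) with 0-based half-open intervals
    and values in [0, 1] (phastCons-style probabilities).
    """

    records: list[tuple[str, int, int, float]]

    def __post_init__(self) -> None:
        for chrom, start, end, value in self.records:
            if start >= end:
                raise ValidationError(f"empty interval {chrom}:{start}-{end}")
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"score {value} outside [0, 1] at {chrom}:{start}")
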