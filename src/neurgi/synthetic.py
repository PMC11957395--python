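"""Synthetic data with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs end to end:

* :func:`generate_feature_table` — a gene feature table whose positive class
  is mean-shifted by a configurable effect size (in SDs) on the signal
  features, with count-encoded and binary columns drawn with class-dependent
  odds, a configurable number of pure-noise features, and gene types enriched
  for regulatory classes among positives;
* :func:`generate_trajectory` — expression profiles along an ordered axis
  with known dynamics (up / down / flat / group-specific);
* :func:`generate_scores` — a 3-component Gaussian mixture on [0, 1]
  emulating the bimodal score distribution the classifier stage consumes.

Every generator is a pure function of its spec and seed. The defaults are
the package's study conditions, not claims about any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionByGroup, GeneFeatureTable

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_feature_table",
    "generate_trajectory",
    "generate_scores",
]

DEFAULT_CATEGORY_SIZES = {
    "expression": 16,
    "physiological": 6,
    "pathological": 5,
    "conservation": 1,
}

# gene-type frequencies; positives enriched for regulatory classes
_POS_TYPE_P = {"enzyme": 0.25, "membrane_protein": 0.15, "rbp": 0.08, "tf": 0.12, "other": 0.40}
_NEG_TYPE_P = {"enzyme": 0.12, "membrane_protein": 0.07, "rbp": 0.04, "tf": 0.05, "other": 0.72}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic cohort.

    The labeled positive set has ``n_positive`` genes (latent truth positive).
    The unlabeled pool holds ``n_latent_negative`` latent negatives plus
    ``n_unlabeled`` hidden latent positives, so PU-learning stages see a
    mixed pool. ``effect_size`` shifts the positive-class mean of every
    signal feature by that many SDs; the last ``noise_features`` feature
    columns carry no class signal at all.
    """

    n_positive: int = 300
    n_latent_negative: int = 300
    n_unlabeled: int = 0
    category_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SIZES)
    )
    effect_size: float = 2.0
    noise_features: int = 7
    bimodal_score_params: tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...]] = (
        (0.02, 0.5, 0.97),   # means
        (0.01, 0.15, 0.01),  # SDs
        (0.25, 0.50, 0.25),  # weights
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_positive, self.n_latent_negative) <= 0:
            raise ValueError("n_positive and n_latent_negative must be positive")
        if self.n_unlabeled < 0 or self.effect_size < 0 or self.noise_features < 0:
            raise ValueError("n_unlabeled, effect_size, noise_features must be >= 0")
        _, _, weights = self.bimodal_score_params
        if not np.isclose(sum(weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if self.noise_features > sum(self.category_sizes.values()):
            raise ValueError("more noise features than features")

    @property
    def n_features(self) -> int:
        return sum(self.category_sizes.values())

    @property
    def n_genes(self) -> int:
        return self.n_positive + self.n_latent_negative + self.n_unlabeled


@dataclass
class SyntheticDataset:
    table: GeneFeatureTable
    truth: pd.Series                 # latent label: 1 positive, 0 negative
    labeled_positives: frozenset[str]
    noise_feature_names: list[str]


def _feature_plan(spec: SyntheticSpec) -> list[tuple[str, str, str]]:
    """(name, category, kind) per feature; kind in continuous/count/binary.

    Physiological columns are 0/1/2 count encodings (GWAS SNP counts); the
    first pathological column is a binary phenotype membership; everything
    else is continuous.
    """
    plan: list[tuple[str, str, str]] = []
    for category in ("expression", "physiological", "pathological", "conservation"):
        for i in range(spec.category_sizes.get(category, 0)):
            name = f"{category[:4]}_{i + 1:02d}"
            if category == "physiological":
                kind = "count"
            elif category == "pathological" and i == 0:
                kind = "binary"
            else:
                kind = "continuous"
            plan.append((name, category, kind))
    return plan


def _count_probs(effect: float) -> tuple[np.ndarray, np.ndarray]:
    # tilt scaled so a count feature discriminates comparably to a
    # continuous feature shifted by `effect` SDs
    base = np.array([0.70, 0.20, 0.10])
    tilted = base * np.exp(effect * np.arange(3))
    return base, tilted / tilted.sum()


def _binary_probs(effect: float) -> tuple[float, float]:
    base = 0.10
    logit = np.log(base / (1 - base)) + 2.0 * effect
    return base, float(1 / (1 + np.exp(-logit)))


def generate_feature_table(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw the synthetic gene feature table and its latent truth labels."""
    rng = np.random.default_rng(spec.seed)
    plan = _feature_plan(spec)
    noise_names = [name for name, _, _ in plan[len(plan) - spec.noise_features:]] if spec.noise_features else []
    noise_set = set(noise_names)

    n = spec.n_genes
    truth = np.r_[
        np.ones(spec.n_positive, dtype=int),
        np.zeros(spec.n_latent_negative, dtype=int),
        np.ones(spec.n_unlabeled, dtype=int),
    ]
    gene_ids = [f"g{i + 1:06d}" for i in range(n)]

    cols: dict[str, np.ndarray] = {}
    count_base, count_pos = _count_probs(spec.effect_size)
    bin_base, bin_pos = _binary_probs(spec.effect_size)
    for name, _category, kind in plan:
        signal = name not in noise_set
        if kind == "continuous":
            shift = spec.effect_size if signal else 0.0
            cols[name] = rng.normal(loc=shift * truth, scale=1.0)
        elif kind == "count":
            draws = np.empty(n)
            for cls, probs in ((0, count_base), (1, count_pos if signal else count_base)):
                mask = truth == cls
                draws[mask] = rng.choice(3, size=mask.sum(), p=probs)
            cols[name] = draws
        else:  # binary
            p = np.where(truth == 1, bin_pos if signal else bin_base, bin_base)
            cols[name] = (rng.random(n) < p).astype(float)

    types = np.array(sorted(_POS_TYPE_P))
    pos_p = np.array([_POS_TYPE_P[t] for t in types])
    neg_p = np.array([_NEG_TYPE_P[t] for t in types])
    gene_type = np.where(
        truth == 1,
        rng.choice(types, size=n, p=pos_p / pos_p.sum()),
        rng.choice(types, size=n, p=neg_p / neg_p.sum()),
    )

    idx = pd.Index(gene_ids, name="gene_id")
    table = GeneFeatureTable(
        features=pd.DataFrame(cols, index=idx),
        gene_type=pd.Series(gene_type, index=idx),
        categories={name: category for name, category, _ in plan},
    )
    return SyntheticDataset(
        table=table,
        truth=pd.Series(truth, index=idx, name="truth"),
        labeled_positives=frozenset(gene_ids[: spec.n_positive]),
        noise_feature_names=noise_names,
    )


def generate_trajectory(
    n_genes: int,
    n_points: int,
    dynamics_mix: dict[str, float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> list[tuple[ExpressionByGroup, str]]:
    """Expression profiles with known dynamics along a 1..N stage axis.

    ``dynamics_mix`` gives the proportions of up / down / flat /
    group-specific genes (default equal quarters). Returns (profile, tag)
    pairs; the tag is the generating dynamic.
    """
    if n_points < 4:
        raise ValueError("need >= 4 points per trajectory")
    mix = dynamics_mix or {"up": 0.25, "down": 0.25, "flat": 0.25, "specific": 0.25}
    if not np.isclose(sum(mix.values()), 1.0):
        raise ValueError("dynamics_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    tags = rng.choice(list(mix), size=n_genes, p=np.array(list(mix.values())))
    order = np.arange(1, n_points + 1, dtype=float)
    labels = [f"stage_{i}" for i in range(1, n_points + 1)]
    ramp = np.linspace(0.0, 1.0, n_points)

    out: list[tuple[ExpressionByGroup, str]] = []
    for i, tag in enumerate(tags):
        if tag == "up":
            base = 0.5 + ramp
        elif tag == "down":
            base = 1.5 - ramp
        elif tag == "flat":
            base = np.ones(n_points)
        else:  # specific: one dominant group
            base = np.full(n_points, 0.02)
            base[rng.integers(n_points)] = 1.0
        values = np.clip(base + rng.normal(0.0, noise_sd, n_points), 0.0, None)
        out.append(
            (
                ExpressionByGroup(
                    gene_id=f"traj{i + 1:05d}",
                    values=values,
                    group_labels=labels,
                    order=order,
                ),
                str(tag),
            )
        )
    return out


def generate_scores(
    params: tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...]],
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw scores from a Gaussian mixture truncated to [0, 1].

    ``params`` is (means, SDs, weights). Out-of-range draws are rejected and
    redrawn so each component keeps its shape inside the unit interval.
    Returns (scores, component_index).
    """
    means, sds, weights = (np.asarray(p, dtype=float) for p in params)
    if not (len(means) == len(sds) == len(weights)):
        raise ValueError("means, SDs and weights must have equal length")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0), np.empty(0, dtype=int)
    comp = rng.choice(len(means), size=n, p=weights / weights.sum())
    scores = rng.normal(means[comp], sds[comp])
    bad = (scores < 0) | (scores > 1)
    while bad.any():
        scores[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = (scores < 0) | (scores > 1)
    return scores, comp
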