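"""Positive-unlabeled labeling via the Spy technique.

A random fraction of the known positives ("spies") is hidden inside the
unlabeled pool. A Gaussian Naive Bayes classifier is trained to separate the
residual positives (oversampled to match the pool size) from the spy-augmented
unlabeled pool; the posterior-positive probabilities of the spies then
calibrate a threshold — unlabeled genes scoring strictly below the chosen spy
quantile become reliable negatives (RN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, child_seed
from .types import GeneFeatureTable, LabeledSets, ValidationError

__all__ = [
    "NaiveBayesModel",
    "split_spies",
    "oversample",
    "fit_naive_bayes",
    "reliable_negatives",
    "label_reliable_negatives",
    "SpyLabelResult",
]

logger = logging.getLogger("neurgi")

_VAR_EPS = 1e-9  # variance floor as a fraction of the pooled feature variance


def split_spies(
    positives: set[str] | frozenset[str],
    fraction: float,
    seed: int,
    mode: str = "bernoulli",
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition the positives into (residual_positives, spies).

    ``mode="bernoulli"`` marks each positive a spy independently with
    probability ``fraction`` (a draw leaving either side empty is resampled
    with the next child seed). ``mode="exact"`` selects exactly
    ``round(fraction * |P|)`` spies (at least 1) without replacement.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    ids = np.array(sorted(positives))
    if len(ids) < 2:
        raise ValidationError("need >= 2 positives to split off spies")
    if mode == "exact":
        rng = np.random.default_rng(seed)
        n_spies = min(max(int(round(fraction * len(ids))), 1), len(ids) - 1)
        spies = rng.choice(ids, size=n_spies, replace=False)
        spy_set = frozenset(spies.tolist())
        return frozenset(ids) - spy_set, spy_set
    if mode != "bernoulli":
        raise ValueError(f"unknown mode {mode!r}")
    for attempt in range(1000):
        rng = np.random.default_rng(child_seed(seed, "spy_split", attempt))
        mask = rng.random(len(ids)) < fraction
        if 0 < mask.sum() < len(ids):
            if attempt:
                logger.info("spy split resampled %d time(s) (degenerate draw)", attempt)
            spy_set = frozenset(ids[mask].tolist())
            return frozenset(ids) - spy_set, spy_set
    raise RuntimeError("spy split repeatedly degenerate")  # pragma: no cover


def oversample(minority: set[str] | frozenset[str], target_size: int, seed: int) -> list[str]:
    """Sample gene ids with replacement up to ``target_size`` (a multiset)."""
    ids = sorted(minority)
    if not ids:
        raise ValidationError("cannot oversample an empty set")
    if target_size < len(ids):
        raise ValueError(f"target_size {target_size} < |minority| {len(ids)}")
    rng = np.random.default_rng(seed)
    return rng.choice(np.array(ids), size=target_size, replace=True).tolist()


@dataclass(frozen=True)
class NaiveBayesModel:
    """Gaussian Naive Bayes with per-feature per-class means and variances.

    Variances are floored at ``eps x pooled variance`` so a constant feature
    cannot produce a degenerate likelihood. Class 1 is the positive class.
    """

    means: np.ndarray       # (2, n_features): row 0 negative, row 1 positive
    variances: np.ndarray   # (2, n_features), strictly positive
    priors: np.ndarray      # (2,), in (0, 1), sums to 1

    def __post_init__(self) -> None:
        if np.any(self.variances <= 0):
            raise ValidationError("variances must be positive")
        if not np.isclose(self.priors.sum(), 1.0) or np.any(self.priors <= 0):
            raise ValidationError("priors must be positive and sum to 1")

    def _joint_log_likelihood(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        jll = np.empty((x.shape[0], 2))
        for k in range(2):
            log_pdf = -0.5 * (
                np.log(2 * np.pi * self.variances[k])
                + (x - self.means[k]) ** 2 / self.variances[k]
            )
            jll[:, k] = np.log(self.priors[k]) + log_pdf.sum(axis=1)
        return jll

    def posterior_positive(self, x: np.ndarray) -> np.ndarray:
        """P(class = positive | x) for each row of x."""
        jll = self._joint_log_likelihood(x)
        jll -= jll.max(axis=1, keepdims=True)
        lik = np.exp(jll)
        return lik[:, 1] / lik.sum(axis=1)


def fit_naive_bayes(pos_rows: np.ndarray, neg_rows: np.ndarray) -> NaiveBayesModel:
    """Fit Gaussian per-feature class-conditionals with priors from class sizes."""
    pos = np.atleast_2d(np.asarray(pos_rows, dtype=float))
    neg = np.atleast_2d(np.asarray(neg_rows, dtype=float))
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValidationError("need >= 2 rows per class")
    if np.isnan(pos).any() or np.isnan(neg).any():
        raise ValidationError("NaN in training rows; impute first")
    pooled = np.vstack([pos, neg])
    # absolute lower bound keeps an all-constant table numerically sane
    floor = max(_VAR_EPS * float(pooled.var(axis=0).max()), 1e-12)
    means = np.vstack([neg.mean(axis=0), pos.mean(axis=0)])
    variances = np.vstack([neg.var(axis=0), pos.var(axis=0)])
    variances = np.maximum(variances, floor)
    n_pos, n_neg = pos.shape[0], neg.shape[0]
    priors = np.array([n_neg, n_pos], dtype=float) / (n_pos + n_neg)
    return NaiveBayesModel(means=means, variances=variances, priors=priors)


def reliable_negatives(
    model: NaiveBayesModel,
    unlabeled_rows: pd.DataFrame,
    spy_rows: np.ndarray,
    quantile: float,
) -> tuple[frozenset[str], float]:
    """Unlabeled genes whose posterior-positive falls strictly below the spy quantile.

    The threshold is the linear-interpolation quantile of the spies'
    posterior-positive probabilities; ties at the threshold are NOT reliable
    negatives (strict inequality).
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    spy_post = model.posterior_positive(np.asarray(spy_rows, dtype=float))
    if spy_post.size == 0:
        raise ValidationError("no spy rows")
    threshold = float(np.quantile(spy_post, quantile, method="linear"))
    if np.all(spy_post == spy_post[0]):
        logger.warning("all spies share posterior %.6g; RN set may be empty", spy_post[0])
    u_post = model.posterior_positive(unlabeled_rows.to_numpy(dtype=float))
    rn = frozenset(unlabeled_rows.index[u_post < threshold].tolist())
    return rn, threshold


@dataclass(frozen=True)
class SpyLabelResult:
    sets: LabeledSets
    threshold: float
    spy_posteriors: pd.Series
    unlabeled_posteriors: pd.Series


def label_reliable_negatives(
    table: GeneFeatureTable,
    positives: set[str] | frozenset[str],
    config: RunConfig,
    mode: str = "bernoulli",
) -> SpyLabelResult:
    """Run the full spy stage on a feature table.

    Splits spies off the positives, oversamples the residual positives to the
    size of the spy-augmented unlabeled pool, fits the Naive Bayes model and
    mines reliable negatives from the original unlabeled genes.
    """
    if table.has_nan():
        raise ValidationError("feature table has NaN; impute first")
    positives = frozenset(positives)
    missing = positives - set(table.gene_ids)
    if missing:
        raise ValidationError(f"positives absent from table: {sorted(missing)[:5]}")
    unlabeled = frozenset(table.gene_ids) - positives

    residual, spies = split_spies(
        positives, config.spy_fraction, config.stage_seed("spy_split"), mode=mode
    )
    us = sorted(unlabeled | spies)
    ps_multiset = oversample(residual, len(us), config.stage_seed("oversample"))

    pos_rows = table.features.loc[ps_multiset].to_numpy(dtype=float)
    neg_rows = table.features.loc[us].to_numpy(dtype=float)
    model = fit_naive_bayes(pos_rows, neg_rows)

    spy_ids = sorted(spies)
    u_ids = sorted(unlabeled)
    spy_frame = table.features.loc[spy_ids]
    u_frame = table.features.loc[u_ids]
    rn, threshold = reliable_negatives(
        model, u_frame, spy_frame.to_numpy(dtype=float), config.rn_quantile
    )
    sets = LabeledSets(
        positives=positives, unlabeled=unlabeled, spies=spies, reliable_negatives=rn
    )
    logger.info(
        "spy labeling: %s, threshold %.6g", sets.sizes(), threshold
    )
    return SpyLabelResult(
        sets=sets,
        threshold=threshold,
        spy_posteriors=pd.Series(model.posterior_positive(spy_frame.to_numpy(float)), index=spy_ids),
        unlabeled_posteriors=pd.Series(model.posterior_positive(u_frame.to_numpy(float)), index=u_ids),
    )
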