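"""Score classification: kernel-density peak diagnostics, a 3-component
univariate Gaussian mixture fitted by EM, and PDF-intersection thresholds
splitting genes into functional / uncertain / non-functional classes.

The mixture p(x) = sum_k pi_k N(x | mu_k, sigma_k^2) is fitted with unequal
variances (one free variance per component). The class boundaries are the
points where adjacent weighted component densities cross: t_low between the
low- and middle-mean components, t_high between the middle- and high-mean
components. Genes score > t_high -> functional, < t_low -> non-functional,
everything else (including exact ties) -> uncertain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.cluster import KMeans

from .config import child_seed

__all__ = [
    "DegeneracyError",
    "GmmModel",
    "ClassificationResult",
    "find_score_peaks",
    "fit_gmm",
    "derive_thresholds",
    "classify_scores",
]

logger = logging.getLogger("neurgi")

CLASSES = ("non_functional", "uncertain", "functional")
_CLIP = 1e-6          # scores clipped into [eps, 1-eps] before EM
_VAR_FLOOR = 1e-10


class DegeneracyError(RuntimeError):
    """The mixture or its thresholds are numerically degenerate."""


def _normal_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2 * np.pi * var)


@dataclass
class GmmModel:
    """Univariate Gaussian mixture, components sorted by mean ascending."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihoods: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights <= 0) or np.any(self.variances <= 0):
            raise ValueError("weights and variances must be positive")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("components must be sorted by mean")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def component_pdf(self, x: np.ndarray, k: int) -> np.ndarray:
        """Weighted density pi_k N(x | mu_k, sigma_k^2)."""
        return self.weights[k] * _normal_pdf(np.asarray(x, dtype=float), self.means[k], self.variances[k])

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(self.component_pdf(x, k) for k in range(self.n_components))

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        comps = np.column_stack(
            [self.component_pdf(x, k) for k in range(self.n_components)]
        )
        total = comps.sum(axis=1, keepdims=True)
        total[total == 0] = np.finfo(float).tiny
        return comps / total


def find_score_peaks(
    scores: np.ndarray, bandwidth: float = 0.02, grid_size: int = 512
) -> np.ndarray:
    """Modes of a Gaussian-kernel density estimate of the scores on [0, 1].

    A grid point is a peak when the first difference of the density changes
    sign from + to -. Grid endpoints can only be peaks if the density falls
    away from them.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 10:
        raise ValueError("need >= 10 scores for peak diagnostics")
    if np.all(s == s[0]):
        raise DegeneracyError("all scores identical; density is a spike")
    grid = np.linspace(0.0, 1.0, grid_size)
    # explicit KDE: mean of Gaussian kernels of width `bandwidth`
    z = (grid[:, None] - s[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).mean(axis=1) / (bandwidth * np.sqrt(2 * np.pi))
    d = np.diff(density)
    rising = np.r_[True, d > 0]
    falling = np.r_[d < 0, True]
    return grid[rising & falling]


def _em_once(
    s: np.ndarray, components: int, seed: int, tol: float, max_iter: int
) -> GmmModel:
    n = s.size
    km = KMeans(n_clusters=components, n_init=3, random_state=seed)
    assign = km.fit_predict(s.reshape(-1, 1))
    weights = np.array([(assign == k).mean() for k in range(components)])
    means = np.array([s[assign == k].mean() if (assign == k).any() else s.mean()
                      for k in range(components)])
    variances = np.array([
        s[assign == k].var() if (assign == k).sum() > 1 else s.var()
        for k in range(components)
    ])
    weights = np.maximum(weights, 1.0 / n)
    weights /= weights.sum()
    variances = np.maximum(variances, _VAR_FLOOR)

    lls: list[float] = []
    for _ in range(max_iter):
        comps = np.column_stack(
            [w * _normal_pdf(s, m, v) for w, m, v in zip(weights, means, variances)]
        )
        total = comps.sum(axis=1)
        total = np.maximum(total, np.finfo(float).tiny)
        ll = float(np.log(total).sum())
        lls.append(ll)
        if len(lls) > 1 and lls[-1] - lls[-2] < tol:
            break
        resp = comps / total[:, None]
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            raise DegeneracyError("a component lost all responsibility")
        weights = nk / n
        means = (resp * s[:, None]).sum(axis=0) / nk
        variances = (resp * (s[:, None] - means) ** 2).sum(axis=0) / nk
        if np.any(variances < _VAR_FLOOR):
            raise DegeneracyError("component variance collapsed")
    order = np.argsort(means)
    return GmmModel(
        weights=weights[order], means=means[order], variances=variances[order],
        log_likelihoods=lls,
    )


def fit_gmm(
    scores: np.ndarray,
    components: int = 3,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GmmModel:
    """Fit the score mixture by EM with k-means initialization and restarts.

    Runs ``n_init`` independent initializations (child seeds derived from
    ``seed``) and returns the best-likelihood fit, components sorted by mean.
    A collapsed run (vanishing variance or empty component) is discarded and
    replaced by the next child seed; persistent failure raises
    :class:`DegeneracyError`.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 10 * components:
        raise ValueError(f"need >= {10 * components} scores for {components} components")
    s = np.clip(s, _CLIP, 1.0 - _CLIP)

    best: GmmModel | None = None
    successes = 0
    attempt = 0
    while successes < n_init and attempt < n_init * 10:
        try:
            model = _em_once(s, components, child_seed(seed, "gmm", attempt), tol, max_iter)
        except DegeneracyError:
            attempt += 1
            continue
        if best is None or model.log_likelihoods[-1] > best.log_likelihoods[-1]:
            best = model
        successes += 1
        attempt += 1
    if best is None:
        raise DegeneracyError("EM failed to converge from any initialization")
    return best


def derive_thresholds(
    model: GmmModel, tol: float = 1e-10, min_separation: float = 1e-3
) -> tuple[float, float]:
    """Crossings of adjacent weighted component densities.

    t_low is the root of pi_1 N_1 - pi_2 N_2 in (mu_1, mu_2); t_high the root
    of pi_2 N_2 - pi_3 N_3 in (mu_2, mu_3). Raises :class:`DegeneracyError`
    when components overlap so much that no sign change exists in the bracket.
    """
    if model.n_components != 3:
        raise ValueError("thresholds are defined for a 3-component mixture")
    mu = model.means
    if np.any(np.diff(mu) <= min_separation):
        raise DegeneracyError(f"component means too close: {mu}")

    def crossing(lo_k: int, hi_k: int) -> float:
        f = lambda x: model.component_pdf(np.array([x]), lo_k)[0] - model.component_pdf(
            np.array([x]), hi_k
        )[0]
        a, b = mu[lo_k], mu[hi_k]
        fa, fb = f(a), f(b)
        if fa <= 0 or fb >= 0:
            raise DegeneracyError(
                f"no density crossing between components {lo_k} and {hi_k}"
            )
        return float(brentq(f, a, b, xtol=tol))

    t_low = crossing(0, 1)
    t_high = crossing(1, 2)
    if not t_low < t_high:
        raise DegeneracyError(f"thresholds out of order: {t_low} >= {t_high}")
    return t_low, t_high


@dataclass
class ClassificationResult:
    t_low: float
    t_high: float
    classes: pd.Series  # per-gene class label

    def counts(self) -> dict[str, int]:
        vc = self.classes.value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}


def classify_scores(
    scores: pd.Series, thresholds: tuple[float, float]
) -> ClassificationResult:
    """Assign functional / uncertain / non-functional by strict comparisons.

    Scores strictly above t_high are functional, strictly below t_low are
    non-functional; everything else — including exact ties at either
    threshold — is uncertain.
    """
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError(f"t_low must be < t_high, got {thresholds}")
    s = scores.astype(float)
    labels = pd.Series("uncertain", index=s.index, name="class")
    labels[s > t_high] = "functional"
    labels[s < t_low] = "non_functional"
    return ClassificationResult(t_low=float(t_low), t_high=float(t_high), classes=labels)
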