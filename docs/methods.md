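# Methods

`neurgi` prioritizes genes for a functional role in a differentiation
process — the motivating system is neutrophil differentiation from
hematopoietic stem cells — starting from a per-gene feature table and a small
list of known functional genes. No labeled negatives exist in this setting,
so the pipeline combines positive-unlabeled (PU) learning with a
cross-validated random-forest ensemble and an unsupervised mixture model over
the resulting scores.

## The model

### Features

Each gene carries numeric features in four categories:

* **Expression dynamics** along an ordered differentiation axis (stage ranks
  1..N for sorted populations, or an externally computed pseudotime):
  Spearman correlation and its two-sided p-value, expression range
  (max − min, scaled cohort-wide into [0, 1] by the maximum raw range), the
  ordinary-least-squares slope of expression on the axis with its p-value,
  and the specificity index Tau = Σᵢ(1 − xᵢ)/(N − 1), where xᵢ is expression
  normalized to the profile maximum. Tau is 0 for a flat (housekeeping)
  profile, 1 for expression confined to a single group, and is invariant to
  positive rescaling.
* **Physiological**: GWAS SNP counts per phenotype encoded 0 / 1 / 2, where
  2 codes "two or more" (the minimal monotone extension of the 0/1/2 scheme).
* **Pathological**: binary phenotype-set membership plus passthrough disease
  indices (DSI, DPI, disease count, pLI). These arrive precomputed; the
  package never queries the source databases.
* **Conservation**: the base-length-weighted mean of per-base conservation
  scores (phastCons-style, values in [0, 1]) over the union of the gene's
  intervals. Bases without a score count 0 with full weight by default
  (unscored = unaligned); an `exclude` mode drops them from the denominator
  instead. Overlapping score records contribute additively, which makes the
  interval arithmetic exactly equal to a per-base expansion of the same
  records.

Missing cells are imputed per category: zero for count/binary encodings
(absence from an annotation source means "no association") and the column
median for continuous features. The policy is configurable and the imputed
cell count is logged.

### PU labeling (spy technique)

A fraction (default 10%) of the positives is hidden among the unlabeled
genes ("spies") — per-gene Bernoulli draws by default, matching a
probabilistic sampling of the positive list, with an exact-count mode
available. The residual positives are oversampled with replacement to the
size of the spy-augmented unlabeled pool, and a Gaussian Naive Bayes
classifier is fitted with the oversampled positives against that pool.
Per-feature class-conditional variances are floored at 10⁻⁹ times the
largest pooled feature variance (with an absolute floor of 10⁻¹²) so constant
columns cannot produce degenerate likelihoods.

The spies' posterior-positive probabilities calibrate the cutoff: the
threshold is their `rn_quantile` (default 0.10) linear-interpolation
quantile, and unlabeled genes strictly below it become reliable negatives
(RN). Ties at the threshold are not reliable negatives. The quantile
convention matters for the RN boundary and is fixed to linear interpolation
between order statistics.

**What the spy threshold can and cannot do.** Spies are exchangeable with any
hidden positives in the unlabeled pool: both are draws from the same
posterior distribution. The expected fraction of hidden positives falling
below the spies' empirical 10% quantile is therefore ≈ 10–13% (slightly
above the nominal quantile for small spy counts, because the interpolated
order statistic k/(m+1) sits above q), *independently of how well the
classes separate*. RN purity is consequently governed by the latent-positive
fraction α of the unlabeled pool: purity ≈ (1−α)/((1−α) + 0.13·α). At
α = 0.25 — the fraction we adopt for the PU benchmark, anchored to the
study's observed functional fraction among scored genes (4,786 / 19,288) —
expected purity is ≈ 96–97%; at α = 0.5 it cannot exceed ≈ 89%. No spy-based
threshold escapes this bound.

### Balanced training and scoring

Reliable negatives are under-sampled without replacement to match the
positive set exactly, stratified by gene type (enzyme, membrane protein,
RBP, TF, other) so each stratum's negative count equals its positive count;
a stratum short of negatives is topped up from the `other` stratum and the
residual pool, with a logged warning. Stratified k-fold cross-validation
(default k = 10) fits one random forest per fold — Gini criterion,
`n_trees` = 1000 trees, `m_try` = 6 candidate features per split — and
evaluates it on the held-out fold with AUC, AUC-PR, accuracy, MCC and F1.
Genes outside the balanced training set are scored by the arithmetic mean of
the k forests' positive-vote fractions, a value in [0, 1]; training genes are
summarized by their out-of-fold scores.

### Importance and ablation

Node impurity is G(t) = 1 − Σ pᵢ² and a split's decrease is
ΔG = G(t) − (n_L/n)G(t_L) − (n_R/n)G(t_R); both are exposed as standalone
pure functions and re-derived from each fitted tree's split records so the
accounting is auditable against the library's stored impurities. A feature's
mean decrease Gini sums its node-fraction-weighted ΔG over all splits and
trees, divided by the number of trees. The divisor is deliberately a
constant: dividing by a feature's own split count makes a rarely-chosen
noise feature with one lucky split outrank a heavily-used signal feature,
inverting the ranking (we verified this empirically before fixing the
convention).

Ablation ranks features ascending by baseline relative importance, removes
the bottom feature one depth at a time, retrains, and records the five
metrics and their unweighted mean; the depth maximizing that mean is
selected, with exact ties broken toward fewer retained features. Iteration
stops when a removal would leave fewer than `m_try` features. An optional
re-ranking mode recomputes the order after each removal.

On the synthetic benchmark, injected noise features rank at the bottom and
are eliminated first in every seeded run. Because the signal features are
mutually redundant at effect size 2, the metric trace plateaus once the
noise is gone, and the argmax legitimately drifts deeper into redundant
signal features at no metric cost — backward elimination identifies *useless*
features reliably, but the stopping depth on redundant panels is
noise-driven. The benchmark assertions therefore target the removal *order*
and the noise-coverage of the selected depth, not an exact stopping point.

### Mixture classification

Scores of all non-training genes are clipped to [10⁻⁶, 1 − 10⁻⁶] and fitted
with a 3-component univariate Gaussian mixture, unequal variances, by EM:
k-means initialization, 5 restarts with derived child seeds, convergence at
log-likelihood gain < 10⁻⁸ or 500 iterations, best-likelihood fit kept,
components sorted by mean. The EM implementation is our own (the
log-likelihood trace is exposed to assert monotonicity); scikit-learn's
`GaussianMixture` serves as an independent cross-check in the tests. A
kernel-density peak diagnostic (Gaussian kernel, bandwidth 0.02, 512-point
grid on [0, 1]) reports the modes of the score distribution.

Class thresholds are the crossings of adjacent weighted component densities:
t_low is the root of π₁N₁ − π₂N₂ in (μ₁, μ₂) and t_high the root of
π₂N₂ − π₃N₃ in (μ₂, μ₃), found by bracketed root-finding to 10⁻¹⁰. For
well-separated fits these coincide with the posterior-dominance crossover
points (asserted in tests). Genes strictly above t_high are `functional`,
strictly below t_low `non_functional`, everything else — including exact
threshold ties — `uncertain`. Components whose means nearly coincide, or a
bracket without a sign change (one component dominated everywhere), raise a
degeneracy error rather than returning arbitrary cutoffs.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
any real dataset:

* a feature table whose positive class is shifted by `effect_size` SDs on
  continuous signal features, with count features tilted by exp(effect ×
  level) and binary features by +2×effect logits so every feature kind
  discriminates comparably; the last `noise_features` columns carry no class
  signal; gene types are drawn with regulatory enrichment among positives;
* expression trajectories with known dynamics (up / down / flat /
  group-specific) on a 1..N stage axis;
* scores from a 3-component Gaussian mixture truncated to [0, 1] by
  rejection.

Defaults are the package's study conditions: 300 positives vs 300 latent
negatives, 28 features (16 expression, 6 physiological, 5 pathological,
1 conservation) with 7 noise columns, effect size 2. The PU benchmark adds a
hidden latent-positive fraction of 0.25 to the unlabeled pool (see above).
Every generator is a pure function of (spec, seed).

What the generator does **not** emulate: correlated features, heavy-tailed
expression, batch structure, label noise in the positive list, or realistic
single-cell count distributions. Passing benchmarks therefore demonstrate
the pipeline's mechanics and its behavior under clean class structure, not
performance on real transcriptomes.

## Numerical choices

* One global integer seed; every stochastic stage derives a child seed
  deterministically from (seed, stage name), so stages are independently
  reproducible and the full pipeline is byte-identical across reruns.
* ROC AUC is trapezoidal over distinct thresholds and equals Mann–Whitney
  concordance with half-credit ties; PR AUC uses step-wise interpolation
  (precision at each threshold times its recall increment), so constant
  scores yield the positive prevalence.
* MCC with any empty marginal is defined as 0.
* A Bernoulli spy draw leaving either side empty is resampled with the next
  child seed (up to 1000 attempts, logged).
* EM restarts that collapse (vanishing variance or an empty component) are
  discarded and replaced by the next child seed.

## Benchmark problem sizes

The test suite and the acceptance script run at desk scale: the 600-gene
supervised benchmark uses 200 trees (100 for the permuted-label null); the
ablation stability sweep uses 20 seeds at k = 5 folds and 60 trees; the PU
purity fixture uses 10,000 genes (2,000 positives, 8,000 unlabeled of which
a quarter are hidden positives) so the spy-quantile Monte-Carlo error is
small; mixture recovery uses n = 3,000; the end-to-end profile uses 2,400
genes with 200 trees. The full protocol values (k = 10, 1000 trees) remain
the `RunConfig` defaults.

## Known limitations

* The spy-quantile purity bound above: RN contamination tracks the
  latent-positive fraction of the unlabeled pool and cannot be pushed below
  the quantile leak by stronger features.
* On cleanly bimodal score distributions with a spread upper cluster, the
  3-component ML fit sometimes splits the upper cluster rather than the
  lower one (this is the true likelihood maximum, verified across
  independent initializations). The extreme classes stay essentially pure,
  but which genes fall to `uncertain` — and hence functional-class recall —
  depends on the fit geometry. The published cutoffs (0.02 / 0.96 in the
  motivating study) are data-derived, and this package always re-derives
  them.
* Backward elimination's stopping depth is unreliable on redundant feature
  panels (see above); interpret the ablation trace, not just the selected
  depth.
* Gene identifiers are opaque strings; homolog mapping between species is an
  input, never computed.
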