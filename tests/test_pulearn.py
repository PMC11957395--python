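"""Spy-based positive-unlabeled labeling: splits, oversampling, the Gaussian
Naive Bayes model and reliable-negative mining."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.naive_bayes import GaussianNB

from neurgi.config import RunConfig
from neurgi.pulearn import (
    fit_naive_bayes,
    label_reliable_negatives,
    oversample,
    reliable_negatives,
    split_spies,
)
from neurgi.synthetic import SyntheticSpec, generate_feature_table
from neurgi.types import ValidationError


class TestSplitSpies:
    def test_bernoulli_spy_count_matches_binomial_mean(self):
        """Over many seeds the spy count of a 10% draw from 293 genes
        averages ~29.3 (Binomial mean), within 3 sigma of the mean."""
        genes = {f"g{i}" for i in range(293)}
        counts = [len(split_spies(genes, 0.1, seed)[1]) for seed in range(1000)]
        se = np.sqrt(293 * 0.1 * 0.9 / 1000)
        assert abs(np.mean(counts) - 29.3) < 3 * se

    def test_exact_mode_rounds_fraction(self):
        genes = {f"g{i}" for i in range(293)}
        residual, spies = split_spies(genes, 0.1, seed=5, mode="exact")
        assert len(spies) == 29
        assert len(residual) == 264
        assert spies.isdisjoint(residual) and spies | residual == frozenset(genes)

    def test_exact_mode_two_genes_half_fraction(self):
        residual, spies = split_spies({"a", "b"}, 0.5, seed=1, mode="exact")
        assert len(spies) == 1 and len(residual) == 1

    def test_partition_always_holds(self):
        genes = {f"g{i}" for i in range(40)}
        for seed in range(20):
            residual, spies = split_spies(genes, 0.25, seed)
            assert spies | residual == frozenset(genes)
            assert not spies & residual
            assert len(spies) > 0 and len(residual) > 0

    def test_degenerate_draws_resampled(self):
        # two genes at 1% spy rate: most draws yield zero spies and must be
        # retried until one side is nonempty
        residual, spies = split_spies({"a", "b"}, 0.01, seed=0)
        assert len(spies) == 1 and len(residual) == 1

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_spies({"a", "b"}, 1.5, 0)


class TestOversample:
    def test_paper_scale_multiset_size(self):
        minority = {f"g{i}" for i in range(271)}
        sample = oversample(minority, 19603, seed=1)
        assert len(sample) == 19603
        assert set(sample) <= minority

    def test_target_equal_to_minority_size(self):
        minority = {"a", "b", "c"}
        assert len(oversample(minority, 3, seed=0)) == 3

    def test_empirical_frequencies_uniform_within_3_sigma(self):
        minority = {"a", "b", "c"}
        draws = pd.Series(oversample(minority, 10000, seed=2)).value_counts()
        expected = 10000 / 3
        sigma = np.sqrt(10000 * (1 / 3) * (2 / 3))
        for gene in minority:
            assert abs(draws[gene] - expected) < 3 * sigma

    def test_empty_minority_rejected(self):
        with pytest.raises(ValidationError):
            oversample(set(), 5, 0)


class TestNaiveBayes:
    def test_separated_classes_give_confident_posterior(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(0.0, 1.0, size=(200, 1))
        neg = rng.normal(10.0, 1.0, size=(200, 1))
        model = fit_naive_bayes(pos, neg)
        assert model.posterior_positive(np.array([[0.0]]))[0] > 0.99

    def test_posterior_matches_closed_form_gaussian(self):
        """Posterior agrees with the analytic two-Gaussian Bayes rule built
        from the fitted moments."""
        rng = np.random.default_rng(1)
        pos = rng.normal(1.0, 1.5, size=(300, 1))
        neg = rng.normal(-1.0, 0.8, size=(300, 1))
        model = fit_naive_bayes(pos, neg)
        x = np.linspace(-3, 3, 21)
        lik_pos = norm.pdf(x, model.means[1, 0], np.sqrt(model.variances[1, 0]))
        lik_neg = norm.pdf(x, model.means[0, 0], np.sqrt(model.variances[0, 0]))
        oracle = (model.priors[1] * lik_pos) / (
            model.priors[1] * lik_pos + model.priors[0] * lik_neg
        )
        np.testing.assert_allclose(
            model.posterior_positive(x.reshape(-1, 1)), oracle, atol=1e-12
        )

    def test_identical_distributions_return_prior(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(size=(400, 3))
        model = fit_naive_bayes(rows[:100], rows[100:])
        post = model.posterior_positive(rng.normal(size=(50, 3)))
        # prior(positive) = 100 / 400
        assert np.allclose(post.mean(), 0.25, atol=0.1)

    def test_constant_feature_equal_priors_gives_half(self):
        pos = np.full((10, 1), 3.0)
        neg = np.full((10, 1), 3.0)
        model = fit_naive_bayes(pos, neg)
        assert model.posterior_positive(np.array([[3.0], [99.0]])) == pytest.approx([0.5, 0.5])

    def test_agrees_with_sklearn_gaussian_nb(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(1.0, 1.0, size=(150, 4))
        neg = rng.normal(0.0, 1.2, size=(250, 4))
        model = fit_naive_bayes(pos, neg)
        x_all = np.vstack([pos, neg])
        y_all = np.r_[np.ones(150), np.zeros(250)]
        skl = GaussianNB().fit(x_all, y_all)
        grid = rng.normal(0.5, 1.5, size=(40, 4))
        np.testing.assert_allclose(
            model.posterior_positive(grid), skl.predict_proba(grid)[:, 1], rtol=1e-6, atol=1e-9
        )

    def test_nan_rows_rejected(self):
        with pytest.raises(ValidationError):
            fit_naive_bayes(np.array([[1.0], [np.nan]]), np.array([[0.0], [0.0]]))


class TestReliableNegatives:
    @staticmethod
    def _model_1d():
        rng = np.random.default_rng(4)
        pos = rng.normal(3.0, 1.0, size=(500, 1))
        neg = rng.normal(-3.0, 1.0, size=(500, 1))
        return fit_naive_bayes(pos, neg)

    def test_threshold_matches_interpolated_quantile_oracle(self):
        model = self._model_1d()
        spy_x = np.linspace(-1.0, 2.0, 10).reshape(-1, 1)
        spy_post = model.posterior_positive(spy_x)
        unlabeled = pd.DataFrame({"f": np.linspace(-5, 5, 30)},
                                 index=[f"u{i}" for i in range(30)])
        rn, threshold = reliable_negatives(model, unlabeled, spy_x, 0.10)
        # oracle: linear interpolation between order statistics
        srt = np.sort(spy_post)
        h = (len(srt) - 1) * 0.10
        lo, frac = int(np.floor(h)), h - int(np.floor(h))
        oracle_t = srt[lo] + frac * (srt[lo + 1] - srt[lo])
        assert threshold == pytest.approx(oracle_t, abs=1e-12)
        u_post = model.posterior_positive(unlabeled.to_numpy())
        assert rn == frozenset(unlabeled.index[u_post < threshold])

    def test_all_unlabeled_above_spies_gives_empty_rn(self):
        model = self._model_1d()
        spy_x = np.full((5, 1), -4.0)        # spies at very low posterior
        unlabeled = pd.DataFrame({"f": [4.0, 5.0, 6.0]}, index=["u1", "u2", "u3"])
        rn, _ = reliable_negatives(model, unlabeled, spy_x, 0.10)
        assert rn == frozenset()

    def test_rn_size_monotone_in_quantile(self):
        model = self._model_1d()
        rng = np.random.default_rng(5)
        spy_x = rng.normal(3.0, 1.0, size=(40, 1))
        unlabeled = pd.DataFrame({"f": rng.normal(0.0, 3.0, 400)},
                                 index=[f"u{i}" for i in range(400)])
        sizes = [len(reliable_negatives(model, unlabeled, spy_x, q)[0])
                 for q in (0.05, 0.1, 0.25, 0.5, 0.75)]
        assert sizes == sorted(sizes)

    def test_stage_determinism(self, bench600):
        cfg = RunConfig(seed=123)
        r1 = label_reliable_negatives(bench600.table, bench600.labeled_positives, cfg)
        r2 = label_reliable_negatives(bench600.table, bench600.labeled_positives, cfg)
        assert r1.sets.reliable_negatives == r2.sets.reliable_negatives
        assert r1.threshold == r2.threshold
        assert r1.sets.spies == r2.sets.spies

    def test_labeled_sets_invariants_after_stage(self, bench600):
        res = label_reliable_negatives(
            bench600.table, bench600.labeled_positives, RunConfig(seed=9)
        )
        s = res.sets.sizes()
        assert s["Us"] == s["U"] + s["spies"]
        assert s["Ps"] == s["P"] - s["spies"]
        res.sets.validate()

    def test_rn_strongly_enriched_for_latent_negatives_at_half_contamination(self):
        """With a 50/50 latent mix in the unlabeled pool, the spy threshold
        admits roughly its quantile-fraction of hidden positives (spies and
        hidden positives are exchangeable), so RN is strongly enriched for
        latent negatives and recovers nearly all of them."""
        spec = SyntheticSpec(n_positive=500, n_latent_negative=2000,
                             n_unlabeled=2000, seed=31)
        data = generate_feature_table(spec)
        res = label_reliable_negatives(data.table, data.labeled_positives, RunConfig(seed=31))
        rn = sorted(res.sets.reliable_negatives)
        truth = data.truth.loc[rn]
        purity = (truth == 0).mean()
        latent_neg_total = ((data.truth == 0)).sum()
        recovered = (truth == 0).sum() / latent_neg_total
        assert purity > 0.80
        assert recovered > 0.95
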