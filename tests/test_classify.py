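"""Score classification: density peaks, mixture fitting, thresholds, classes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.mixture import GaussianMixture

from neurgi.classify import (
    DegeneracyError,
    GmmModel,
    classify_scores,
    derive_thresholds,
    find_score_peaks,
    fit_gmm,
)
from neurgi.synthetic import generate_scores


class TestFindScorePeaks:
    def test_bimodal_sample_yields_two_peaks_near_modes(self):
        rng = np.random.default_rng(0)
        s = np.clip(np.r_[rng.normal(0.1, 0.02, 1000), rng.normal(0.9, 0.02, 1000)], 0, 1)
        peaks = find_score_peaks(s)
        assert len(peaks) == 2
        assert abs(peaks[0] - 0.1) < 0.03 and abs(peaks[1] - 0.9) < 0.03

    def test_unimodal_sample_yields_one_peak(self):
        rng = np.random.default_rng(1)
        s = np.clip(rng.normal(0.5, 0.05, 500), 0, 1)
        assert len(find_score_peaks(s)) == 1

    def test_peak_count_invariant_to_shuffling(self):
        rng = np.random.default_rng(2)
        s = np.clip(np.r_[rng.normal(0.2, 0.03, 300), rng.normal(0.8, 0.03, 300)], 0, 1)
        a = find_score_peaks(s)
        b = find_score_peaks(rng.permutation(s))
        np.testing.assert_array_equal(a, b)

    def test_degenerate_identical_scores_signalled(self):
        with pytest.raises(DegeneracyError):
            find_score_peaks(np.full(100, 0.5))


class TestFitGmm:
    def test_parameter_recovery_on_separated_components(self):
        params = ((0.05, 0.5, 0.95), (0.02, 0.02, 0.02), (0.3, 0.3, 0.4))
        scores, _ = generate_scores(params, n=3000, seed=5)
        model = fit_gmm(scores, components=3, seed=5)
        np.testing.assert_allclose(model.means, params[0], atol=0.01)
        np.testing.assert_allclose(model.weights, params[2], atol=0.03)

    def test_log_likelihood_non_decreasing(self):
        scores, _ = generate_scores(((0.1, 0.5, 0.9), (0.05, 0.1, 0.05), (0.4, 0.2, 0.4)),
                                    n=800, seed=6)
        model = fit_gmm(scores, seed=6)
        ll = np.asarray(model.log_likelihoods)
        assert np.all(np.diff(ll) >= -1e-8)

    def test_components_sorted_by_mean(self):
        scores, _ = generate_scores(((0.2, 0.5, 0.8), (0.04, 0.04, 0.04), (1 / 3,) * 3),
                                    n=900, seed=7)
        model = fit_gmm(scores, seed=7)
        assert np.all(np.diff(model.means) > 0)

    def test_agrees_with_sklearn_mixture(self):
        """Independent EM implementation recovers the same solution as
        sklearn's GaussianMixture on well-separated data."""
        scores, _ = generate_scores(((0.1, 0.5, 0.9), (0.03, 0.05, 0.03), (0.35, 0.3, 0.35)),
                                    n=2000, seed=8)
        model = fit_gmm(scores, seed=8)
        skl = GaussianMixture(n_components=3, covariance_type="full", n_init=5,
                              random_state=8).fit(scores.reshape(-1, 1))
        order = np.argsort(skl.means_.ravel())
        np.testing.assert_allclose(model.means, skl.means_.ravel()[order], atol=0.01)
        np.testing.assert_allclose(model.weights, skl.weights_[order], atol=0.02)

    def test_determinism(self):
        scores, _ = generate_scores(((0.1, 0.5, 0.9), (0.03, 0.08, 0.03), (0.4, 0.2, 0.4)),
                                    n=600, seed=9)
        a = fit_gmm(scores, seed=42)
        b = fit_gmm(scores, seed=42)
        np.testing.assert_array_equal(a.means, b.means)

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm(np.linspace(0, 1, 20), components=3, seed=0)


def _grid_crossing(model, k_lo, k_hi, lo, hi):
    """Dense-grid argmin of |weighted pdf difference| between two components."""
    grid = np.linspace(lo, hi, 200001)
    diff = np.abs(model.component_pdf(grid, k_lo) - model.component_pdf(grid, k_hi))
    return grid[np.argmin(diff)]


class TestDeriveThresholds:
    def test_symmetric_equal_weight_crossing_at_midpoint(self):
        model = GmmModel(weights=np.array([0.4, 0.4, 0.2]),
                         means=np.array([0.0, 1.0, 5.0]),
                         variances=np.array([0.01, 0.01, 0.01]))
        t_low, _ = derive_thresholds(model)
        assert t_low == pytest.approx(0.5, abs=1e-9)

    def test_unequal_weights_match_dense_grid_oracle(self):
        model = GmmModel(weights=np.array([0.9 * 0.5, 0.1 * 0.5, 0.5]),
                         means=np.array([0.0, 1.0, 3.0]),
                         variances=np.array([0.01, 0.01, 0.04]))
        t_low, t_high = derive_thresholds(model)
        assert t_low == pytest.approx(_grid_crossing(model, 0, 1, 0.0, 1.0), abs=1e-4)
        assert t_high == pytest.approx(_grid_crossing(model, 1, 2, 1.0, 3.0), abs=1e-4)

    def test_invariant_to_weight_rescaling(self):
        w = np.array([0.3, 0.3, 0.4])
        base = GmmModel(weights=w, means=np.array([0.1, 0.5, 0.9]),
                        variances=np.array([0.004, 0.01, 0.004]))
        # doubling all weights and renormalizing is the same mixture
        scaled = GmmModel(weights=(2 * w) / (2 * w).sum(), means=base.means,
                          variances=base.variances)
        np.testing.assert_allclose(derive_thresholds(base), derive_thresholds(scaled),
                                   atol=1e-10)

    def test_nearly_coincident_means_signalled(self):
        model = GmmModel(weights=np.array([1 / 3] * 3),
                         means=np.array([0.4900, 0.4905, 0.95]),
                         variances=np.array([0.04, 0.04, 0.04]))
        with pytest.raises(DegeneracyError):
            derive_thresholds(model)

    def test_dominated_middle_component_signalled(self):
        # the low component overwhelms the tiny middle one everywhere in the
        # bracket, so no density crossing exists
        model = GmmModel(weights=np.array([0.949, 0.001, 0.05]),
                         means=np.array([0.3, 0.5, 0.9]),
                         variances=np.array([0.09, 0.01, 0.0001]))
        with pytest.raises(DegeneracyError):
            derive_thresholds(model)

    def test_agrees_with_posterior_crossover(self):
        """The PDF intersection coincides with where the dominant component
        of the posterior switches, for well-separated fits."""
        model = GmmModel(weights=np.array([0.25, 0.5, 0.25]),
                         means=np.array([0.05, 0.5, 0.95]),
                         variances=np.array([0.001, 0.02, 0.001]))
        t_low, t_high = derive_thresholds(model)
        for t, (a, b) in ((t_low, (0, 1)), (t_high, (1, 2))):
            eps = 1e-6
            r_before = model.responsibilities(np.array([t - eps]))[0]
            r_after = model.responsibilities(np.array([t + eps]))[0]
            assert np.argmax(r_before[[a, b]]) == 0
            assert np.argmax(r_after[[a, b]]) == 1


class TestClassifyScores:
    def test_quoted_cutpoints(self):
        scores = pd.Series([0.01, 0.5, 0.99], index=["a", "b", "c"])
        result = classify_scores(scores, (0.02, 0.96))
        assert list(result.classes) == ["non_functional", "uncertain", "functional"]

    def test_tie_at_threshold_is_uncertain(self):
        scores = pd.Series([0.96, 0.02], index=["hi", "lo"])
        result = classify_scores(scores, (0.02, 0.96))
        assert (result.classes == "uncertain").all()

    def test_counts_partition_input(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.random(500), index=[f"g{i}" for i in range(500)])
        result = classify_scores(scores, (0.3, 0.7))
        assert sum(result.counts().values()) == 500

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_scores(pd.Series([0.5]), (0.9, 0.1))


class TestEndToEndClassification:
    def test_component_membership_recovery(self):
        """Mixture draws at the published peak locations are assigned back to
        their generating component with >= 95% accuracy."""
        params = ((0.02, 0.5, 0.97), (0.01, 0.15, 0.01), (0.25, 0.5, 0.25))
        scores, comp = generate_scores(params, n=19288, seed=12)
        model = fit_gmm(scores, seed=12)
        t_low, t_high = derive_thresholds(model)
        result = classify_scores(pd.Series(scores), (t_low, t_high))
        predicted = result.classes.map(
            {"non_functional": 0, "uncertain": 1, "functional": 2}
        ).to_numpy()
        assert (predicted == comp).mean() >= 0.95

    def test_extreme_class_recall_on_bimodal_generator(self):
        """Functional / non-functional recall is >= 0.95 when the outer
        components are separated by >= 0.8 with SD <= 0.05."""
        params = ((0.05, 0.5, 0.9), (0.03, 0.1, 0.03), (0.4, 0.2, 0.4))
        scores, comp = generate_scores(params, n=5000, seed=13)
        model = fit_gmm(scores, seed=13)
        result = classify_scores(pd.Series(scores), derive_thresholds(model))
        cls = result.classes.to_numpy()
        assert (cls[comp == 2] == "functional").mean() >= 0.95
        assert (cls[comp == 0] == "non_functional").mean() >= 0.95
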