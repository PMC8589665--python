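import math
import warnings

import numpy as np
import pytest

from bistate import (
    ValidationError,
    classify_modality,
    distance_symptom_correlation,
    fit_gmm,
    kmeans_peaks,
    normalize_conditions,
)


def two_component_sample(rng, n=200, m1=800.0, m2=2000.0, sd=50.0, w=0.5):
    comp = rng.random(n) < w
    return np.where(comp, rng.normal(m1, sd, n), rng.normal(m2, sd, n))


class TestNormalizeConditions:
    def test_equal_condition_means_is_identity(self):
        rts = np.array([1000.0, 1200.0, 1000.0, 1200.0])
        labels = np.array(["angry", "angry", "neutral", "neutral"])
        out = normalize_conditions(rts, labels)
        assert np.allclose(out.normalized_rts, rts)

    def test_recenters_both_conditions_to_grand_mean(self):
        rts = np.array([1150.0, 1250.0, 950.0, 1050.0])  # angry mean 1200, neutral 1000
        labels = np.array(["angry", "angry", "neutral", "neutral"])
        out = normalize_conditions(rts, labels)
        angry = out.normalized_rts[labels == "angry"]
        neutral = out.normalized_rts[labels == "neutral"]
        assert angry.mean() == pytest.approx(1100.0)
        assert neutral.mean() == pytest.approx(1100.0)
        assert out.normalized_rts.mean() == pytest.approx(rts.mean())

    def test_missing_condition_rejected(self):
        with pytest.raises(ValidationError):
            normalize_conditions([1.0, 2.0], ["angry", "angry"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            normalize_conditions([], [])


class TestFitGmm:
    def test_k1_matches_closed_form_mle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1200, 150, 48)
        fit = fit_gmm(x, 1)
        assert fit.means[0] == pytest.approx(x.mean())
        assert fit.variances[0] == pytest.approx(x.var(ddof=0))
        expected_logl = -0.5 * x.size * (
            math.log(2 * math.pi) + math.log(x.var(ddof=0)) + 1.0
        )
        assert fit.log_likelihood == pytest.approx(expected_logl)

    def test_aic_formula(self):
        rng = np.random.default_rng(1)
        fit = fit_gmm(rng.normal(size=30), 1)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.log_likelihood)
        fit2 = fit_gmm(rng.normal(size=30), 2, seed=0)
        assert fit2.n_params == 5
        assert fit2.aic == pytest.approx(10 - 2 * fit2.log_likelihood)

    def test_k2_recovers_well_separated_means(self):
        rng = np.random.default_rng(42)
        x = two_component_sample(rng)
        fit = fit_gmm(x, 2, seed=0)
        assert fit.converged
        assert fit.means[0] == pytest.approx(800.0, abs=25.0)
        assert fit.means[1] == pytest.approx(2000.0, abs=25.0)

    def test_means_reported_ascending(self):
        rng = np.random.default_rng(3)
        fit = fit_gmm(two_component_sample(rng, n=60), 2, seed=5)
        assert fit.means[0] <= fit.means[1]

    def test_k2_likelihood_never_below_k1(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(0, 1, 48)
            f1, f2 = fit_gmm(x, 1), fit_gmm(x, 2, seed=1)
            assert f2.log_likelihood >= f1.log_likelihood - 1e-9

    def test_delta_aic_is_twice_loglik_gap_minus_six(self):
        rng = np.random.default_rng(5)
        x = two_component_sample(rng, n=48)
        f1, f2 = fit_gmm(x, 1), fit_gmm(x, 2, seed=2)
        delta = f1.aic - f2.aic
        assert delta == pytest.approx(
            2 * (f2.log_likelihood - f1.log_likelihood) - 6, abs=1e-9
        )

    def test_small_sample_rejected_for_k2(self):
        with pytest.raises(ValidationError):
            fit_gmm(np.arange(5.0), 2, seed=0)


class TestClassifyModality:
    def fits(self, delta, converged=True):
        f1 = fit_gmm(np.random.default_rng(0).normal(size=48), 1)
        f2 = f1.__class__(
            k=2, weights=(0.5, 0.5), means=(0.0, 1.0), variances=(1.0, 1.0),
            log_likelihood=(f1.aic + delta - 10) / -2.0, n_params=5,
            aic=f1.aic - delta, converged=converged, seed=0, n=f1.n,
        )
        return f1, f2

    def test_above_threshold_is_bimodal(self):
        f1, f2 = self.fits(2.5)
        assert classify_modality(f1, f2).preferred == "bimodal"

    def test_below_threshold_is_unimodal(self):
        f1, f2 = self.fits(1.9)
        assert classify_modality(f1, f2).preferred == "unimodal"

    def test_nonconverged_fit_is_indeterminate(self):
        f1, f2 = self.fits(5.0, converged=False)
        assert classify_modality(f1, f2).preferred == "indeterminate"

    def test_mismatched_sample_sizes_rejected(self):
        f1, f2 = self.fits(1.0)
        f2 = f2.__class__(**{**f2.__dict__, "n": f2.n + 1})
        with pytest.raises(ValidationError):
            classify_modality(f1, f2)


class TestKmeansPeaks:
    def test_perfectly_separable_values(self):
        x = [1000.0, 1000.0, 1000.0, 3000.0, 3000.0, 3000.0]
        centers, dist = kmeans_peaks(x, seed=0)
        assert centers == pytest.approx((1000.0, 3000.0))
        assert dist == pytest.approx(2000.0)

    def test_distance_tracks_true_separation(self):
        rng = np.random.default_rng(6)
        x = two_component_sample(rng, n=200, m1=1000.0, m2=1800.0, sd=80.0)
        _, dist = kmeans_peaks(x, seed=1)
        assert dist == pytest.approx(800.0, rel=0.10)

    def test_constant_vector_degenerates_to_zero(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, dist = kmeans_peaks([5.0, 5.0, 5.0], seed=0)
        assert dist == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        x = two_component_sample(rng, n=100, m1=900.0, m2=1700.0, sd=60.0)
        _, d1 = kmeans_peaks(x, seed=3)
        _, d2 = kmeans_peaks(x + 12345.0, seed=3)
        assert d1 == pytest.approx(d2, abs=1e-6)


class TestDistanceSymptomCorrelation:
    def cohort(self, rng, n_patients=12, coupled=True):
        samples, sums = [], []
        for i in range(n_patients):
            sep = 400.0 + 900.0 * (i / (n_patients - 1))
            rts = two_component_sample(rng, n=48, m1=1200.0, m2=1200.0 + sep, sd=100.0)
            labels = np.array(["angry", "neutral"] * 24)
            samples.append(normalize_conditions(rts, labels, subject_id=f"p{i}"))
            sums.append(sep / 1000.0 if coupled else rng.random())
        return samples, sums

    def test_planted_coupling_detected(self):
        rng = np.random.default_rng(8)
        samples, sums = self.cohort(rng, coupled=True)
        res = distance_symptom_correlation(samples, sums, n_iterations=25, seed=0)
        assert res.mean_r > 0.5
        assert res.mean_p < 0.05

    def test_iteration_count_and_ranges(self):
        rng = np.random.default_rng(9)
        samples, sums = self.cohort(rng)
        res = distance_symptom_correlation(samples, sums, n_iterations=10, seed=1)
        assert len(res.r_values) == 10
        assert res.r_range[0] <= res.mean_r <= res.r_range[1]
        assert res.p_range[0] <= res.mean_p <= res.p_range[1]

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(10)
        samples, sums = self.cohort(rng)
        a = distance_symptom_correlation(samples, sums, n_iterations=5, seed=4)
        b = distance_symptom_correlation(samples, sums, n_iterations=5, seed=4)
        assert a.r_values == b.r_values

    def test_too_few_patients_rejected(self):
        rng = np.random.default_rng(11)
        samples, sums = self.cohort(rng, n_patients=3)
        with pytest.raises(ValidationError):
            distance_symptom_correlation(samples, sums, n_iterations=2, seed=0)


def test_gmm_cross_check_against_sklearn():
    """Independent EM route (sklearn) should find the same optimum on a
    well-separated sample."""
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(12)
    x = two_component_sample(rng, n=150, m1=900.0, m2=1900.0, sd=90.0)
    ours = fit_gmm(x, 2, seed=0)
    ref = GaussianMixture(2, covariance_type="spherical", n_init=5, random_state=0)
    ref.fit(x.reshape(-1, 1))
    ref_means = np.sort(ref.means_.ravel())
    assert ours.means[0] == pytest.approx(ref_means[0], abs=10.0)
    assert ours.means[1] == pytest.approx(ref_means[1], abs=10.0)
    ref_logl = float(ref.score(x.reshape(-1, 1)) * x.size)
    assert ours.log_likelihood == pytest.approx(ref_logl, abs=1.0)
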