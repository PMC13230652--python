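"""Tests of the synthetic item-response generator and reliability tooling."""

import numpy as np
import pytest
from scipy.stats import norm

from truescoreci import (
    ItemModelSpec,
    NormScale,
    T_SCALE,
    calibrate_error_sd,
    closed_form_error_sd,
    continuous_cohort,
    cronbach_alpha,
    default_ordinal_thresholds,
    draw_dichotomous_thresholds,
    draw_true_scores,
    make_cohort,
    simulate_responses,
    sum_and_standardize,
)
from truescoreci.simulate import _spec_with_error_sd


class TestDraws:
    def test_true_scores_match_the_norm_distribution(self):
        t = draw_true_scores(1_000_000, T_SCALE, seed=1)
        assert t.mean() == pytest.approx(50.0, abs=0.05)
        assert t.std(ddof=1) == pytest.approx(10.0, abs=0.05)

    def test_determinism(self):
        a = draw_true_scores(100, T_SCALE, seed=7)
        b = draw_true_scores(100, T_SCALE, seed=7)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, draw_true_scores(100, T_SCALE, seed=8))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            draw_true_scores(0, T_SCALE, seed=1)

    def test_dichotomous_thresholds(self):
        thr = draw_dichotomous_thresholds(50, T_SCALE, seed=3)
        assert thr.shape == (50,)
        assert 46 < thr.mean() < 54  # 3 SE bound around the norm mean
        np.testing.assert_array_equal(thr, draw_dichotomous_thresholds(50, T_SCALE, seed=3))


class TestOrdinalThresholds:
    def test_ascending_and_symmetric(self):
        cuts = default_ordinal_thresholds(6, 12.0, T_SCALE)
        assert cuts.shape == (5,)
        assert np.all(np.diff(cuts) > 0)
        np.testing.assert_allclose(cuts + cuts[::-1], 100.0)

    def test_two_categories_cut_at_the_mean(self):
        np.testing.assert_allclose(default_ordinal_thresholds(2, 5.0, T_SCALE), [50.0])

    def test_marginal_category_distribution_is_near_normal(self):
        """Analytic check under the normal latent model: the 6-category
        histogram implied by the default cutoffs is symmetric and mesokurtic
        enough (|skewness| < 0.1)."""
        sigma = 9.0
        cuts = default_ordinal_thresholds(6, sigma, T_SCALE)
        z = (cuts - 50.0) / sigma
        probs = np.diff(np.concatenate([[0.0], norm.cdf(z), [1.0]]))
        cats = np.arange(1, 7)
        mean = (probs * cats).sum()
        var = (probs * (cats - mean) ** 2).sum()
        skew = (probs * (cats - mean) ** 3).sum() / var**1.5
        assert abs(skew) < 0.1

    def test_invalid_categories(self):
        with pytest.raises(ValueError):
            default_ordinal_thresholds(1, 5.0, T_SCALE)


class TestResponses:
    def _ordinal_spec(self, sigma_e=5.0):
        return _spec_with_error_sd(
            ItemModelSpec(kind="ordinal", n_items=10, n_categories=6, latent_error_sd=1.0),
            sigma_e,
            T_SCALE,
        )

    def test_ordinal_range_and_determinism(self):
        t = draw_true_scores(500, T_SCALE, seed=2)
        spec = self._ordinal_spec()
        r1 = simulate_responses(t, spec, seed=5)
        r2 = simulate_responses(t, spec, seed=5)
        np.testing.assert_array_equal(r1, r2)
        assert r1.min() >= 1 and r1.max() <= 6

    def test_vanishing_error_gives_identical_rows_for_identical_true_scores(self):
        t = np.full(20, 57.0)
        spec = self._ordinal_spec(sigma_e=1e-9)
        resp = simulate_responses(t, spec, seed=1)
        assert np.unique(resp, axis=0).shape[0] == 1

    def test_dichotomous_extremes(self):
        thr = draw_dichotomous_thresholds(20, T_SCALE, seed=1)
        spec = ItemModelSpec(
            kind="dichotomous", n_items=20, latent_error_sd=1.0, dichotomous_thresholds=thr
        )
        high = simulate_responses(np.full(5, 1e6), spec, seed=1)
        low = simulate_responses(np.full(5, -1e6), spec, seed=1)
        assert np.all(high == 1) and np.all(low == 0)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ItemModelSpec(
                kind="ordinal", n_items=10, n_categories=6, latent_error_sd=1.0,
                ordinal_thresholds=np.array([1.0, 0.5, 2.0, 3.0, 4.0]),
            )
        with pytest.raises(ValueError):
            ItemModelSpec(kind="dichotomous", n_items=3, latent_error_sd=0.0)


class TestCronbachAlpha:
    def test_hand_computed_example(self):
        # two items with sample variances 1 and covariance .5: alpha = 2/3
        resp = np.column_stack([[-1.0, 0.0, 1.0], [0.0, -1.0, 1.0]])
        assert cronbach_alpha(resp) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_identical_items_give_one(self):
        col = np.array([1.0, 5.0, 2.0, 4.0])
        assert cronbach_alpha(np.column_stack([col] * 4)) == pytest.approx(1.0)

    def test_orthogonal_equal_variance_items_give_zero(self):
        resp = np.column_stack([[1, -1, 1, -1], [1, 1, -1, -1]]).astype(float)
        assert cronbach_alpha(resp) == pytest.approx(0.0, abs=1e-12)

    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        base = rng.normal(size=200)
        data = pd.DataFrame(
            {f"i{j}": base + rng.normal(scale=1.5, size=200) for j in range(5)}
        )
        ours = cronbach_alpha(data.to_numpy())
        theirs = pingouin.cronbach_alpha(data=data)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 3)))  # zero total variance
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 1)))


class TestStandardization:
    def test_exact_moments_and_rank_preservation(self):
        rng = np.random.default_rng(4)
        resp = rng.integers(1, 7, size=(500, 10))
        obs = sum_and_standardize(resp, T_SCALE)
        assert obs.mean() == pytest.approx(50.0, abs=1e-9)
        assert obs.std(ddof=1) == pytest.approx(10.0, abs=1e-9)
        sums = resp.sum(axis=1)
        assert np.array_equal(np.argsort(sums, kind="stable"), np.argsort(obs, kind="stable"))

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        resp = rng.normal(size=(200, 5))
        np.testing.assert_allclose(
            sum_and_standardize(resp, T_SCALE),
            sum_and_standardize(resp + 3.0, T_SCALE),
            atol=1e-9,
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sum_and_standardize(np.ones((10, 4)), T_SCALE)


class TestCalibration:
    def test_continuous_closed_form(self):
        # k parallel continuous items: reliability of the sum has a closed form
        assert closed_form_error_sd(10, 0.5, T_SCALE) == pytest.approx(np.sqrt(1000.0))
        k, sigma_e = 10, 40.0
        rng = np.random.default_rng(6)
        t = draw_true_scores(1_000_000, T_SCALE, rng)
        latent = t[:, None] + rng.normal(0, sigma_e, size=(t.size, k))
        expected = k * 100 / (k * 100 + sigma_e**2)
        assert cronbach_alpha(latent) == pytest.approx(expected, abs=0.005)

    def test_discretisation_attenuates_alpha(self):
        k, sigma_e = 10, 12.0
        rng = np.random.default_rng(7)
        t = draw_true_scores(100_000, T_SCALE, rng)
        latent = t[:, None] + rng.normal(0, sigma_e, size=(t.size, k))
        spec = _spec_with_error_sd(
            ItemModelSpec(kind="ordinal", n_items=k, n_categories=6, latent_error_sd=1.0),
            sigma_e,
            T_SCALE,
        )
        discrete = np.searchsorted(spec.ordinal_thresholds, latent) + 1
        assert cronbach_alpha(discrete) <= cronbach_alpha(latent) + 0.01

    def test_round_trip_hits_the_target(self):
        template = ItemModelSpec(kind="ordinal", n_items=10, n_categories=6, latent_error_sd=1.0)
        result = calibrate_error_sd(template, 0.60, T_SCALE, calib_n=100_000, seed=9, tol=0.01)
        assert abs(result.achieved_alpha - 0.60) <= 0.01
        # an independent cohort simulated at the calibrated SD reproduces alpha
        spec = _spec_with_error_sd(template, result.latent_error_sd, T_SCALE)
        cohort = make_cohort(spec, 100_000, T_SCALE, seed=10)
        assert cronbach_alpha(cohort.responses) == pytest.approx(0.60, abs=0.01)

    def test_alpha_decreases_in_error_sd(self):
        template = ItemModelSpec(kind="ordinal", n_items=10, n_categories=6, latent_error_sd=1.0)
        rng = np.random.default_rng(12)
        t = draw_true_scores(50_000, T_SCALE, rng)
        z = rng.standard_normal((t.size, 10))
        alphas = []
        for sigma in (5.0, 15.0, 40.0, 90.0):
            spec = _spec_with_error_sd(template, sigma, T_SCALE)
            alphas.append(cronbach_alpha(np.searchsorted(spec.ordinal_thresholds, t[:, None] + sigma * z) + 1))
        assert np.all(np.diff(alphas) < 0)

    def test_invalid_target(self):
        template = ItemModelSpec(kind="ordinal", n_items=10, n_categories=6, latent_error_sd=1.0)
        with pytest.raises(ValueError):
            calibrate_error_sd(template, 1.0, T_SCALE, calib_n=1000, seed=1)


class TestCohort:
    def test_cohort_invariants_and_export(self, tmp_path):
        template = ItemModelSpec(kind="ordinal", n_items=10, n_categories=6, latent_error_sd=1.0)
        spec = _spec_with_error_sd(template, 10.0, T_SCALE)
        cohort = make_cohort(spec, 2000, T_SCALE, seed=13)
        assert cohort.observed_scores.mean() == pytest.approx(50.0, abs=1e-9)
        assert cohort.observed_scores.std(ddof=1) == pytest.approx(10.0, abs=1e-9)
        df = cohort.to_dataframe()
        assert list(df.columns[:3]) == ["participant_id", "true_score", "observed_T"]
        assert df.shape == (2000, 13)
        out = tmp_path / "cohort.csv"
        cohort.to_csv(out)
        assert out.exists()

    def test_norming_convention_equates_true_and_observed_sd(self):
        """Standardizing the sums makes SD(observed) = SD(true) = scale.sd —
        the structural fact that makes RETS the correct posterior center."""
        template = ItemModelSpec(kind="ordinal", n_items=10, n_categories=6, latent_error_sd=1.0)
        spec = _spec_with_error_sd(template, 20.0, T_SCALE)
        cohort = make_cohort(spec, 100_000, T_SCALE, seed=14)
        assert cohort.true_scores.std(ddof=1) == pytest.approx(
            np.asarray(cohort.observed_scores).std(ddof=1), rel=0.01
        )

    def test_continuous_cohort_known_reliability(self):
        t, x = continuous_cohort(200_000, 0.6, T_SCALE, seed=15)
        assert np.corrcoef(t, x)[0, 1] ** 2 == pytest.approx(0.6, abs=0.01)
        assert x.std(ddof=1) == pytest.approx(10.0, abs=1e-9)
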