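"""Naive OLS, calibration fits, corrected estimators, robust variance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcal import (
    CalibrationDataset,
    ErrorModel,
    apply_error,
    correct_differential,
    correct_systematic,
    fit_calibration,
    fit_calibration_by_arm,
    fit_ols,
    fit_ols_adjusted,
    generate_trial,
    hc3_vcov,
    reliability_sample_size,
)
from trialcal.errors import (
    SingularCalibrationError,
    SingularDesignError,
    UndefinedCorrectionError,
)


class TestFitOls:
    def test_perfect_fit(self):
        fit = fit_ols([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        assert fit.alpha_star == 0.0
        assert fit.beta_star == 1.0
        assert fit.residual_sd == 0.0

    def test_hand_computed_four_points(self):
        # arm means 2 and 6; pooled residual variance (2+8)/2 = 5
        fit = fit_ols([1.0, 3.0, 4.0, 8.0], [0, 0, 1, 1])
        assert fit.beta_star == pytest.approx(4.0)
        assert fit.alpha_star == pytest.approx(2.0)
        assert fit.residual_sd**2 == pytest.approx(5.0)
        assert fit.vcov[1, 1] == pytest.approx(5.0 * (0.5 + 0.5))
        assert fit.df == 2

    def test_slope_is_difference_of_arm_means(self, rng):
        # two-group OLS identity, to machine precision
        for _ in range(20):
            n0, n1 = rng.integers(2, 30, size=2)
            y = rng.normal(size=n0 + n1)
            x = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
            fit = fit_ols(y, x)
            assert fit.beta_star == pytest.approx(
                y[n0:].mean() - y[:n0].mean(), abs=1e-12
            )

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        y = rng.normal(size=60)
        x = np.concatenate([np.zeros(25, int), np.ones(35, int)])
        fit = fit_ols(y, x)
        sm_fit = sm.OLS(y, sm.add_constant(x.astype(float))).fit()
        assert fit.beta_star == pytest.approx(sm_fit.params[1])
        np.testing.assert_allclose(fit.vcov, sm_fit.cov_params(), rtol=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(SingularDesignError):
            fit_ols([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])

    def test_large_trial_recovers_effect(self, base_model, rng):
        trial = generate_trial(base_model, 100_000, rng)
        fit = fit_ols(trial.y_true, trial.x)
        se = np.sqrt(fit.vcov[1, 1])
        assert fit.beta_star == pytest.approx(6.9, abs=4 * se)


class TestHc3:
    def test_hand_computed_four_points(self):
        # leverage 1/2 everywhere; HC3 arm variances 2 and 8
        y = np.array([1.0, 3.0, 4.0, 8.0])
        x = np.array([0, 0, 1, 1])
        fit = fit_ols(y, x)
        robust = hc3_vcov(fit, y, x)
        np.testing.assert_allclose(robust, [[2.0, -2.0], [-2.0, 10.0]])
        assert fit.robust_vcov is robust

    def test_matches_statsmodels_hc3(self, rng):
        import statsmodels.api as sm

        y = rng.normal(size=80) * np.concatenate([np.full(40, 1.0), np.full(40, 3.0)])
        x = np.concatenate([np.zeros(40, int), np.ones(40, int)])
        fit = fit_ols(y, x)
        robust = hc3_vcov(fit, y, x)
        sm_fit = sm.OLS(y, sm.add_constant(x.astype(float))).fit(cov_type="HC3")
        np.testing.assert_allclose(robust, sm_fit.cov_params(), rtol=1e-8)

    def test_agrees_with_model_based_under_homoscedasticity(self, rng):
        y = rng.normal(size=10_000)
        x = np.concatenate([np.zeros(5_000, int), np.ones(5_000, int)])
        fit = fit_ols(y, x)
        robust = hc3_vcov(fit, y, x)
        assert robust[1, 1] == pytest.approx(fit.vcov[1, 1], rel=0.05)


class TestCalibrationFits:
    def test_exact_line(self):
        calib = CalibrationDataset(y_true=[0.0, 1.0, 2.0], y_star=[0.0, 1.05, 2.1])
        fit = fit_calibration(calib)
        assert fit.theta0_hat == pytest.approx(0.0, abs=1e-12)
        assert fit.theta1_hat == pytest.approx(1.05)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-7)
        assert fit.syy == pytest.approx(2.0)
        assert fit.df == 1

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        y_true = rng.normal(120, 12.6, size=40)
        y_star = 1.05 * y_true + rng.normal(0, 6.6, size=40)
        fit = fit_calibration(CalibrationDataset(y_true=y_true, y_star=y_star))
        sm_fit = sm.OLS(y_star, sm.add_constant(y_true)).fit()
        assert fit.theta1_hat == pytest.approx(sm_fit.params[1])
        np.testing.assert_allclose(fit.vcov, sm_fit.cov_params(), rtol=1e-9)

    def test_large_k_recovers_parameters(self, base_model, rng):
        from trialcal import generate_calibration

        error = ErrorModel.systematic(0.0, 1.05, 6.615)
        calib = generate_calibration(base_model, error, 200_000, "placebo_only", rng)
        fit = fit_calibration(calib)
        assert fit.theta1_hat == pytest.approx(1.05, abs=0.01)

    def test_constant_y_true_is_singular(self):
        calib = CalibrationDataset(y_true=[2.0, 2.0, 2.0], y_star=[1.0, 2.0, 3.0])
        with pytest.raises(SingularCalibrationError):
            fit_calibration(calib)

    def test_by_arm_exact_lines_and_swap_symmetry(self):
        y_true = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        y_star = np.array([0.0, 1.0, 2.0, 0.0, 1.05, 2.1])
        x = np.array([0, 0, 0, 1, 1, 1])
        c = CalibrationDataset(y_true=y_true, y_star=y_star, x=x)
        f0, f1 = fit_calibration_by_arm(c)
        assert (f0.theta0_hat, f0.theta1_hat) == pytest.approx((0.0, 1.0))
        assert (f1.theta0_hat, f1.theta1_hat) == pytest.approx((0.0, 1.05))
        swapped = CalibrationDataset(y_true=y_true, y_star=y_star, x=1 - x)
        g0, g1 = fit_calibration_by_arm(swapped)
        assert (g0.theta0_hat, g0.theta1_hat) == (f1.theta0_hat, f1.theta1_hat)
        assert (g1.theta0_hat, g1.theta1_hat) == (f0.theta0_hat, f0.theta1_hat)


def _calib_fit(theta0, theta1, var_theta1=0.0):
    from trialcal import CalibrationFit

    return CalibrationFit(
        theta0_hat=theta0,
        theta1_hat=theta1,
        vcov=np.array([[0.0, 0.0], [0.0, var_theta1]]),
        k=10,
        df=8,
        syy=1.0,
        residual_sd=0.0,
    )


class TestCorrections:
    def test_systematic_arithmetic(self):
        fit = fit_ols([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        fit.alpha_star, fit.beta_star = 120.0, 7.245
        est = correct_systematic(fit, _calib_fit(0.0, 1.05))
        assert est.alpha_hat == pytest.approx(120.0 / 1.05)
        assert est.beta_hat == pytest.approx(6.9)

    def test_identity_calibration_returns_naive(self):
        fit = fit_ols([1.0, 3.0, 4.0, 8.0], [0, 0, 1, 1])
        est = correct_systematic(fit, _calib_fit(0.0, 1.0))
        assert est.alpha_hat == fit.alpha_star
        assert est.beta_hat == fit.beta_star

    def test_negative_slope_flips_sign(self):
        fit = fit_ols([1.0, 3.0, 4.0, 8.0], [0, 0, 1, 1])
        est = correct_systematic(fit, _calib_fit(0.5, -1.0))
        assert est.beta_hat == pytest.approx(-fit.beta_star)

    def test_zero_slope_undefined(self):
        fit = fit_ols([1.0, 3.0, 4.0, 8.0], [0, 0, 1, 1])
        with pytest.raises(UndefinedCorrectionError):
            correct_systematic(fit, _calib_fit(0.0, 0.0))

    def test_differential_arithmetic(self):
        fit = fit_ols([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        fit.alpha_star, fit.beta_star = 120.0, 13.245
        est = correct_differential(fit, _calib_fit(0.0, 1.0), _calib_fit(0.0, 1.05))
        assert est.alpha_hat == pytest.approx(120.0)
        assert est.beta_hat == pytest.approx(6.9)

    def test_differential_null_preserved(self):
        fit = fit_ols([1.0, -1.0, 1.0, -1.0], [0, 0, 1, 1])
        fit.alpha_star, fit.beta_star = 0.0, 0.0
        for c in (0.5, 1.0, 2.0):
            est = correct_differential(fit, _calib_fit(0.0, c), _calib_fit(0.0, c))
            assert est.beta_hat == pytest.approx(0.0, abs=1e-12)

    def test_differential_collapses_to_systematic_with_shared_params(self, rng):
        # with one shared (theta0, theta1) for both arms, the differential
        # correction reduces algebraically to the systematic one
        for _ in range(1_000):
            a, b, t0 = rng.normal(size=3) * 10
            t1 = rng.normal() or 1.0
            fit = fit_ols([1.0, 3.0, 4.0, 8.0], [0, 0, 1, 1])
            fit.alpha_star, fit.beta_star = a, b
            shared = _calib_fit(t0, t1)
            diff = correct_differential(fit, shared, shared)
            sys = correct_systematic(fit, shared)
            assert diff.beta_hat == pytest.approx(sys.beta_hat, rel=1e-9, abs=1e-9)

    def test_exact_composition_with_error_free_pipeline(self, base_model, rng):
        # identity-line calibration + error-free endpoint reproduces the
        # true-endpoint OLS estimates to machine precision
        trial = generate_trial(base_model, 100, rng)
        error = ErrorModel.systematic(0.0, 1.0, 1e-300)
        observed = apply_error(trial, error, rng)
        fit = fit_ols(observed.y_star, observed.x)
        line = np.linspace(100.0, 140.0, 10)
        calib = fit_calibration(CalibrationDataset(y_true=line, y_star=line))
        est = correct_systematic(fit, calib)
        truth = fit_ols(trial.y_true, trial.x)
        assert est.beta_hat == pytest.approx(truth.beta_star, abs=1e-10)
        assert est.alpha_hat == pytest.approx(truth.alpha_star, abs=1e-10)


class TestAdjustedFit:
    def test_matches_statsmodels_with_covariate(self, rng):
        import statsmodels.api as sm

        n = 200
        x = np.repeat([0, 1], n // 2)
        s = rng.binomial(1, 0.75, n)
        y = 120 + 6.9 * x + 10 * s + rng.normal(0, 12.6, n)
        fit = fit_ols_adjusted(y, x, s)
        design = sm.add_constant(np.column_stack([x, s]).astype(float))
        sm_fit = sm.OLS(y, design).fit()
        assert fit.beta_x == pytest.approx(sm_fit.params[1])
        assert fit.var_beta_x == pytest.approx(sm_fit.cov_params()[1, 1])

    def test_constant_covariate_column_dropped(self, rng):
        y = rng.normal(size=40)
        x = np.repeat([0, 1], 20)
        unadjusted = fit_ols(y, x)
        degenerate = fit_ols_adjusted(y, x, np.zeros(40))
        assert degenerate.beta_x == pytest.approx(unadjusted.beta_star, abs=1e-12)


class TestAlgebraicProperties:
    @given(
        theta1=st.floats(0.05, 5.0),
        sigma=st.floats(0.1, 100.0),
        r2=st.floats(0.01, 0.99),
    )
    @settings(derandomize=True, max_examples=200)
    def test_tau_for_r2_inverts_the_r2_formula(self, theta1, sigma, r2):
        from trialcal import tau_for_r2

        tau = tau_for_r2(theta1, sigma, r2)
        implied = theta1**2 * sigma**2 / (theta1**2 * sigma**2 + tau**2)
        assert implied == pytest.approx(r2, rel=1e-9)

    @given(
        alpha_star=st.floats(-200, 200),
        beta_star=st.floats(-50, 50),
        theta0=st.floats(-10, 10),
        theta1=st.floats(-3, 3).filter(lambda t: abs(t) > 1e-3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_systematic_correction_is_scale_equivariant(
        self, alpha_star, beta_star, theta0, theta1
    ):
        # re-expressing the observed endpoint through (theta0, theta1) and
        # correcting must recover the original scale exactly
        fit = fit_ols([1.0, 3.0, 4.0, 8.0], [0, 0, 1, 1])
        fit.alpha_star = theta0 + theta1 * alpha_star
        fit.beta_star = theta1 * beta_star
        est = correct_systematic(fit, _calib_fit(theta0, theta1))
        assert est.beta_hat == pytest.approx(beta_star, rel=1e-9, abs=1e-9)
        assert est.alpha_hat == pytest.approx(alpha_star, rel=1e-9, abs=1e-6)


class TestReliabilitySampleSize:
    @pytest.mark.parametrize("n, r, expected", [(400, 0.8, 500), (400, 1.0, 400), (108, 0.5, 216)])
    def test_inflation(self, n, r, expected):
        assert reliability_sample_size(n, r) == expected

    def test_rejects_non_positive_reliability(self):
        with pytest.raises(ValueError):
            reliability_sample_size(400, 0.0)
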