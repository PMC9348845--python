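"""Fitting behaviour of the three dose-response estimators."""

import warnings

import numpy as np
import pytest
from sklearn.base import clone

import betadose as bd
from betadose._fitting import dpd_covariance, fit_dpd_design


def _beta_data(seed, b0=0.0, b1=1.0, phi=100.0, reps=3, span=30.0):
    logd = np.repeat(np.linspace(-np.log(span), np.log(span), 7), reps)
    d = np.exp(logd)
    mu = bd.inv_logit(b1 * logd + b0)
    y = np.random.default_rng(seed).beta(mu * phi, (1 - mu) * phi)
    return d, y


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = bd.BetaDoseResponse(alpha=0.3, precision="log_dose")
        params = est.get_params()
        assert params["alpha"] == 0.3 and params["precision"] == "log_dose"
        est2 = clone(est).set_params(alpha="auto")
        assert est2.get_params()["alpha"] == "auto"

    def test_predict_matches_curve(self, clean_beta_data):
        d, y = clean_beta_data
        est = bd.BetaDoseResponse(alpha=0).fit(d, y)
        pred = est.predict(d[:5])
        expect = bd.effect_at_dose(est.curve_params_, d[:5])
        np.testing.assert_allclose(pred, expect)

    def test_input_validation(self):
        est = bd.BetaDoseResponse(alpha=0)
        with pytest.raises(ValueError):
            est.fit([1.0, 2.0], [0.2, 0.4])  # fewer than 3 observations
        with pytest.raises(ValueError):
            est.fit([1.0, 1.0, 1.0], [0.2, 0.4, 0.3])  # one distinct dose
        with pytest.raises(ValueError):
            est.fit([1.0, 2.0, 3.0], [0.2, 1.0, 0.3])  # boundary response


class TestBetaRegressionFit:
    def test_recovers_truth_within_3_se(self):
        d, y = _beta_data(seed=3, b0=1.0, b1=-1.0)
        est = bd.BetaDoseResponse(alpha=0).fit(d, y)
        se = np.sqrt(np.diag(est.covariance_))
        assert abs(est.beta0_ - 1.0) < 3 * se[0]
        assert abs(est.beta1_ + 1.0) < 3 * se[1]

    def test_dose_rescaling_equivariance(self, clean_beta_data):
        d, y = clean_beta_data
        a = bd.BetaDoseResponse(alpha=0.3).fit(d, y)
        b = bd.BetaDoseResponse(alpha=0.3).fit(10.0 * d, y)
        assert b.beta1_ == pytest.approx(a.beta1_, abs=1e-6)
        assert b.beta0_ == pytest.approx(a.beta0_ - a.beta1_ * np.log(10.0), abs=1e-5)
        np.testing.assert_allclose(b.predict(10.0 * d), a.predict(d), atol=1e-7)

    def test_alpha_zero_matches_mle_route(self, clean_beta_data):
        """The DPD minimiser at alpha=0 equals the independent
        maximum-likelihood fit (statsmodels backend)."""
        import pandas as pd

        d, y = clean_beta_data
        est = bd.BetaDoseResponse(alpha=0).fit(d, y)
        frame = pd.DataFrame({"dose": d, "response": y, "group": "g"})
        mle = bd.fit_mle(frame)
        theta = np.concatenate([[est.beta0_, est.beta1_], est.gamma_])
        assert np.max(np.abs(theta - mle.theta_)) < 1e-5

    def test_sandwich_covariance_contract(self, clean_beta_data):
        d, y = clean_beta_data
        logd = np.log(d)
        Zm = np.column_stack([np.ones_like(logd), logd])
        Zp = np.ones((y.size, 1))
        rf = fit_dpd_design(y, Zm, Zp, 0.4)
        cov = dpd_covariance(rf.theta, y, Zm, Zp, 0.4)
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(cov)) > -1e-10

    def test_observed_information_at_alpha_zero(self, clean_beta_data):
        """At alpha=0 the covariance is the inverse observed information of
        the log-likelihood (cross-checked against statsmodels)."""
        import pandas as pd

        d, y = clean_beta_data
        est = bd.BetaDoseResponse(alpha=0).fit(d, y)
        mle = bd.fit_mle(pd.DataFrame({"dose": d, "response": y, "group": "g"}))
        # both carry the same df adjustment, so they are directly comparable
        np.testing.assert_allclose(np.diag(est.covariance_),
                                   np.diag(mle.covariance_), rtol=0.01)

    def test_precision_log_dose_submodel(self):
        # generate with dose-dependent precision and check gamma1 recovery
        logd = np.repeat(np.linspace(-2.0, 2.0, 7), 30)
        d = np.exp(logd)
        mu = bd.inv_logit(logd)
        phi = np.exp(np.log(60.0) + 0.5 * logd)
        y = np.random.default_rng(5).beta(mu * phi, (1 - mu) * phi)
        est = bd.BetaDoseResponse(alpha=0, precision="log_dose").fit(d, y)
        assert est.gamma_.size == 2
        assert est.gamma_[1] == pytest.approx(0.5, abs=0.25)
        assert est.phi_at(1.0) == pytest.approx(np.exp(est.gamma_[0]))

    def test_bounded_influence_vs_least_squares(self, fig_style_perturbed):
        """Moving the smallest response from 0.005 to 1e-6 barely moves the
        robust beta fit; the logit-linear fit swings by far more."""
        d, y, y_pert = fig_style_perturbed
        d3, y3 = np.repeat(d, 3), np.repeat(y, 3)
        y3p = y3.copy()
        y3p[0] = 1e-6
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            brm_a = bd.BetaDoseResponse(alpha=0.4).fit(d3, y3)
            brm_b = bd.BetaDoseResponse(alpha=0.4).fit(d3, y3p)
            lrm_a = bd.LogitLinearDoseResponse().fit(d3, y3)
            lrm_b = bd.LogitLinearDoseResponse().fit(d3, y3p)
        drift_brm = abs(np.log(brm_b.ic50_) - np.log(brm_a.ic50_))
        drift_lrm = abs(np.log(lrm_b.ic50_) - np.log(lrm_a.ic50_))
        assert drift_brm < 0.2 * drift_lrm

    def test_separation_warning(self):
        # noiseless very steep curve: the fitted |logit(mu)| passes 20 at
        # the end doses and the precision runs away
        d = np.exp(np.linspace(-6.0, 6.0, 9))
        y = bd.inv_logit(4.0 * np.log(d))
        with pytest.warns(UserWarning, match="separation"):
            bd.BetaDoseResponse(alpha=0).fit(d, y)


class TestLogitLinear:
    def test_exact_recovery_on_curve(self, fig_style_perturbed):
        d, y, _ = fig_style_perturbed
        est = bd.LogitLinearDoseResponse().fit(d, y)
        assert est.beta0_ == pytest.approx(0.0, abs=1e-10)
        assert est.beta1_ == pytest.approx(1.0, abs=1e-10)

    def test_slope_sign_under_rescaling(self, clean_beta_data):
        d, y = clean_beta_data
        a = bd.LogitLinearDoseResponse().fit(d, y)
        b = bd.LogitLinearDoseResponse().fit(37.0 * d, y)
        assert a.beta1_ == pytest.approx(b.beta1_, abs=1e-10)


class TestHeavyTailed:
    def test_concordant_with_ols_without_outliers(self):
        hits = 0
        for seed in range(20):
            d, y = _beta_data(seed=seed, span=8.0)
            lrm = bd.LogitLinearDoseResponse().fit(d, y)
            hlrm = bd.HeavyTailedDoseResponse().fit(d, y)
            se = np.sqrt(np.diag(lrm.covariance_))
            if (abs(hlrm.beta0_ - lrm.beta0_) < 3 * se[0]
                    and abs(hlrm.beta1_ - lrm.beta1_) < 3 * se[1]):
                hits += 1
        assert hits >= 19

    def test_deterministic_given_data(self, clean_beta_data):
        d, y = clean_beta_data
        a = bd.HeavyTailedDoseResponse().fit(d, y)
        b = bd.HeavyTailedDoseResponse().fit(d, y)
        assert (a.beta0_, a.beta1_, a.scale_) == (b.beta0_, b.beta1_, b.scale_)

    def test_closer_to_truth_than_ols_under_contamination(self):
        """With a gross boundary outlier the t(3) fit tracks the true slope
        more often than least squares."""
        wins = 0
        n_rep = 200
        for seed in range(n_rep):
            d, y = _beta_data(seed=1000 + seed, span=8.0)
            y = y.copy()
            y[0] = 1e-5  # gross outlier at the lowest dose
            lrm = bd.LogitLinearDoseResponse().fit(d, y)
            hlrm = bd.HeavyTailedDoseResponse().fit(d, y)
            if abs(hlrm.beta1_ - 1.0) < abs(lrm.beta1_ - 1.0):
                wins += 1
        assert wins >= 0.7 * n_rep
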