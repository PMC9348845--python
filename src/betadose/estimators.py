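"""Scikit-learn style dose-response estimators.

Three single-curve estimators share one interface (``fit(X, y)`` with ``X``
the doses and ``y`` the observed effect fractions in (0,1), ``predict``
returning the fitted effect, trailing-underscore fitted attributes):

``BetaDoseResponse``
    Robust beta regression.  The response is beta-law distributed with mean
    linked to log dose through the logit and precision through a log link
    (optionally with a log-dose regressor).  Fitting minimises the density
    power divergence (DPD) with tuning parameter ``alpha``; ``alpha="auto"``
    selects it by the SQV stability search, ``alpha=0`` is maximum
    likelihood.

``LogitLinearDoseResponse``
    The classical approach: ordinary least squares of ``logit(y)`` on log
    dose (homoscedastic normal error on the logit scale).

``HeavyTailedDoseResponse``
    The same logit-linear model with scaled Student-t errors (default 3 df),
    fitted by maximum likelihood, as a conventional outlier-damping baseline.

All three expose ``potency`` / ``curve_band`` for delta-method inference on
derived drug-activity quantities (median-effect dose, dose at an arbitrary
effect level, Hill coefficient, effect at a dose).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._dpd import ALPHA_ZERO
from ._fitting import dpd_covariance, fit_dpd_design
from .alphasearch import AlphaSearchConfig, select_alpha
from .medianeffect import CurveParams, effect_at_dose, hill_coefficient
from . import inference

__all__ = [
    "BetaDoseResponse",
    "LogitLinearDoseResponse",
    "HeavyTailedDoseResponse",
]


def _validate_dose_response(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be a single dose column")
        X = X[:, 0]
    elif X.ndim != 1:
        raise ValueError("X must be 1d or a single-column 2d array")
    y = np.asarray(y, dtype=float)
    if y.shape != X.shape:
        raise ValueError("X and y length mismatch")
    if X.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(X).size < 2:
        raise ValueError("need at least 2 distinct doses")
    if np.any(X <= 0) or not np.all(np.isfinite(X)):
        raise ValueError("doses must be positive and finite")
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError(
            "responses must lie strictly inside (0, 1); run preprocessing "
            "truncation first"
        )
    return X, y


class _DoseResponseBase(RegressorMixin, BaseEstimator):
    """Shared prediction / inference surface of the fitted curve."""

    orientation = "affected"

    @property
    def curve_params_(self) -> CurveParams:
        check_is_fitted(self, "beta1_")
        return CurveParams(self.beta0_, self.beta1_, self.orientation)

    def predict(self, X):
        check_is_fitted(self, "beta1_")
        X = np.asarray(X, dtype=float)
        d = X[:, 0] if X.ndim == 2 else X
        return effect_at_dose(self.curve_params_, d)

    @property
    def hill_(self) -> float:
        return hill_coefficient(self.curve_params_)

    @property
    def ic50_(self) -> float:
        from .medianeffect import median_effect_dose

        return median_effect_dose(self.curve_params_)

    def _beta_cov(self):
        return np.asarray(self.covariance_)[:2, :2]

    def potency(self, quantity="median_effect_dose", level=0.5, dose=None,
                conf_level=0.95):
        """Delta-method point estimate, SE and CI for a derived quantity."""
        check_is_fitted(self, "beta1_")
        return inference.potency_from_params(
            self.beta0_, self.beta1_, self._beta_cov(), quantity=quantity,
            level=level, dose=dose, conf_level=conf_level,
            orientation=self.orientation, df=getattr(self, "df_", None),
        )

    def curve_band(self, dose_grid, conf_level=0.95):
        """Pointwise delta-method confidence band for the effect curve."""
        check_is_fitted(self, "beta1_")
        return inference.curve_band_from_params(
            self.beta0_, self.beta1_, self._beta_cov(), dose_grid, conf_level,
            df=getattr(self, "df_", None),
        )


class BetaDoseResponse(_DoseResponseBase):
    """Robust beta-regression dose-response curve (MDPDE).

    Parameters
    ----------
    alpha : float or "auto", default "auto"
        DPD tuning parameter in [0, alpha_max].  0 is maximum likelihood;
        "auto" runs the SQV stability search.
    precision : {"constant", "log_dose"}
        Precision submodel: constant ``phi`` or ``log phi = g0 + g1 ln d``.
    orientation : {"affected", "unaffected"}
        Fraction being modelled; fixes the Hill-coefficient sign.
    alpha_max, spacing, window, threshold_L
        SQV search settings (see :class:`~betadose.alphasearch.AlphaSearchConfig`).

    Attributes
    ----------
    beta0_, beta1_ : float
        Logit-scale intercept and log-dose slope.
    gamma_ : ndarray
        Log-link precision coefficients (length 1 or 2).
    alpha_ : float
        Tuning parameter actually used.
    covariance_ : ndarray
        Asymptotic covariance of ``(beta0, beta1, *gamma)``; inverse observed
        information at alpha=0, M-estimation sandwich otherwise.
    objective_value_ : float
        Minimised mean DPD objective (negative mean log-likelihood at 0).
    loglik_ : float
        Total beta log-likelihood at the estimate.
    alpha_trace_ : AlphaSearchTrace or None
        Search record when ``alpha="auto"``.
    """

    def __init__(self, alpha="auto", precision="constant", orientation="affected",
                 alpha_max=1.0, spacing=0.02, window=6, threshold_L=0.02):
        self.alpha = alpha
        self.precision = precision
        self.orientation = orientation
        self.alpha_max = alpha_max
        self.spacing = spacing
        self.window = window
        self.threshold_L = threshold_L

    def _designs(self, d):
        logd = np.log(d)
        Zm = np.column_stack([np.ones_like(logd), logd])
        if self.precision == "constant":
            Zp = np.ones((d.size, 1))
        elif self.precision == "log_dose":
            Zp = Zm.copy()
        else:
            raise ValueError("precision must be 'constant' or 'log_dose'")
        return Zm, Zp

    def fit(self, X, y):
        d, y = _validate_dose_response(X, y)
        Zm, Zp = self._designs(d)
        self.n_features_in_ = 1

        if self.alpha == "auto":
            config = AlphaSearchConfig(self.alpha_max, self.spacing,
                                       self.window, self.threshold_L)
            cache = {}
            last = {"theta": None}

            def fit_at(a):
                if a not in cache:
                    rf = fit_dpd_design(y, Zm, Zp, a, theta0=last["theta"])
                    rf.covariance = dpd_covariance(rf.theta, y, Zm, Zp, a)
                    last["theta"] = rf.theta
                    cache[a] = rf
                rf = cache[a]
                se = np.sqrt(np.diag(rf.covariance))
                return rf.theta, se, rf.n_obs

            alpha_opt, trace = select_alpha(fit_at, config)
            self.alpha_trace_ = trace
            rf = cache.get(alpha_opt)
            if rf is None:
                rf = fit_dpd_design(y, Zm, Zp, alpha_opt)
                rf.covariance = dpd_covariance(rf.theta, y, Zm, Zp, alpha_opt)
        else:
            a = float(self.alpha)
            if a < 0:
                raise ValueError("alpha must be nonnegative")
            rf = fit_dpd_design(y, Zm, Zp, a)
            rf.covariance = dpd_covariance(rf.theta, y, Zm, Zp, a)
            self.alpha_trace_ = None

        self.beta0_ = float(rf.theta[0])
        self.beta1_ = float(rf.theta[1])
        self.gamma_ = rf.theta[2:].copy()
        self.alpha_ = float(rf.alpha)
        # classical finite-sample calibration: df-adjusted covariance and
        # t(n-p) critical values downstream (exact in the Gaussian analogue)
        n, p = rf.n_obs, rf.n_params
        self.df_ = max(n - p, 1)
        self.covariance_ = rf.covariance * (n / self.df_ if n > p else 1.0)
        self.objective_value_ = rf.objective
        self.loglik_ = rf.loglik
        self.converged_ = rf.converged
        self.n_obs_ = rf.n_obs
        fitted_eta = Zm @ rf.theta[:2]
        if np.any(np.abs(fitted_eta) > 20):
            import warnings

            warnings.warn("fitted |logit(mu)| > 20 at a design point; "
                          "possible separation")
        return self

    def phi_at(self, dose):
        """Fitted precision ``phi(d)`` from the log-link submodel."""
        check_is_fitted(self, "gamma_")
        from ._dpd import precision_submodel

        return precision_submodel(dose, self.gamma_)


class LogitLinearDoseResponse(_DoseResponseBase):
    """Ordinary least squares of logit(y) on log dose (the classical LRM)."""

    def __init__(self, orientation="affected"):
        self.orientation = orientation

    def fit(self, X, y):
        import statsmodels.api as sm

        d, y = _validate_dose_response(X, y)
        self.n_features_in_ = 1
        ylogit = np.log(y) - np.log1p(-y)
        Z = sm.add_constant(np.log(d))
        res = sm.OLS(ylogit, Z).fit()
        self.beta0_ = float(res.params[0])
        self.beta1_ = float(res.params[1])
        self.covariance_ = np.asarray(res.cov_params())  # already df-adjusted
        self.sigma2_ = float(res.scale)
        self.loglik_ = float(res.llf)
        self.df_resid_ = float(res.df_resid)
        self.df_ = int(res.df_resid)
        self.n_obs_ = d.size
        self.converged_ = True
        return self


class HeavyTailedDoseResponse(_DoseResponseBase):
    """Logit-linear regression with scaled Student-t errors (default 3 df).

    ``logit(y) = beta1 ln d + beta0 + s*T``, ``T ~ t(df)``, fitted by maximum
    likelihood with covariance from the inverse observed information.
    """

    def __init__(self, df=3.0, orientation="affected"):
        self.df = df
        self.orientation = orientation

    def fit(self, X, y):
        d, y = _validate_dose_response(X, y)
        self.n_features_in_ = 1
        ylogit = np.log(y) - np.log1p(-y)
        logd = np.log(d)
        Z = np.column_stack([np.ones_like(logd), logd])
        b0, *_ = np.linalg.lstsq(Z, ylogit, rcond=None)
        resid = ylogit - Z @ b0
        s0 = max(float(np.std(resid)), 1e-3)
        nu = float(self.df)

        def nll(theta):
            r = ylogit - Z @ theta[:2]
            s = np.exp(theta[2])
            return -np.sum(t_dist.logpdf(r / s, df=nu) - theta[2])

        res = minimize(nll, np.r_[b0, np.log(s0)], method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-8})
        theta = res.x
        H = _numerical_hessian(nll, theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular Hessian in t-regression: {exc}") from exc
        self.beta0_ = float(theta[0])
        self.beta1_ = float(theta[1])
        self.scale_ = float(np.exp(theta[2]))
        n, p = d.size, 3
        self.df_ = max(n - p, 1)
        self.covariance_ = 0.5 * (cov + cov.T) * (n / self.df_ if n > p else 1.0)
        self.loglik_ = float(-res.fun)
        self.n_obs_ = d.size
        self.converged_ = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
        return self


def _numerical_hessian(f, x, rel_step=1e-5):
    p = x.size
    H = np.empty((p, p))
    h = rel_step * (1.0 + np.abs(x))
    for i in range(p):
        for j in range(i, p):
            xpp = x.copy(); xpp[[i, j]] += [h[i], h[j]]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H
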