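"""Joint multi-group dose-response fits.

One drug-response experiment typically carries several groups (agents, cell
lines).  Groups get independent curve parameters ``(beta0_g, beta1_g)`` and
per-group precision intercepts; when the log-dose precision regressor is
enabled its slope is shared across groups.  Constrained variants — common
curve (both intercept and slope shared) or common slope only — provide the
nested models for the likelihood-ratio comparisons.

Maximum-likelihood fits go through :class:`statsmodels` beta regression
(``BetaModel``); the robust MDPDE path uses this package's DPD core with one
tuning parameter shared across groups, selected on the pooled fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._dpd import ALPHA_ZERO
from ._fitting import dpd_covariance, fit_dpd_design
from .alphasearch import AlphaSearchConfig, select_alpha
from .medianeffect import CurveParams
from .preprocessing import DoseResponseDataset
from . import inference

__all__ = ["GroupedFit", "fit_mle", "fit_mdpde"]

_CONSTRAINTS = ("free", "shared_curve", "shared_slope")


def _as_frame(data):
    if isinstance(data, DoseResponseDataset):
        return data.data
    return data


def build_designs(df, constraint="free", precision="constant"):
    """Design matrices and parameter names for a grouped fit."""
    if constraint not in _CONSTRAINTS:
        raise ValueError(f"constraint must be one of {_CONSTRAINTS}")
    groups = list(pd.unique(df["group"]))
    G = len(groups)
    logd = np.log(df["dose"].to_numpy(float))
    n = len(df)
    gidx = df["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    dummies = np.zeros((n, G))
    dummies[np.arange(n), gidx] = 1.0

    if constraint == "free":
        Zm = np.zeros((n, 2 * G))
        Zm[:, 0::2] = dummies
        Zm[:, 1::2] = dummies * logd[:, None]
        mean_names = [f"{p}[{g}]" for g in groups for p in ("beta0", "beta1")]
    elif constraint == "shared_curve":
        Zm = np.column_stack([np.ones(n), logd])
        mean_names = ["beta0", "beta1"]
    else:  # shared_slope
        Zm = np.column_stack([dummies, logd])
        mean_names = [f"beta0[{g}]" for g in groups] + ["beta1"]

    Zp = dummies.copy()
    prec_names = [f"gamma0[{g}]" for g in groups]
    if precision == "log_dose":
        Zp = np.column_stack([Zp, logd])
        prec_names.append("gamma1")
    elif precision != "constant":
        raise ValueError("precision must be 'constant' or 'log_dose'")
    return Zm, Zp, groups, mean_names + prec_names


class GroupedFit:
    """Result of a joint multi-group fit.

    Attributes
    ----------
    theta_ : ndarray
        Full parameter vector (mean coefficients then precision
        coefficients, in ``param_names_`` order).
    covariance_ : ndarray
        Asymptotic covariance of ``theta_``.
    loglik_ : float
        Total beta log-likelihood at the estimate.
    alpha_ : float
        DPD tuning parameter used (0 for MLE).
    """

    def __init__(self, theta, covariance, loglik, alpha, groups, param_names,
                 constraint, precision, n_obs, objective=None, converged=True,
                 orientation="affected", alpha_trace=None):
        self.theta_ = np.asarray(theta, dtype=float)
        self.covariance_ = np.asarray(covariance, dtype=float)
        self.loglik_ = float(loglik)
        self.alpha_ = float(alpha)
        self.groups_ = list(groups)
        self.param_names_ = list(param_names)
        self.constraint = constraint
        self.precision = precision
        self.n_obs_ = int(n_obs)
        self.objective_value_ = objective
        self.converged_ = converged
        self.orientation = orientation
        self.alpha_trace_ = alpha_trace

    @property
    def n_params_(self):
        return self.theta_.size

    def _mean_index(self, group):
        g = self.groups_.index(group)
        if self.constraint == "free":
            return [2 * g, 2 * g + 1]
        if self.constraint == "shared_curve":
            return [0, 1]
        return [g, len(self.groups_)]  # shared_slope

    def curve_params(self, group) -> CurveParams:
        i0, i1 = self._mean_index(group)
        return CurveParams(float(self.theta_[i0]), float(self.theta_[i1]),
                           self.orientation)

    def beta_cov(self, group):
        idx = self._mean_index(group)
        return self.covariance_[np.ix_(idx, idx)]

    @property
    def df_(self):
        return max(self.n_obs_ - self.n_params_, 1)

    def potency(self, group, quantity="median_effect_dose", level=0.5,
                dose=None, conf_level=0.95):
        cp = self.curve_params(group)
        return inference.potency_from_params(
            cp.beta0, cp.beta1, self.beta_cov(group), quantity=quantity,
            level=level, dose=dose, conf_level=conf_level,
            orientation=self.orientation, df=self.df_)

    def curve_band(self, group, dose_grid, conf_level=0.95):
        cp = self.curve_params(group)
        return inference.curve_band_from_params(
            cp.beta0, cp.beta1, self.beta_cov(group), dose_grid, conf_level,
            df=self.df_)

    def log_dm_vector(self):
        """log median-effect dose per group, with delta-method covariance."""
        G = len(self.groups_)
        vals = np.empty(G)
        J = np.zeros((G, self.theta_.size))
        for i, g in enumerate(self.groups_):
            cp = self.curve_params(g)
            if abs(cp.beta1) < 1e-8:
                raise ZeroDivisionError(f"zero slope in group {g!r}")
            vals[i] = -cp.beta0 / cp.beta1
            i0, i1 = self._mean_index(g)
            J[i, i0] = -1.0 / cp.beta1
            J[i, i1] = cp.beta0 / cp.beta1**2
        cov = J @ self.covariance_ @ J.T
        return vals, cov


def fit_mle(data, precision="constant", constraint="free",
            orientation="affected") -> GroupedFit:
    """Maximum-likelihood grouped beta regression (statsmodels backend)."""
    from statsmodels.othermod.betareg import BetaModel

    df = _as_frame(data)
    y = df["response"].to_numpy(float)
    _check_fit_preconditions(df)
    Zm, Zp, groups, names = build_designs(df, constraint, precision)
    res = BetaModel(y, Zm, exog_precision=Zp).fit(disp=0)
    if not res.mle_retvals.get("converged", True):
        # polish with a second pass from the previous solution
        res = BetaModel(y, Zm, exog_precision=Zp).fit(
            start_params=res.params, method="bfgs", disp=0)
    n, p = len(df), len(names)
    cov = np.asarray(res.cov_params()) * (n / (n - p) if n > p else 1.0)
    return GroupedFit(res.params, cov, res.llf, 0.0, groups, names,
                      constraint, precision, len(df),
                      objective=-res.llf / len(df),
                      converged=bool(res.mle_retvals.get("converged", True)),
                      orientation=orientation)


def fit_mdpde(data, alpha="auto", precision="constant", constraint="free",
              orientation="affected",
              search: AlphaSearchConfig | None = None) -> GroupedFit:
    """Robust grouped beta regression via MDPDE.

    ``alpha`` may be a fixed value in [0, alpha_max] or ``"auto"`` for the
    SQV search; one alpha is shared by all groups (selected on the pooled
    objective).
    """
    df = _as_frame(data)
    y = df["response"].to_numpy(float)
    _check_fit_preconditions(df)
    Zm, Zp, groups, names = build_designs(df, constraint, precision)

    trace = None
    if alpha == "auto":
        search = search or AlphaSearchConfig()
        cache = {}
        last = {"theta": None}

        def fit_at(a):
            if a not in cache:
                rf = fit_dpd_design(y, Zm, Zp, a, theta0=last["theta"])
                rf.covariance = dpd_covariance(rf.theta, y, Zm, Zp, a)
                last["theta"] = rf.theta
                cache[a] = rf
            rf = cache[a]
            return rf.theta, np.sqrt(np.diag(rf.covariance)), rf.n_obs

        alpha, trace = select_alpha(fit_at, search)
        rf = cache.get(alpha)
        if rf is None:
            rf = fit_dpd_design(y, Zm, Zp, alpha)
            rf.covariance = dpd_covariance(rf.theta, y, Zm, Zp, alpha)
    else:
        alpha = float(alpha)
        rf = fit_dpd_design(y, Zm, Zp, alpha)
        rf.covariance = dpd_covariance(rf.theta, y, Zm, Zp, alpha)

    n, p = rf.n_obs, rf.n_params
    cov = rf.covariance * (n / (n - p) if n > p else 1.0)
    return GroupedFit(rf.theta, cov, rf.loglik, alpha, groups,
                      names, constraint, precision, len(df),
                      objective=rf.objective, converged=rf.converged,
                      orientation=orientation, alpha_trace=trace)


def _check_fit_preconditions(df):
    for g, sub in df.groupby("group", sort=False):
        if len(sub) < 3:
            raise ValueError(f"group {g!r}: need >= 3 observations")
        if sub["dose"].nunique() < 2:
            raise ValueError(f"group {g!r}: need >= 2 distinct doses")
    y = df["response"].to_numpy(float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("responses must lie strictly inside (0,1); "
                         "run preprocessing truncation first")
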