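"""Hypothesis tests comparing dose-response curves across groups.

Three global tests and a pairwise follow-up:

* model equality — likelihood-ratio test of a common curve (intercept and
  slope shared) against independent per-group curves; chi-square, 2(G-1) df.
* slope equality — LRT of a common Hill slope; chi-square, G-1 df.
* potency equality — Wald-type F test on the contrasts of per-group log
  median-effect doses, F(G-1, N-k) with k the free-model parameter count.
* pairwise potency — two-sided t tests of log-Dm differences for every
  ordered pair (df = N-k), Benjamini-Hochberg adjusted.

Likelihood-ratio tests are computed from maximum-likelihood fits (alpha = 0)
even when headline estimates use a robust alpha > 0: the chi-square
calibration of the LRT under DPD objectives is not established, so tests are
anchored to the likelihood.  Pairwise tests are reported unconditionally and
should be read as exploratory when the global potency test is not
significant.  Shared-curve and shared-slope fits constrain only the mean
submodel; per-group precision stays free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, f as f_dist, t as t_dist
from statsmodels.stats.multitest import multipletests

from .multigroup import GroupedFit, fit_mle

__all__ = [
    "TestResult",
    "test_model_equality",
    "test_slope_equality",
    "test_potency_equality",
    "pairwise_potency",
    "bh_adjust",
    "compare_groups",
]

_LRT_TOL = 1e-6


class NestingError(ValueError):
    """Shared-model likelihood exceeded the free-model likelihood."""


@dataclass
class TestResult:
    test: str
    statistic: float
    df: object
    p_value: float
    pairs: list = field(default_factory=list)

    def to_dict(self):
        stat = self.statistic if np.isfinite(self.statistic) else None
        d = {"test": self.test, "statistic": stat,
             "df": self.df, "p_value": self.p_value}
        if self.pairs:
            d["pairs"] = [
                {"group_i": a, "group_j": b, "estimate_diff": e,
                 "raw_p": p, "adjusted_p": q}
                for a, b, e, p, q in self.pairs
            ]
        return d


def _lrt(fit_free: GroupedFit, fit_shared: GroupedFit, df, name) -> TestResult:
    if fit_free.n_obs_ != fit_shared.n_obs_:
        raise ValueError("free and shared fits use different data")
    stat = 2.0 * (fit_free.loglik_ - fit_shared.loglik_)
    if stat < -_LRT_TOL * max(1.0, abs(fit_free.loglik_)):
        raise NestingError(
            f"shared log-likelihood exceeds free log-likelihood ({stat:.3g})")
    stat = max(stat, 0.0)
    if df <= 0:
        raise ValueError(f"{name}: test needs at least two groups")
    p = float(chi2.sf(stat, df))
    return TestResult(name, float(stat), int(df), p)


def test_model_equality(fit_free: GroupedFit, fit_shared: GroupedFit) -> TestResult:
    """LRT of one common curve against independent curves; 2(G-1) df."""
    G = len(fit_free.groups_)
    return _lrt(fit_free, fit_shared, 2 * (G - 1), "model_equality")


def test_slope_equality(fit_free: GroupedFit, fit_shared_slope: GroupedFit) -> TestResult:
    """LRT of a common Hill slope against free slopes; G-1 df."""
    G = len(fit_free.groups_)
    return _lrt(fit_free, fit_shared_slope, G - 1, "slope_equality")


def test_potency_equality(fit: GroupedFit) -> TestResult:
    """Wald-type F test that all median-effect doses are equal.

    Contrasts ``log Dm_g - log Dm_1`` (g = 2..G) with the delta-method
    covariance; F with (G-1, N-k) degrees of freedom, k the number of free
    parameters in ``fit``.
    """
    G = len(fit.groups_)
    if G < 2:
        raise ValueError("potency comparison needs >= 2 groups")
    vals, cov = fit.log_dm_vector()
    C = np.hstack([-np.ones((G - 1, 1)), np.eye(G - 1)])
    diff = C @ vals
    V = C @ cov @ C.T
    df2 = fit.n_obs_ - fit.n_params_
    if df2 <= 0:
        raise ValueError("nonpositive denominator degrees of freedom")
    stat = float(diff @ np.linalg.solve(V, diff)) / (G - 1)
    p = float(f_dist.sf(stat, G - 1, df2))
    return TestResult("potency_equality", stat, (G - 1, int(df2)), p)


def pairwise_potency(fit: GroupedFit, conf_level=0.95) -> TestResult:
    """BH-adjusted pairwise two-sided t tests on log Dm differences."""
    G = len(fit.groups_)
    if G < 2:
        raise ValueError("pairwise comparison needs >= 2 groups")
    vals, cov = fit.log_dm_vector()
    df = fit.n_obs_ - fit.n_params_
    pairs = []
    raw = []
    for i in range(G):
        for j in range(i + 1, G):
            diff = vals[i] - vals[j]
            se = np.sqrt(max(cov[i, i] + cov[j, j] - 2 * cov[i, j], 0.0))
            if se == 0:
                tstat, p = 0.0, 1.0
            else:
                tstat = diff / se
                p = float(2.0 * t_dist.sf(abs(tstat), df))
            pairs.append([fit.groups_[i], fit.groups_[j], float(diff), p])
            raw.append(p)
    adj = bh_adjust(raw)
    out = [(a, b, e, p, float(q)) for (a, b, e, p), q in zip(pairs, adj)]
    # summary p: smallest BH-adjusted p (evidence for any pair differing)
    return TestResult("pairwise_potency", float("nan"), int(df),
                      float(np.min(adj)), pairs=out)


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1d vector")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(data, precision="constant", orientation="affected"):
    """Run the full comparison suite on a multi-group dataset.

    Fits the free, shared-curve and shared-slope maximum-likelihood models
    and returns ``{test_name: TestResult}``.
    """
    free = fit_mle(data, precision=precision, constraint="free",
                   orientation=orientation)
    if len(free.groups_) < 2:
        raise ValueError("comparisons need at least two groups")
    shared = fit_mle(data, precision=precision, constraint="shared_curve",
                     orientation=orientation)
    shared_slope = fit_mle(data, precision=precision, constraint="shared_slope",
                           orientation=orientation)
    return {
        "model_equality": test_model_equality(free, shared),
        "slope_equality": test_slope_equality(free, shared_slope),
        "potency_equality": test_potency_equality(free),
        "pairwise_potency": pairwise_potency(free),
    }
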