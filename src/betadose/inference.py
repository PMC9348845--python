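"""Delta-method inference for drug-activity measurements.

Every quantity of interest is a smooth function of the logit-linear curve
parameters ``(beta0, beta1)``:

    log Dm         = -beta0/beta1                (median-effect dose, log)
    log dose(p)    = (logit(p) - beta0)/beta1    (dose at effect level p)
    Hill m         = +/- beta1
    effect(d)      = inv_logit(beta1 ln d + beta0)

Given the estimate and its covariance, the multivariate delta method yields a
standard error on a transformation-appropriate scale: log-dose scale for dose
quantities (so back-transformed intervals are positive) and the logit scale
for effects (so back-transformed bands stay inside (0,1)).  Intervals use
Student-t critical values with the fit's residual degrees of freedom when
available (``df=None`` falls back to the asymptotic normal quantile): the
delta method is asymptotic, and the t quantile is the usual finite-sample
concession for replicate-level assay data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, t as t_dist

from .medianeffect import SLOPE_TOL, SlopeZeroError, inv_logit, logit

__all__ = ["PotencyEstimate", "potency_from_params", "curve_band_from_params"]

_QUANTITIES = ("median_effect_dose", "dose_at_effect", "hill", "effect_at_dose")

# strictly-inside-(0,1) clamp for back-transformed effects: keeps bands open
# even when the logit-scale interval runs past float saturation
_ONE_MINUS = float(np.nextafter(1.0, 0.0))


def _unit_open(x):
    return float(min(max(x, 1e-300), _ONE_MINUS))


@dataclass(frozen=True)
class PotencyEstimate:
    """Point estimate with delta-method SE and confidence interval.

    ``point``/``ci_low``/``ci_high`` are on the natural reporting scale;
    ``se`` is on the delta scale noted in ``scale`` ("log" for dose
    quantities, "logit" for effects, "natural" for the Hill coefficient).
    """

    quantity: str
    point: float
    se: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    level: float | None = None
    dose: float | None = None
    scale: str = "natural"

    def __post_init__(self):
        if not (self.ci_low <= self.point <= self.ci_high or np.isnan(self.se)):
            raise ValueError("confidence interval does not bracket the point")


def _delta(gradient, cov):
    var = float(np.asarray(gradient) @ np.asarray(cov) @ np.asarray(gradient))
    return np.sqrt(max(var, 0.0))


def _crit(conf_level, df):
    q = 1.0 - (1.0 - conf_level) / 2.0
    return float(norm.ppf(q) if df is None else t_dist.ppf(q, df))


def potency_from_params(beta0, beta1, cov, quantity="median_effect_dose",
                        level=0.5, dose=None, conf_level=0.95,
                        orientation="affected", df=None):
    """Delta-method estimate for one drug-activity quantity.

    ``cov`` is the 2x2 covariance of ``(beta0, beta1)``; ``df`` the residual
    degrees of freedom for the t critical value (None for normal).
    """
    if quantity not in _QUANTITIES:
        raise ValueError(f"quantity must be one of {_QUANTITIES}")
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    cov = np.asarray(cov, dtype=float)
    z = _crit(conf_level, df)

    if quantity in ("median_effect_dose", "dose_at_effect"):
        if abs(beta1) < SLOPE_TOL:
            raise SlopeZeroError("dose quantities undefined at zero slope")
        lp = 0.0 if quantity == "median_effect_dose" else logit(level)
        log_dose = (lp - beta0) / beta1
        grad = np.array([-1.0 / beta1, -(lp - beta0) / beta1**2])
        se = _delta(grad, cov)
        lo, hi = log_dose - z * se, log_dose + z * se
        est = PotencyEstimate(quantity, float(np.exp(log_dose)), se,
                              float(np.exp(lo)), float(np.exp(hi)),
                              conf_level,
                              level=(0.5 if quantity == "median_effect_dose"
                                     else float(level)),
                              scale="log")
    elif quantity == "hill":
        sign = 1.0 if orientation == "affected" else -1.0
        point = sign * beta1
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
        est = PotencyEstimate("hill", float(point), se,
                              float(point - z * se), float(point + z * se),
                              conf_level, scale="natural")
    else:  # effect_at_dose
        if dose is None or dose <= 0:
            raise ValueError("effect_at_dose requires a positive dose")
        eta = beta1 * np.log(dose) + beta0
        grad = np.array([1.0, np.log(dose)])
        se = _delta(grad, cov)
        lo, hi = eta - z * se, eta + z * se
        est = PotencyEstimate("effect_at_dose", _unit_open(inv_logit(eta)), se,
                              _unit_open(inv_logit(lo)),
                              _unit_open(inv_logit(hi)),
                              conf_level, dose=float(dose), scale="logit")

    if est.point != 0 and np.isfinite(est.se) and est.se / max(abs(_delta_scale_point(est)), 1e-300) > 10:
        warnings.warn(f"unstable CI for {quantity}: delta-scale SE/point > 10")
    return est


def _delta_scale_point(est: PotencyEstimate) -> float:
    if est.scale == "log":
        return np.log(est.point) if est.point > 0 else np.inf
    if est.scale == "logit":
        return logit(est.point)
    return est.point


def curve_band_from_params(beta0, beta1, cov, dose_grid, conf_level=0.95,
                           df=None):
    """Pointwise delta-method band for the effect curve on a dose grid.

    Returns a list of ``PotencyEstimate`` (quantity "effect_at_dose"), one
    per grid dose; constructed on the logit scale so the band stays in (0,1).
    """
    dose_grid = np.asarray(dose_grid, dtype=float)
    if np.any(dose_grid <= 0):
        raise ValueError("dose grid must be positive")
    cov = np.asarray(cov, dtype=float)
    z = _crit(conf_level, df)
    logd = np.log(dose_grid)
    eta = beta1 * logd + beta0
    var = (cov[0, 0] + 2.0 * logd * cov[0, 1] + logd**2 * cov[1, 1])
    se = np.sqrt(np.clip(var, 0.0, None))
    out = []
    for d, e, s in zip(dose_grid, eta, se):
        out.append(PotencyEstimate(
            "effect_at_dose", _unit_open(inv_logit(e)), float(s),
            _unit_open(inv_logit(e - z * s)), _unit_open(inv_logit(e + z * s)),
            conf_level, dose=float(d), scale="logit"))
    return out
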