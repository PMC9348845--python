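"""Median-effect equation: deterministic curve math.

The median-effect model of mass action links a drug concentration ``d`` to the
affected fraction ``fa`` through ``fa/fu = (d/Dm)**m`` with ``fu = 1 - fa``.
On the logit scale this is linear in log dose,

    logit(E) = beta1 * ln(d) + beta0,

so the median-effect dose is ``Dm = exp(-beta0/beta1)`` and the Hill
coefficient is ``beta1`` when the affected fraction is modelled (``-beta1``
for the unaffected fraction).  All logarithms here are natural.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "CurveParams",
    "logit",
    "inv_logit",
    "effect_at_dose",
    "median_effect_dose",
    "dose_for_effect",
    "hill_coefficient",
]

Orientation = Literal["affected", "unaffected"]

#: slopes smaller than this are treated as zero (dose quantities undefined)
SLOPE_TOL = 1e-8


class SlopeZeroError(ZeroDivisionError):
    """Raised when a dose-type quantity is requested with slope ~ 0."""


@dataclass(frozen=True)
class CurveParams:
    """Logit-linear curve parameters.

    Parameters
    ----------
    beta0 : float
        Intercept on the logit scale.
    beta1 : float
        Slope with respect to natural-log dose.
    orientation : {"affected", "unaffected"}
        Whether the modelled fraction is the affected (``fa``) or unaffected
        (``fu``) fraction; this fixes the sign of the Hill coefficient.
    """

    beta0: float
    beta1: float
    orientation: Orientation = "affected"

    def __post_init__(self) -> None:
        if self.orientation not in ("affected", "unaffected"):
            raise ValueError(f"invalid orientation {self.orientation!r}")


def _check_effect_level(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("effect level must lie strictly inside (0, 1)")
    return p


def logit(p):
    """log(p / (1 - p)) for p strictly inside (0, 1).

    Accepts scalars or arrays; raises ``ValueError`` on boundary values.
    """
    p = _check_effect_level(p)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """exp(x)/(1 + exp(x)), overflow-safe for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out) if out.ndim == 0 else out


def effect_at_dose(params: CurveParams, d):
    """Expected effect ``inv_logit(beta1 * ln d + beta0)`` at dose ``d > 0``."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0.0) or not np.all(np.isfinite(d)):
        raise ValueError("dose must be a positive finite number")
    out = inv_logit(params.beta1 * np.log(d) + params.beta0)
    return float(out) if np.ndim(out) == 0 else out


def median_effect_dose(params: CurveParams) -> float:
    """Dm = exp(-beta0 / beta1): the dose producing a 50% effect."""
    if abs(params.beta1) < SLOPE_TOL:
        raise SlopeZeroError("median-effect dose undefined for zero slope")
    return float(np.exp(-params.beta0 / params.beta1))


def dose_for_effect(params: CurveParams, p) -> float:
    """Dose producing effect level ``p``: exp((logit(p) - beta0)/beta1).

    Generalises the median-effect dose to arbitrary target levels (IC90 is
    ``dose_for_effect(params, 0.9)`` for an inhibition curve with rising
    orientation); at ``p = 0.5`` it equals :func:`median_effect_dose`.
    """
    if abs(params.beta1) < SLOPE_TOL:
        raise SlopeZeroError("dose undefined for zero slope")
    lp = logit(p)
    out = np.exp((lp - params.beta0) / params.beta1)
    return float(out) if np.ndim(out) == 0 else out


def hill_coefficient(params: CurveParams) -> float:
    """Hill coefficient m: beta1 for affected orientation, -beta1 otherwise."""
    return float(params.beta1 if params.orientation == "affected" else -params.beta1)
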