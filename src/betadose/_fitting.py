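"""Numerical core: DPD minimisation over design matrices and covariance.

The mean submodel is ``logit(mu_i) = Zm[i] @ b`` and the precision submodel
``log(phi_i) = Zp[i] @ g``; constrained multi-group fits are expressed purely
through the columns of ``Zm``/``Zp``.  Optimisation is quasi-Newton
(L-BFGS-B) on the unconstrained parameter vector with the analytic gradient
from :mod:`betadose._dpd`, multi-started from a logit-scale OLS fit and a
conservative fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._dpd import ALPHA_ZERO, dpd_objective_design, dpd_pointwise, dpd_pointwise_grad_theta
from .medianeffect import inv_logit

__all__ = ["FitResult", "fit_dpd_design", "dpd_covariance", "start_values"]

# box keeps exp() finite; log-precision cap ~ phi <= 9e6
_B_BOUND = (-80.0, 80.0)
_G_BOUND = (-7.0, 16.0)


class ConvergenceError(RuntimeError):
    pass


class SingularHessianError(np.linalg.LinAlgError):
    pass


@dataclass
class FitResult:
    theta: np.ndarray
    objective: float
    loglik: float
    alpha: float
    converged: bool
    n_obs: int
    n_params: int
    message: str = ""
    covariance: np.ndarray | None = field(default=None)


def _moment_precision(y, mu):
    resid = y - mu
    v = float(np.var(resid))
    mw = float(np.mean(mu * (1.0 - mu)))
    phi0 = mw / v - 1.0 if v > 0 else 1e4
    return float(np.clip(phi0, 2.0, 1e4))


def _pack(b, phi0, Zp):
    g = np.zeros(Zp.shape[1])
    g[0] = np.log(phi0)
    return np.concatenate([b, g])


def start_values(y, Zm, Zp):
    """OLS of logit(y) on Zm plus a moment-matched precision start."""
    ylog = np.log(y) - np.log1p(-y)
    b, *_ = np.linalg.lstsq(Zm, ylog, rcond=None)
    mu = inv_logit(Zm @ b)
    return _pack(b, _moment_precision(y, mu), Zp)


def start_values_robust(y, Zm, Zp, iters=15):
    """Huber IRLS of logit(y) on Zm: an outlier-resistant start.

    Gross boundary responses produce huge logit leverage that can pull the
    plain OLS start into a shallow compromise basin of the DPD objective;
    the Huber line starts the optimiser near the uncontaminated curve.
    """
    ylog = np.log(y) - np.log1p(-y)
    b, *_ = np.linalg.lstsq(Zm, ylog, rcond=None)
    for _ in range(iters):
        r = ylog - Zm @ b
        mad = np.median(np.abs(r - np.median(r)))
        c = 1.345 * max(1.4826 * mad, 1e-8)
        w = np.minimum(1.0, c / np.maximum(np.abs(r), 1e-12))
        Wz = Zm * w[:, None]
        b_new, *_ = np.linalg.lstsq(Wz.T @ Zm, Wz.T @ ylog, rcond=None)
        if np.max(np.abs(b_new - b)) < 1e-10:
            b = b_new
            break
        b = b_new
    mu = inv_logit(Zm @ b)
    return _pack(b, _moment_precision(y, mu), Zp)


def _safe_objective(theta, y, Zm, Zp, alpha):
    """DPD objective with a smooth barrier for the integrability region.

    For alpha > 0 the closed-form K term requires ``(1+alpha)*shape > alpha``
    for both beta shapes at every observation.  Line searches can step
    outside that region; a linear penalty on the violation (with matching
    gradient) steers them back without raising.
    """
    pm = Zm.shape[1]
    if alpha > ALPHA_ZERO:
        eta = Zm @ theta[:pm]
        zeta = Zp @ theta[pm:]
        mu = inv_logit(eta)
        phi = np.exp(zeta)
        margin = alpha * (1.0 + 1e-6)
        ap = (1.0 + alpha) * mu * phi - margin
        bp = (1.0 + alpha) * (1.0 - mu) * phi - margin
        va = np.clip(-ap, 0.0, None)
        vb = np.clip(-bp, 0.0, None)
        if va.any() or vb.any():
            C = 1e6
            value = C * float(np.sum(va + vb))
            # d ap/d eta = (1+alpha) phi mu(1-mu); d ap/d zeta = (1+alpha) mu phi
            w = (1.0 + alpha) * phi * mu * (1.0 - mu)
            deta = -w * (va > 0) + w * (vb > 0)
            dzeta = (-(1.0 + alpha) * mu * phi * (va > 0)
                     - (1.0 + alpha) * (1.0 - mu) * phi * (vb > 0))
            grad = C * np.concatenate([Zm.T @ deta, Zp.T @ dzeta])
            return value + 1e3, grad
    return dpd_objective_design(theta, y, Zm, Zp, alpha)


def _minimize(theta0, y, Zm, Zp, alpha):
    pm = Zm.shape[1]
    bounds = [_B_BOUND] * pm + [_G_BOUND] * Zp.shape[1]
    return minimize(
        _safe_objective,
        theta0,
        args=(y, Zm, Zp, alpha),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-9},
    )


def fit_dpd_design(y, Zm, Zp, alpha, theta0=None):
    """Minimise the mean DPD objective; returns a :class:`FitResult`.

    ``theta0`` (e.g. the solution at a neighbouring alpha) is tried first;
    the OLS start and a conservative (b=0, phi=10) start are always tried as
    well and the best objective wins.
    """
    y = np.asarray(y, dtype=float)
    starts = []
    if theta0 is not None:
        # warm start (e.g. the neighbouring grid alpha) is reliable on its
        # own; the cold starts below are kept as fallbacks only
        starts.append(np.asarray(theta0, dtype=float))
    else:
        starts.append(start_values(y, Zm, Zp))
        starts.append(start_values_robust(y, Zm, Zp))
        cons = np.zeros(Zm.shape[1] + Zp.shape[1])
        cons[Zm.shape[1]] = np.log(10.0)
        starts.append(cons)

    best = None
    for s in starts:
        try:
            res = _minimize(s, y, Zm, Zp, alpha)
        except FloatingPointError:  # pragma: no cover - defensive
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("all optimisation starts failed")

    theta = np.asarray(best.x, dtype=float)
    rho0, _, _ = dpd_pointwise(y, Zm @ theta[: Zm.shape[1]], Zp @ theta[Zm.shape[1]:], 0.0)
    loglik = float(-np.sum(rho0))
    return FitResult(
        theta=theta,
        objective=float(best.fun),
        loglik=loglik,
        alpha=float(alpha),
        converged=bool(best.success),
        n_obs=y.size,
        n_params=theta.size,
        message=str(best.message),
    )


def _hessian(theta, y, Zm, Zp, alpha):
    """Central finite differences of the analytic gradient of the mean objective."""
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        _, gp = dpd_objective_design(tp, y, Zm, Zp, alpha)
        _, gm = dpd_objective_design(tm, y, Zm, Zp, alpha)
        H[j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def dpd_covariance(theta, y, Zm, Zp, alpha):
    """Asymptotic covariance of the minimiser of the mean DPD objective.

    At ``alpha = 0`` this is the inverse observed information of the total
    log-likelihood.  For ``alpha > 0`` it is the M-estimation sandwich
    ``J^-1 K J^-1 / n`` with ``J`` the Hessian of the mean objective and ``K``
    the empirical second moment of the per-observation gradients.
    """
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = y.size
    J = _hessian(theta, y, Zm, Zp, alpha)
    try:
        Jinv = np.linalg.inv(J)
    except np.linalg.LinAlgError as exc:
        raise SingularHessianError(str(exc)) from exc
    if alpha <= ALPHA_ZERO:
        cov = Jinv / n
    else:
        U = dpd_pointwise_grad_theta(theta, y, Zm, Zp, alpha)
        K = (U.T @ U) / n
        cov = Jinv @ K @ Jinv / n
    cov = 0.5 * (cov + cov.T)
    if not np.all(np.isfinite(cov)):
        raise SingularHessianError("non-finite covariance")
    return cov
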