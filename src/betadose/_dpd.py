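"""Beta-law density power divergence: objective, closed-form integral, gradients.

The beta law is parameterised by mean ``mu`` and precision ``phi`` with shapes
``a = mu*phi`` and ``b = (1-mu)*phi`` (variance ``mu*(1-mu)/(1+phi)``).  The
density power divergence (DPD) objective for tuning parameter ``alpha > 0`` is

    H_n(theta) = n^{-1} sum_i [ K_i(theta) - (1+alpha)/alpha * g_i(y_i)^alpha ]

where ``g_i`` is the beta density at observation ``i`` and

    K_i = int_0^1 g_i(y)^{1+alpha} dy
        = B((1+a)*a_i - a, (1+a)*b_i - a) / B(a_i, b_i)^{1+alpha}

(the closed form holds whenever both transformed shapes are positive).  At
``alpha = 0`` the objective is the negative mean log-likelihood, which the DPD
family approaches continuously; ``alpha = 1`` is the L2 divergence.

Gradients are analytic, propagated through the logit link for the mean and
the log link for the precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, digamma, gammaln

from .medianeffect import inv_logit

__all__ = [
    "beta_logdensity",
    "dpd_integral_K",
    "dpd_objective",
    "precision_submodel",
    "IntegrabilityError",
]

#: below this, alpha is treated as exactly zero (likelihood disparity branch)
ALPHA_ZERO = 1e-8


class IntegrabilityError(ValueError):
    """g^(1+alpha) is not integrable for the given shape parameters."""


def _shapes(mu, phi):
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    return mu * phi, (1.0 - mu) * phi


def beta_logdensity(y, mu, phi):
    """Log density of Beta(mu*phi, (1-mu)*phi) at y in (0,1), via log-gamma."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("y must lie strictly inside (0, 1)")
    a, b = _shapes(mu, phi)
    out = (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)
    return float(out) if out.ndim == 0 else out


def dpd_integral_K(mu, phi, alpha):
    """Closed-form ``int_0^1 g(y)^(1+alpha) dy`` for the beta density g.

    Requires ``(1+alpha)*mu*phi - alpha > 0`` and
    ``(1+alpha)*(1-mu)*phi - alpha > 0``; otherwise the integral diverges and
    :class:`IntegrabilityError` is raised.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    a, b = _shapes(mu, phi)
    ap = (1.0 + alpha) * a - alpha
    bp = (1.0 + alpha) * b - alpha
    if np.any(ap <= 0) or np.any(bp <= 0):
        raise IntegrabilityError(
            "g^(1+alpha) not integrable: transformed shape <= 0 "
            f"(alpha={alpha}, min shapes {np.min(ap):.4g}, {np.min(bp):.4g})"
        )
    out = np.exp(betaln(ap, bp) - (1.0 + alpha) * betaln(a, b))
    return float(out) if np.ndim(out) == 0 else out


def precision_submodel(dose, gamma):
    """Dose-dependent precision ``phi(d) = exp(gamma0 + gamma1 * ln d)``.

    ``gamma`` has length 1 (constant precision) or 2 (log-dose regressor).
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be positive")
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    eta = gamma[0]
    if gamma.size > 1:
        eta = eta + gamma[1] * np.log(dose)
    out = np.exp(eta)
    return float(out) if np.ndim(out) == 0 else out * np.ones_like(dose)


# ---------------------------------------------------------------------------
# objective + gradient on the linear-predictor scale
# ---------------------------------------------------------------------------

def _loglik_terms(y, eta, zeta):
    """Per-obs log density and its partials w.r.t. eta (logit mean) and
    zeta (log precision)."""
    # keep mu strictly inside (0,1) in float64; |eta|>30 is already flat
    mu = inv_logit(np.clip(eta, -30.0, 30.0))
    phi = np.exp(zeta)
    a = mu * phi
    b = (1.0 - mu) * phi
    ly = np.log(y)
    l1y = np.log1p(-y)
    logg = (a - 1.0) * ly + (b - 1.0) * l1y - betaln(a, b)
    psa = digamma(a)
    psb = digamma(b)
    psab = digamma(a + b)
    # d logg / d eta = phi * mu(1-mu) * (logit(y) - (psi(a)-psi(b)))
    dl_deta = phi * mu * (1.0 - mu) * ((ly - l1y) - (psa - psb))
    # d logg / d zeta = phi * (mu(ln y - psi a) + (1-mu)(ln(1-y) - psi b) + psi(a+b))
    dl_dzeta = phi * (mu * (ly - psa) + (1.0 - mu) * (l1y - psb) + psab)
    return logg, dl_deta, dl_dzeta, mu, phi, a, b, psa, psb, psab


def dpd_pointwise(y, eta, zeta, alpha):
    """Per-observation DPD contribution and its partials.

    Returns ``(rho, drho_deta, drho_dzeta)`` where ``rho_i`` is the summand of
    the mean objective.  ``alpha <= ALPHA_ZERO`` gives the negative log
    density (likelihood disparity branch).
    """
    logg, dl_deta, dl_dzeta, mu, phi, a, b, psa, psb, psab = _loglik_terms(y, eta, zeta)
    if alpha <= ALPHA_ZERO:
        return -logg, -dl_deta, -dl_dzeta

    ap = (1.0 + alpha) * a - alpha
    bp = (1.0 + alpha) * b - alpha
    if np.any(ap <= 0) or np.any(bp <= 0):
        raise IntegrabilityError(
            f"g^(1+alpha) not integrable at alpha={alpha}: shapes too small"
        )
    K = np.exp(betaln(ap, bp) - (1.0 + alpha) * betaln(a, b))
    psap = digamma(ap)
    psbp = digamma(bp)
    psabp = digamma(ap + bp)
    dK_da = K * (1.0 + alpha) * (psap - psabp - psa + psab)
    dK_db = K * (1.0 + alpha) * (psbp - psabp - psb + psab)
    dK_deta = phi * mu * (1.0 - mu) * (dK_da - dK_db)
    dK_dzeta = phi * (mu * dK_da + (1.0 - mu) * dK_db)

    galpha = np.exp(alpha * logg)
    c = (1.0 + alpha) / alpha
    rho = K - c * galpha
    drho_deta = dK_deta - (1.0 + alpha) * galpha * dl_deta
    drho_dzeta = dK_dzeta - (1.0 + alpha) * galpha * dl_dzeta
    return rho, drho_deta, drho_dzeta


def dpd_objective_design(theta, y, Zm, Zp, alpha):
    """Mean DPD objective and gradient for a design-matrix parameterisation.

    ``theta`` concatenates mean coefficients ``b`` (eta = Zm @ b) and
    precision coefficients ``g`` (log phi = Zp @ g).
    """
    pm = Zm.shape[1]
    b = theta[:pm]
    g = theta[pm:]
    eta = Zm @ b
    zeta = Zp @ g
    rho, de, dz = dpd_pointwise(y, eta, zeta, alpha)
    n = y.shape[0]
    value = float(np.mean(rho))
    grad = np.concatenate([Zm.T @ de, Zp.T @ dz]) / n
    return value, grad


def dpd_pointwise_grad_theta(theta, y, Zm, Zp, alpha):
    """n x p matrix of per-observation gradients of rho_i w.r.t. theta."""
    pm = Zm.shape[1]
    eta = Zm @ theta[:pm]
    zeta = Zp @ theta[pm:]
    _, de, dz = dpd_pointwise(y, eta, zeta, alpha)
    return np.hstack([Zm * de[:, None], Zp * dz[:, None]])


def dpd_objective(theta_mean, theta_prec, dose, y, alpha):
    """Mean DPD objective for a single curve (convenience wrapper).

    ``theta_mean = (beta0, beta1)``; ``theta_prec`` is the log-link precision
    coefficient vector (length 1 or 2).
    """
    dose = np.asarray(dose, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("responses must lie strictly inside (0, 1)")
    logd = np.log(dose)
    Zm = np.column_stack([np.ones_like(logd), logd])
    theta_prec = np.atleast_1d(np.asarray(theta_prec, dtype=float))
    if theta_prec.size == 1:
        Zp = np.ones((y.size, 1))
    else:
        Zp = np.column_stack([np.ones_like(logd), logd])
    theta = np.concatenate([np.asarray(theta_mean, dtype=float), theta_prec])
    value, _ = dpd_objective_design(theta, y, Zm, Zp, alpha)
    return value
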