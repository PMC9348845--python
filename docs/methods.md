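# Methods

## Model

The median-effect equation links the affected fraction `fa` at concentration
`d` to the unaffected fraction `fu = 1 − fa` through
`fa/fu = (d/Dm)^m`.  Writing `E` for the modelled effect fraction this is
log-linear on the logit scale,

    logit(E) = β₁ ln d + β₀ ,

so `Dm = exp(−β₀/β₁)`, the dose at effect level `p` is
`exp((logit p − β₀)/β₁)`, and the Hill coefficient is `β₁` when the
affected fraction is modelled and `−β₁` for the unaffected fraction.  All
internal logarithms are natural; display on log₁₀ axes is a plotting choice
that never enters estimation.

Observed fractions are modelled with the beta law in its mean/precision
parameterisation, `y ~ Beta(μφ, (1−μ)φ)` with `μ = logit⁻¹(β₁ ln d + β₀)`
and `Var(y) = μ(1−μ)/(1+φ)`.  The precision can depend on dose through a
log link, `ln φ = γ₀ + γ₁ ln d`, which captures assays whose replicate
spread shrinks or grows with concentration.  The model assumes responses
are conditionally independent given dose and that one smooth logit-linear
curve spans the tested range (full efficacy at saturating dose); compounds
with a lower plateau below 100% would need an Emax-type mean function,
which is out of scope.

## Robust estimation (MDPDE)

Maximum likelihood for the beta regression is still outlier-sensitive, so
the parameters are estimated by minimising the mean density power
divergence objective

    H_n(θ) = n⁻¹ Σᵢ [ Kᵢ(θ) − (1+α)/α · gᵢ(yᵢ)^α ] ,

where `gᵢ` is the beta density at observation `i` and
`Kᵢ = ∫₀¹ gᵢ^{1+α} dy` has the closed form
`B((1+α)aᵢ−α, (1+α)bᵢ−α)/B(aᵢ,bᵢ)^{1+α}` for shapes `aᵢ = μᵢφᵢ`,
`bᵢ = (1−μᵢ)φᵢ` (valid whenever both transformed shapes are positive; the
implementation raises an integrability error otherwise and the optimiser is
kept inside the valid region by a linear penalty barrier).  At `α = 0` the
objective is the negative mean log-likelihood — the estimator *is* the MLE
— and `α = 1` is the L2 divergence.  The tuning parameter therefore
interpolates efficiency against robustness; values around 0.3–0.4 give
strong outlier resistance at modest efficiency cost.

Optimisation is L-BFGS-B on `(β, γ)` with the analytic gradient
(propagated through the logit and log links), box bounds `|β| ≤ 80`,
`γ ∈ [−7, 16]` purely to keep exponentials finite, and multi-start: a
logit-scale OLS start with moment-matched precision, a Huber-IRLS robust
start (gross boundary responses can pull the OLS start into a shallow
compromise basin of the DPD objective), and a conservative `(β = 0,
φ = 10)` fallback; the best objective wins.  Warm starts chain the fits
along the `α` grid.

## Choosing α (SQV stability search)

The search fits the MDPDE on the grid `α = 0, ρ, 2ρ, …, α_max`
(defaults `ρ = 0.02`, `α_max = 1`) and monitors the standardized quadratic
variation between neighbouring grid points,

    SQV_k = ‖z_{k} − z_{k+1}‖ / p ,      z_k = θ̂(α_k) / se₀ ,

with `p` the parameter count and `se₀` the standard errors of the baseline
(α = 0) fit.  A window of 6 consecutive grid points passes when every SQV
in it falls below `L = 0.02`; the selected α is the smallest α of the
first passing window.  On failure the search restarts just past the
largest failing grid point (restarting *at* it would re-test a pair that
deterministically fails again); if the grid is exhausted the search falls
back to `α = 0`.

Two design choices matter here.  First, the standardization uses the
*baseline* standard errors rather than the per-α sandwich errors, and no
`√n` factor: drift of the estimate along the α path scales with the
statistical uncertainty itself, so this statistic is invariant to sample
size and is not drowned by the sampling jitter of re-estimated standard
errors (with per-α errors scaled by `√n` the criterion is never met at any
realistic `n` and the search would degenerate to always returning 0).
Second, the threshold/spacing pair was fixed once against the behaviour
the method is meant to have: on uncontaminated beta-law data the
first window is stable in ≳90% of samples (selected α ≈ 0), while gross
boundary outliers keep the estimate drifting (SQV ≈ 2–3 L) until they are
fully downweighted, which lands the selection at α ≈ 0.3–0.4.  Datasets
whose draws merely *look* extreme (a 3% true effect at the lowest dose)
occasionally trigger a positive α as well — that is the search correctly
flagging influential points, not a false alarm.

A fixed α can always be supplied to bypass the search.  In multi-group
fits one α is shared across groups and selected on the pooled objective;
groups keep independent curve parameters and precision intercepts (the
log-dose precision slope, when enabled, is shared).

## Covariance and intervals

At `α = 0` the covariance is the inverse observed information.  For
`α > 0` it is the M-estimation sandwich `J⁻¹KJ⁻¹/n` with `J` the numerical
Hessian of the mean objective (central differences of the analytic
gradient) and `K` the empirical second moment of per-observation
gradients; at large `n` its delta-method CI for `log Dm` matches a
parametric-bootstrap percentile CI to well under 1%.

Replicate-level assay data are small (a 7-dose × 3-replicate experiment
has n = 21), where the raw asymptotic covariance is optimistic: the
precision MLE is biased upward (analogous to the `n` vs `n−k` divisor for
a Gaussian variance) and the estimator has finite-sample variance excess.
The package therefore applies the classical finite-sample construction —
covariance scaled by `n/(n−p)` and Student-t (or F) critical values with
`n−p` degrees of freedom — uniformly across estimators; it is exact in the
Gaussian linear analogue and brings the beta-regression Wald coverage at
n = 21 from ≈ 0.89 to ≈ 0.94.

Derived quantities use the multivariate delta method on a
transformation-appropriate scale: log-dose for `Dm` and dose-at-level
(gradient `(−1/β₁, −(logit p − β₀)/β₁²)`), giving positive back-transformed
endpoints, and logit for pointwise curve bands, keeping them inside (0,1).
Dose quantities are undefined at `β₁ = 0` (singularity error below
`|β₁| < 10⁻⁸`), and a warning flags delta-scale SE/point ratios above 10.

## Comparing curves

Model equality (common `β₀, β₁` across G groups, 2(G−1) df) and slope
equality (common `β₁`, G−1 df) are likelihood-ratio tests against the
free fit, referred to chi-square; at the default study size their
empirical size at nominal 5% is 5–6%.  The LRTs are always computed from
maximum-likelihood fits even when the headline estimates are robust,
because chi-square calibration of likelihood ratios under DPD objectives
is not established; the report says so.  Constrained fits share only the
mean-curve parameters — per-group precision stays free, since the tests
target the curve, not the dispersion.

Potency equality is a Wald-type F test on the contrasts of per-group
`log D̂m` with the delta-method covariance, `F(G−1, N−k)` where `k` counts
the free-model parameters; for G = 2 it is exactly the squared pairwise t.
Pairwise contrasts use two-sided t tests (`df = N−k`) with
Benjamini-Hochberg step-up adjustment (statsmodels), computed
unconditionally but flagged as exploratory when the global test is not
significant.  Maximum-likelihood grouped fits go through statsmodels'
beta regression; the package's own DPD path at `α = 0` agrees with it to
< 10⁻⁴ per parameter, which doubles as a cross-implementation check.

## Preprocessing

Input CSVs are read positionally (dose, response, group; one header row).
Responses that look like percentages (majority of values above 1.5) are
rescaled by 1/100 with a loud warning.  Nonpositive doses cannot enter the
log-dose model and are dropped with a logged warning; a group left with
fewer than two distinct doses is an error.

Boundary and out-of-range responses must be moved strictly inside (0,1).
The conventional compression `(y(n−1)+0.5)/n` (per-group `n`) is available
but perturbs *every* value, which is coarse at small n.  The default is a
sequential scheme of this package's own design: interior values are
untouched and the j-th most extreme offender at a boundary maps to
`j·δ` (lower) or `1 − j·δ` (upper) with
`δ = min(gap/(k+1), 1/(2n), 10⁻³)`, `gap` the distance from the most
extreme interior value to that boundary and `k` the offender count — rank
order is preserved and collisions with interior values are impossible.
The scheme is idempotent, so preprocessing may be applied repeatedly.

## Simulation design

The generator emulates a potency assay on a true logit-linear curve
(β₀ = 0, β₁ = 1, i.e. Dm = 1, so doses are in units of the true IC50):
7 log-equally spaced doses spanning Dm/30…30·Dm, 3 replicates per dose.
At the end doses the true effects are ≈ 0.032 and 0.968, inside the
extreme-response zone (≤ 5% / ≥ 95%), which is what makes the design
stress logit-scale estimators.  Scenario families: `7` (the base design),
`6noL`/`6noS` (largest/smallest dose removed — the delete-the-extremes
strategy), `7lessE` (doses Dm/8…8·Dm, no extreme design point), and
`7NCP` (dose-dependent precision, γ₁ = 0.3).

Error laws: `beta` (responses drawn from the beta law with φ = 100 —
heteroscedastic, variance largest mid-curve) and `logit_normal`
(homoscedastic N(0, σ²) noise on the logit scale, σ = 0.2 chosen to match
the beta law's mid-curve spread).  Under the logit-normal law the
logit-linear estimator is correctly specified and efficient, so robustness
comparisons are run under the beta law, where extreme design points give
`logit(y)` large variance and bias; the logit-normal option is kept for
contrast.  Every generated dataset passes through sequential truncation
before any estimator sees it, so all estimators receive identical inputs.
One master seed spawns per-(scenario, replicate) substreams, making
estimator comparisons paired and the whole study byte-reproducible.

What passing these simulations does *not* show: the generator draws from
the assumed model family (or its logit-normal cousin), so it cannot
reveal misspecification of the logit-linear mean itself (partial efficacy
plateaus, biphasic curves), plate effects or correlated replicates, or
measurement error in the dose.

The study runner scores β₀, β₁, log IC50 and log IC90 (doses on the log
scale so errors and widths are comparable) for LRM (OLS on logits), HLRM
(t(3) errors, ML), BRM (this package, auto α) and LRM_truncated (OLS after
deleting extreme responses), reporting bias, RMSE, 95% CI coverage and
mean CI width, with failed fits counted and excluded.  Problem sizes used
by the shipped checks — 500 datasets for coverage calibration, 200 for
the estimator comparison, 1000 null replicates for test sizes, 500
bootstrap replicates at n = 2100 — keep the full suite in the
single-digit minutes on one CPU while leaving Monte-Carlo error well
below the margins being asserted.

## Known limitations

* The mean model assumes 100% attainable effect; no Emax/probit/Weibull
  links.
* Wald-type intervals, even t-calibrated, remain approximate at very
  small n (two or three doses); profile or bootstrap intervals are not
  built in.
* The LRTs are anchored to α = 0; a robust fit that deviates strongly
  from the MLE signals contamination that the tests do not model.
* The SQV search refits the model across the α grid, so auto-tuned fits
  cost roughly an order of magnitude more than fixed-α fits.
* Weighted regression with externally supplied weights is deliberately
  absent — the data-driven α replaces it.
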