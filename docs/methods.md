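# Methods

## The problem and the models

The package analyses per-mother counts of under-five child deaths from a
two-stage cluster survey: mothers (level 1) are nested in enumeration
areas (EAs, level 2), the count has a large spike at zero (about 54% of
mothers report no death) and is overdispersed (variance well above the
mean).  Four two-part count families address the excess zeros:

* **Zero-inflated Poisson (ZIP)** — a point mass at zero mixed with a
  Poisson(μ); with inflation probability π,
  P(Y=0) = π + (1−π)e^{−μ} and P(Y=y) = (1−π)·Pois(y; μ) for y>0.
* **Zero-inflated negative binomial (ZINB)** — the same mixture with an
  NB base of mean μ and variance μ + αμ² (α > 0 the overdispersion), so
  P(Y=0) = π + (1−π)(1+αμ)^{−1/α}.
* **Poisson hurdle (PH)** — P(Y=0) = π exactly; positive counts follow the
  zero-truncated Poisson, Pois(y; μ) / (1 − e^{−μ}).
* **NB hurdle (NBH)** — P(Y=0) = π; positives follow the zero-truncated NB
  with normalizer 1 − (1+αμ)^{−1/α}.

Both parts carry regressions and EA random intercepts:

    log μ_ij   = x_ij'β + u_j,   u_j ~ N(0, σ_u²)
    logit π_ij = z_ij'γ + w_j,   w_j ~ N(0, σ_w²)

with u and w independent and the covariate sets x and z allowed to
differ.  exp(β) are incidence rate ratios (IRR) for the count severity;
exp(γ) are odds ratios for the zero part.  **Convention:** the zero part
models the probability that the count *is* zero, so hurdle odds ratios
are odds of a zero count (many libraries model P(Y>0); coefficients flip
sign between the conventions).  The zero-truncated NB in the hurdle is
properly normalized — an unnormalized positive branch would not sum to
one.  Random slopes are accepted in the model specification as a declared
extension point but are not implemented; only intercepts are random.

All pmf arithmetic is on the log scale with log-gamma functions; the NB
uses size 1/α and success probability 1/(1+αμ).

## Estimation

Parameters are estimated by marginal maximum likelihood: the EA random
effects are integrated out with **adaptive Gauss–Hermite quadrature**.
Per cluster, the integrand's mode is found by a damped Newton search
(finite-difference derivatives, vectorized across clusters, warm-started
between likelihood evaluations) and the Gauss–Hermite grid is centred at
the mode and scaled by the curvature there.  The default is 15 nodes per
dimension; with cluster variances in the 0.5–0.7 range the value is
stable to well below 1e−6 against doubling the node count, so analyses
here routinely use 9 nodes.

For the **hurdle families the marginal likelihood factorizes exactly**:
the Bernoulli zero part depends only on w and the truncated count part
only on u, so each factor is a one-dimensional integral and the two parts
are maximized separately (the joint deviance is the sum).  The
zero-inflated families do not factorize (the zero branch mixes π and μ)
and use a tensor-product two-dimensional rule.

Optimization is L-BFGS-B on a transformed scale — log α, log σ_u, log σ_w —
which enforces positivity; starting values come from a
no-random-effects two-part fit maximized inside the package, with σ
started at 0.3.  When several families are fitted on the same data, ZINB
is warm-started from the fitted ZIP (α starting at 0.3) and NBH from PH;
this shortens the path and in practice avoids a poorer ZINB local
optimum found from cold starts.  The `converged` flag combines the
optimizer's own status with a gradient-norm check scaled by the
likelihood magnitude (finite-difference gradients carry noise
proportional to |ℓ|, so a fixed absolute threshold would be meaningless
for large n).  Variance estimates below 1e−3 are flagged as boundary
estimates and their intervals replaced by a one-sided note.

Standard errors come from the numerically differentiated (central,
symmetric) Hessian of the marginal log-likelihood at the optimum.
Effect tables report exp(estimate) with 95% Wald intervals
exp(est ± 1.96·SE); variance components get Wald intervals on log σ,
back-transformed to the σ² scale — asymmetric and strictly positive.
Reference categories (the first listed level) appear as ratio-1 rows.

Model choice uses deviance = −2·maximized marginal log-likelihood,
AIC = deviance + 2k and BIC = deviance + k·ln(n) with n = number of
mothers; the AIC minimizer is selected.  Information criteria are only
comparable across fits of the same data, which is enforced with a data
fingerprint.

## Synthetic data generator

The real microdata are restricted-access, so a generator emulates their
structure and every downstream stage is validated against it:

* **Scale:** 645 EAs × 22 mothers (≈14,200; the study has 14,370 in 645
  EAs).  Cluster sizes can alternatively be Poisson-distributed.
* **Covariates:** sampled independently with marginals matching the
  published category totals (e.g. 17.3% vaccinated, 49.6% with a
  preceding birth interval ≤ 24 months, 3.9% multiple births); mother's
  age (sd 8 years) and family size (sd 2.2) enter as centred Gaussians so
  the intercepts pin the marginal moments directly.
* **Effects:** generating β and γ are the logs of the published adjusted
  IRRs/ORs (vaccination IRR 0.735 / OR 1.825, etc.); cluster variances
  default to σ_u² = 0.526 and σ_w² = 0.691.
* **Intercepts:** β₀ = −0.235 and γ₀ = −0.57 were solved once by
  bisection on large simulated samples so that the marginal zero share is
  ≈ 53.7% and the marginal mean count ≈ 0.9, and then frozen.  At these
  settings the marginal variance is ≈ 2.3–2.5 — above the study's 1.697
  because the published per-year age effects imply more between-mother
  heterogeneity than the real (correlated) covariates do.  Zeros and
  overdispersion are therefore emulated faithfully; the exact marginal
  variance is not.
* **Mechanism:** u_j, w_j drawn per cluster; hurdle outcomes as a
  Bernoulli(π) zero against an exact inverse-cdf zero-truncated draw;
  zero-inflated outcomes as Bernoulli(π) inflation against an untruncated
  base draw.  Generation is deterministic given the scenario seed.

What passing tests on this generator do **not** show: behaviour under
correlated covariates, informative cluster sizes, survey weights, or
spatial structure — none of which the generator produces.

A small recovery design (300 EAs × 25 mothers, one balanced binary
covariate in both parts, β = (0, 0.4), γ = (0.5, −0.7), α = 0.6,
σ_u² = 0.5, σ_w² = 0.7) is used for parameter-recovery checks; the
model-selection study runs a scaled-down version (80 EAs × 18 mothers,
9 quadrature nodes) so that repeated two-dimensional ZI fits stay cheap
on a single CPU.

## Descriptives

The descriptive stage reproduces the published summary layout: per-mother
outcome distribution (zero share, mean, n−1 variance, histogram) and
per-covariate r×2 tables of (mothers with ≥1 death, without) with percent
columns (one decimal, half-away-from-zero) and the standard Pearson
chi-square test (df = r−1, no continuity correction by default, optional
Yates flag for 2×2).  The published category counts are packaged as
fixtures; their percent columns reproduce the published values exactly.
The published chi-square statistics themselves are *not* reproducible
from the published counts by the Pearson formula (they may come from a
design-adjusted test or a different grouping) and are treated as
non-targets.

## Numerical choices and degenerate inputs

* Inverse-logit values are clipped to [1e−12, 1−1e−12]; linear predictors
  to ±700 before exponentiation.
* A pmf of zero at an observed count yields −inf with a warning, not an
  exception; a truncation normalizer that degenerates to nan raises a
  dedicated error.
* σ² = 0 collapses the corresponding integral to the conditional
  likelihood at 0 (degenerate Gaussian), exactly.
* Design columns with zero variance after reference coding are dropped
  with a warning; unknown category levels are an error naming the level.
* A non-SPD curvature at a quadrature mode falls back to the prior's
  diagonal scaling for that cluster.

## Known limitations

* No survey weights or stratification; estimation is unweighted ML.
* Random intercepts only; the random-slope extension point is declared
  but unimplemented, and the two intercepts are independent (no
  cross-part correlation).
* Wald intervals throughout; no profile or bootstrap intervals.
* The published regression tables cannot be reproduced without the
  restricted microdata; they serve only as generator settings here.
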