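# Methods

## The single-estimate model

Throughout, *B* is an approximately normal, unbiased estimator of a
regression coefficient β with known standard error se; the t-correction for
estimated standard errors is deliberately out of scope (it is negligible
beyond ~40 degrees of freedom, and the package's p-value pathway offers the
implied standard error |b|/|z| as a partial remedy when only a p-value was
reported).

The default prior is β ~ N(0, g·se²) with g = 1.  Conjugate algebra gives
the posterior

  β | B=b ~ N( b·g/(g+1), se²·g/(g+1) ),

i.e. N(b/2, se²/2) at g = 1.  All posterior summaries in
`defaultprior.conjugate` are closed-form in the standard normal CDF; the
module contains no Monte Carlo.  Note the square roots: the posterior sd at
g = 1 is se/√2, the sign probability is Φ(b/(√2·se)), and the conditional
coverage of the Wald interval is Φ(b/(√2 se) + 1.96√2) − Φ(b/(√2 se) −
1.96√2).  These are the renderings consistent with the uniformity property
below (the marginal of B is N(0, (g+1)se²), so at g = 1, B/(√2 se) is
standard normal and Φ(B/(√2 se)) is exactly uniform).

Parameters:

* **g** (dimensionless, default 1) — ratio of the prior variance to se².
  g = 1 is the sign-non-informative choice; empirical-Bayes fits of
  published collections tend to land slightly above 1 (see below).  All
  single-estimate functions accept arbitrary g > 0; g → ∞ recovers every
  flat-prior formula.
* **level** (default 0.95) — credible/confidence level; interval
  multipliers use the exact normal quantile (1.959964…), not the rounded
  1.96; the difference is below 2e-5 in coverage.
* **conflict threshold** (two-sided p < 0.001, fixed) — under the g = 1
  prior, P(|Z| > 3.29) = 2Φ(−3.29/√2) ≈ 0.020; an observation that
  surprising is treated as prior-data conflict and flagged rather than
  shrunk.  The boundary p = 0.001 itself is *not* flagged (strict
  inequality), matching the collection filter.

When both a reported se and a p-value are available, the conflict rule and
the posterior default to the reported se; `--use-implied-se` switches to
|b|/|z|.  The implied se is undefined at b = 0 or p ≥ 1 and raises rather
than substituting a value.

## Magnitude (type-M) machinery

If X ~ N(μ, σ²), |X| is folded normal with mean |μ| + √(2/π)σe^(−μ²/2σ²) −
2|μ|Φ(−|μ|/σ).  Three uses: the frequentist bias of |B| for |β| (maximal at
β = 0, value √(2/π)·se ≈ 0.7979·se); the flat-prior posterior mean of |β|
(the same formula at μ = b — larger still than |b|); and the
shrinkage-prior posterior mean of |β| (the same formula at the posterior
mean and sd — exact because the posterior is normal).  For |μ|/σ > 38 both
correction terms underflow double precision and the function returns |μ|
directly.

## Sign (type-S) machinery

Under the flat prior, P(sgn β = sgn B | b) = Φ(|b|/se).  Among all priors
with a symmetric unimodal density this is the *maximum* attainable sign
agreement; `sign_agreement_prob` verifies the bound numerically for any
user-supplied prior by adaptive quadrature of the posterior odds
(numerator/denominator tolerance 1e-10, effective support truncated where
the prior density falls below 1e-16 of its peak; the bound check needs at
least six reliable digits).  sgn(0) is left undefined: b = 0 raises instead
of adopting a convention, since every sign statement conditions on a
nonzero estimate.

The uniformity property — P(β > 0 | B) ~ Uniform(0,1) when the prior sd
equals se — is checked by simulation with a Kolmogorov–Smirnov test at
n = 10⁵ (`theorem1_uniformity_sim`), including a misspecified variant
(prior sd = 2se) that the test must reject.  Every stochastic function
takes an explicit integer seed and uses its own `numpy` Generator.

## Jeffreys prior for the magnitude

Reparameterizing (sign, magnitude) with a Bernoulli(½) sign prior makes B
a two-component normal mixture in θ = |β|.  The Jeffreys prior √I(θ) has no
closed form; `fisher_info` integrates score² × density over
|b| ≤ θ + 10·se by adaptive quadrature (absolute tolerance 1e-9; the
neglected tail mass is < 1e-12).  The score is implemented as the exact
derivative — the proportionality constant 1/se² matters because the
information squares it — and is validated against central finite
differences.  Useful invariants: I(0) = 0 (the components coincide and the
score vanishes identically), I(θ)·se² depends on θ/se only, and
I(θ) ≤ 1/se² with equality in the separation limit.  The tabulated prior
(`jeffreys_grid`) is improper (constant positive tail ~ 1/se) and is
reported unnormalized; display code may normalize to a maximum of one.

## The hierarchical model for published z-values

Study j carries g_j ~ N(g, σ²); coefficient i of study j has
β_ij | g_j ~ N(0, g_j·se²_ij) and B_ij | β_ij ~ N(β_ij, se²_ij).  Then
Z_ij = B_ij/se_ij is N(0, g_j + 1) given g_j, and Z²_ij is Gamma with shape
½ and mean g_j + 1 — the scaled-χ²₁ identity.  The package fits this as a
Gamma mixed model on squared z-values with identity link, offset 1, shape
fixed at ½ (not estimated), and a Gaussian random study effect; the
intercept estimates g.

Two scale conventions circulate for a parameter like g: variance ratio
versus sd ratio.  The model above puts g on the **variance** scale (the
marginal mean of z² is g + 1), and that is what `fit_conditional` and
`fit_marginal` report; a fitted g of 1.28 on this scale corresponds to a
prior sd of √1.28 ≈ 1.13 standard errors.  Discussions that describe such
a fit as "prior sd = 1.28·se" conflate the two conventions; the package
reports g and leaves √g to the caller.

### Likelihood evaluation

The marginal likelihood of a study integrates the Gaussian effect u over
the feasible region where the Gamma mean m = g + σu + 1 is positive; the
Gaussian tail with m ≤ 0 is truncated away (the model itself permits
negative prior variances, which cannot enter a Gamma likelihood; the
truncated prior mass Φ(−(1+g)/σ) is reported as a diagnostic and is ~1e-6
at g ≈ 1.3, σ = 0.5).  The integral is computed in t = log m, which maps
the feasible region onto the whole line, removes the essential singularity
of the Gamma density at m → 0⁺, and leaves an analytic integrand with
doubly-exponential tails.  On such integrands the trapezoid rule converges
spectrally, so the evaluator:

1. finds each study's integrand mode and Laplace scale in t by a vectorized
   closed-form Newton iteration;
2. expands a window from the mode until the log integrand has dropped by 45
   on each side (neglected mass < e^{-45} of the peak);
3. applies the trapezoid rule starting at `n_quad` nodes (default 40) and
   doubles the grid until the total log-likelihood moves by < 1e-9.

The returned value is therefore insensitive to `n_quad`, which only sets
the starting resolution; doubling it from 20 to 40 changes the
log-likelihood by far less than 1e-6 on realistic collections.  The
evaluator agrees with an independent `scipy.integrate.quad` oracle to
machine precision.  A random-effect sd below 1e-8·(|g|+1) is collapsed to
the exact σ = 0 likelihood (the window would underflow double precision,
and the difference is far below the quadrature tolerance).

### Fitting

`fit_conditional` maximizes over (g, σ) by Nelder–Mead with bounds
g > −0.999, σ ≥ 0, starting from the moment estimate (mean(z²) − 1, 0.5)
plus three perturbed restarts against plateaus.  Non-convergence is
reported in the fit object, not raised.  The default interval for g is
profile likelihood — endpoints where twice the profile drop crosses the
χ²₁ quantile, bracketed and solved by Brent to 1e-4 — because g is a
variance-ratio-like parameter whose Wald interval misbehaves near the
boundary; a Wald interval from a finite-difference Hessian is available.
If the profile never crosses on one side within the search range the
interval is one-sided and flagged.  `fit_marginal` delegates the
no-random-effect model to a statsmodels Gamma GLM (identity link, offset 1;
the intercept-only MLE is mean(z²) − 1) with cluster-robust (by study)
sandwich standard errors; it is the σ = 0 cross-check for the mixed fit,
with which it agrees to ~1e-3 in ĝ on homogeneous data.

No adjustment is made for the censoring induced by excluding p < 0.001 from
collections; the model is fitted to the collected values as-is, and an
adjusted likelihood is explicitly out of scope.  Because very small
p-values are excluded, fitted g values are, if anything, modest
underestimates of the uncensored ratio — and at the same time collections
of published values carry inflation pressures (favorable dichotomization,
unreported null predictors) that push the other way.

## Collections

Input CSVs carry one row per reported two-sided p-value with the article in
`study_id`.  Row-level problems (non-numeric p such as "NS" or "p < 0.05",
p outside (0, 1], malformed flags) are collected with their line numbers
and never silently dropped; missing required columns are a schema error.
Eligibility filters drop intercept rows (a zero-centred prior is
inapplicable to intercepts), F-test rows, p < 0.001 (strictly — p = 0.001
is kept), and outcomes beyond the first; each drop is labelled with its
rule, and the filters are idempotent.  Reported p-values are used at face
value; rounding in the source articles is not modelled as interval
censoring.  The "first outcome only" rule is enforceable only when an
`outcome_rank` column is present; otherwise all rows pass.

Conversion to the fitted scale is z² = (Φ⁻¹(p/2))²; the unknown sign of z
is irrelevant because only symmetric priors are in play and the model uses
z² only.

## Synthetic data

`simulate_zdataset` draws from the hierarchical model above.  Defaults
mirror a realistic meta-analytic harvest: **50 studies × 12 values**
(≈ 576 values), g = 1 (the default prior; recovery experiments also use
1.28, a plausible fitted value for published collections), σ = 0.5.  No
published estimate of σ was available to calibrate against; 0.5 was chosen
once as producing visible but moderate between-study heterogeneity
(study-level z-variances g_j + 1 ranging over roughly 1.5–3 at g = 1) and
is flagged as a convention, not an estimate.  Study effects are drawn with
rejection to g_j ≥ 0 — the Gaussian model permits negative prior variances
that cannot be simulated from — and the realized rejection rate
(≈ Φ(−g/σ); about 2% at g = 1, σ = 0.5) is returned so callers can judge
the distortion.  This truncation is a deliberate deviation forced by the
model's internal tension, and it means the generator's effective g is
slightly above the nominal one when σ/g is large.

What the generator does *not* emulate: publication bias, p-hacking,
rounding of reported p-values, correlated coefficients within an article,
and the p < 0.001 reporting censoring.  Passing recovery tests on this
generator therefore demonstrates correctness of the likelihood and
optimizer under the stated model, not robustness to the messiness of real
published collections.

`simulate_estimates` draws (β, B) pairs from the single-level model for
coverage and sign simulations; marginally the Wald interval covers β at its
nominal rate (the frequentist statement holds for every fixed β, hence
also averaged over the prior), while conditional coverage given B follows
the declining closed-form curve — the package's main end-to-end stochastic
check.

## Numerical conventions and edge cases

* Probabilities are computed via `scipy.stats.norm`; no hand-rolled
  approximations.
* `credible_interval` validates level ∈ (0, 1); `p_to_absz` validates
  p ∈ (0, 1]; violations raise `ValueError` with the offending value.
* A z² of exactly 0 (p = 1) is representable in a dataset but rejected by
  the Gamma likelihood (infinite density at 0); collections containing
  p = 1 must be screened before fitting.
* Optimizer traces and truncation diagnostics are exposed on the fit
  object rather than logged by default.
* Every CLI run writes a `<output>.manifest.json` with the subcommand,
  parameters, seed and package version.

## Problem sizes used in the checks

The test suite uses 10⁵ draws for uniformity KS checks, 10⁶-draw Monte
Carlo oracles for folded-normal and Fisher-information cross-checks, 2×10⁶
(β, B) pairs for the binned conditional-coverage comparison, and 20–50
replicate fits at the 50 × 12 design for recovery and interval-coverage
experiments.  These sizes make the stochastic assertions comfortably
separated from their tolerances (4 Monte-Carlo standard errors or better)
while keeping the full suite under a few minutes on one core.

## Known limitations

* Single-coefficient inference only; no joint or multivariate priors.
* Normality with known se is assumed throughout; small-sample t behaviour
  is not modelled.
* The empirical-Bayes fit treats collected p-values as exact and
  uncensored (see above); its g estimates inherit both biases.
* The profile CI search range for σ is bounded (4σ̂ + 2); pathological
  likelihoods could in principle place an endpoint beyond it, which would
  surface as a flagged one-sided interval.
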