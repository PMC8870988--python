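# Methods

## Model and scope

The package estimates the shape `ξ` and scale `σ` of the Generalized
Pareto Distribution (GPD) that models exceedances `X − u | X > u` of a
univariate series over a high threshold `u = q_p`. Three estimators
are implemented — classical Metropolis–Hastings on the exceedances
(MH), baseline MH (BMH) and informative-priors baseline MH (IPBMH) —
together with the stable-law theory that powers the baseline methods
and a simulation harness that compares them by mean absolute error
(MAE).

Supported baseline families are the three analytic stable laws — Lévy
(α = 1/2, β = 1), Cauchy (α = 1, β = 0) and Normal (α = 2), plus the
Gamma family for the air-quality-style application. General stable
laws (densities by characteristic-function inversion, arbitrary
(α, β) sampling) are out of scope: relations for other baselines are
reachable only through the simulation-calibration routine.

### Standardization conventions

A stable baseline is written `X = aZ + b` with `Z` the standard
member. For the Normal family the standard member is N(0,1) — not the
variance-2 canonical α = 2 stable — so `a` coincides with the usual
standard deviation; the calibrated Normal relation below is tied to
that convention. The location `b` never enters the tail relations and
the simulation studies fix `b = 0`.

### Tail relations

For α < 2 the survival function of the standard member obeys
`P(Z > x) ~ (1+β) C_α x^(−α)` with `C_α = Γ(α) sin(απ/2)/π`, which
yields the closed-form relation `ξ_Z = 1/α`,
`σ_Z = (1/α)[C_α(1+β)/(1−p)]^(1/α)` for the exceedances of `Z` above
its p-quantile, and `(ξ, σ) = (ξ_Z, a σ_Z)` on the observed scale.
The shape is therefore *data-independent* within a family: exactly 2
for Lévy and 1 for Cauchy.

The Normal baseline has no power-law tail; its relation is the
calibrated polynomial pair `ξ_Z = −0.7 + 0.61p`,
`σ_Z = 0.34 + 3.18(1−p) − 12.4(1−p)²`. Its validity window is exposed
as `p ∈ [0.90, 0.995]`; evaluation outside the window warns rather
than errors (the σ polynomial turns negative well outside it, which
does raise). The source material is ambiguous about whether the
calibration grid started at 0.90 or 0.99; the wider, figure-consistent
window is used.

The Gamma(shape, rate) relation is `ξ = 0`,
`σ = (1 + 0.22 ln²shape)/rate`. The `ln²shape` reading is adopted
because it is the only one forced by theory at shape = 1, where the
baseline is Exponential(rate) and its tail is *exactly* itself, so
`σ = 1/rate`; a base-2-logarithm variant (also exact at shape 1) is
available behind `reading="log2"`.

## The MH engine

All fitters share one componentwise Gaussian random-walk
Metropolis–Hastings kernel. Acceptance probabilities are computed as
`exp` of log-posterior differences — never as transcriptions of the
closed-form conditional-ratio expressions, whose structure is instead
*verified* against the log-posterior differences by dedicated tests
(at 100 random parameter states per sampler, tolerance 1e−10).
Support violations enter exclusively as `−∞` log-posteriors, so
proposals may probe out-of-support regions without exceptions; a NaN
log-posterior is a hard error.

Design choices where the protocol is silent:

* **Proposal scales.** Never stated in the reference protocol.
  Default: adaptive multiplicative scaling during burn-in targeting a
  25–40% acceptance rate (window of 50 iterations, factors 0.7/1.4),
  then frozen, so all retained draws come from a fixed kernel and the
  stationary distribution is preserved. Fixed scales are accepted for
  exact replication.
* **Initialization.** The protocol mentions choosing initial values
  per sample without a rule. Fitters use moment/quantile heuristics
  (light tail: `δ₀ = 1.5·max(x)` with `k₀` from the sample mean;
  heavy tail: `ξ₀ = 1`, `σ₀ = median(x)`; baseline scale: conjugate
  mode or median-based); the engine also offers a deterministic grid
  search (`init="auto"`).
* **Chain lengths.** Defaults follow the reference protocol (10,000
  burn-in, thinning 25, 10,000 retained draws). The simulation-study
  and application defaults use the desk-scale reduction 2,000 kept /
  1,000 burn-in / thinning 5, and the study harness uses 25 replicates
  instead of 100; the full protocol is available as
  `reference_study_config()`.
* **Update order.** Components are swept in declaration order each
  iteration (k then δ; ξ then σ; the single scale parameter for
  baselines).

Point estimates are chain means; intervals are empirical 2.5%/97.5%
quantiles.

## Priors

Numerical hyperparameters are never given in the reference protocol;
the defaults are weakly informative and all overridable:
Gamma(0.01, 0.01) for `k`, `δ` and the baseline scale `a`; type-I
Pareto with index 1 and lower bound 0.01 for heavy-tail `ξ`;
inverse-Gamma(0.01, 0.01) for `σ` and for `a²`. The Pareto lower
bound restricts the heavy-tail sampler to `ξ > 0.01`, which is also
how near-exponential (Gamma-baseline) tails are fitted.

The IPBMH priors are untruncated Normals; feasibility for `ξ < 0` is
enforced only through the likelihood's `−∞` region. The widths are
shipped as constants (`b1` = 0.03, 0.065, 0.1 for Normal, Cauchy,
Lévy; `b2 = exp(c1 p² + c2 p + c3)` with per-family coefficients);
they were evidently tuned by simulation with an unreported objective,
so the calibration machinery is available to re-derive them but no
re-tuning is attempted here. For the Gamma application, which has no
tuned row, the package uses `b1 = 0.03` (the light-tail value) and
`b2` equal to 10% of the prior σ mean.

## Baseline samplers and BMH

Lévy and Cauchy scale likelihoods are sampled on `a` with Gamma
priors; the Normal family is sampled on `a²` (where the inverse-Gamma
prior lives) and reported on the `a` scale, with the point estimate
defined as the mean of the `a = √(a²)` draws, not the square root of
the mean of `a²`. The Lévy and Normal cases are conjugate
(Gamma and inverse-Gamma posteriors respectively), which the tests
exploit as closed-form oracles.

BMH plugs the posterior mean `â` into the family relation
(`ξ̂ = ξ_Z`, `σ̂ = â σ_Z`). Intervals for `σ̂` are obtained by mapping
each retained `a` draw through the relation.

## Thresholding

The empirical threshold is the order statistic at (1-based) index
`⌈p·n⌉` of the sorted sample — the threshold is then always an
observed value and roughly `(1−p)n` strict exceedances remain. The
convention is a package choice; the source never states one. The pure-
family simulation study uses the *theoretical* baseline quantile
`u = a·z_p` (the baseline is known there), while mixture studies and
data-driven fitting use the empirical quantile; both are available
everywhere. With theoretical thresholds and small n, a replicate can
have no exceedances; such replicates are recorded as failures and
excluded from MAE averages with a logged count.

## Simulation studies

`run_mae_study` draws replicate series over a grid of families,
sample sizes `n` and scales `a`, runs the requested methods, and
scores `|ξ̂ − ξ_Z|` and `|σ̂ − a σ_Z|` against the family relation at
the cell's `a` — which makes BMH's ξ error identically zero for pure
stable baselines, a structural feature, not a bug. Desk defaults:
`n ∈ {32, 512}`, `a ∈ {0.25, 1, 4}`, `p = 0.9`, 25 replicates,
2,000-draw chains; all grids and the full-scale preset are
configurable.

Mixture scenarios (`run_mixture_study`) have no closed-form tail
truth. The reference values are produced by a one-off large-sample
oracle: 10⁶ mixture draws, empirical exceedances at `p`, and a tail
MH fit (2,000 kept draws) — enough exceedances (~10⁵) that the
oracle's Monte-Carlo error is negligible against desk-scale
estimation errors. Oracles are cached per mixture and seed-stamped.
Two behaviors of this design are worth knowing. First, for scale or
location mixtures *within* a heavy-tailed family the tail index is
invariant, so the oracle ξ sits at `ξ_Z` up to pre-asymptotic bias
and BMH's constant `ξ̂ = ξ_Z` is nearly exact — IPBMH, whose
posterior at a handful of exceedances equals that same prior centre
plus a small likelihood tilt, cannot better it on ξ. Second, at 25
replicates the MAE of the exceedance-based methods carries a relative
Monte-Carlo error of order 10%, so comparisons between methods that
differ by less than that are not stable across seeds.

The mixture component notation `(γ, δ)` is read as location and scale
in the `X = aZ + b` sense. A mixture weight of 1 is allowed and
degenerates to the first component.

## What the synthetic generators do and do not emulate

Stable draws use exact closed-form transforms (Lévy: reciprocal
squared unit-Normal; Cauchy: tangent of a uniform; Normal: unit
Normal), so the simulated baselines are exactly the models the theory
assumes. The Gamma generator stands in for real air-quality series:
it reproduces the marginal distribution a PM2.5 record fits, but not
serial dependence, seasonality, missing-data patterns or measurement
rounding of real monitoring data. Passing tests therefore demonstrate
correctness of the estimators under the stated models, and the
methods' *relative* behavior (full-data methods beating
exceedance-only methods when the baseline family is right), not
field performance on dependent or misspecified data.

## Application pipeline

`run_application` emulates the PM2.5-style analysis: Gamma baseline
ML-fitted on the full series (method-of-moments fallback), threshold
at the empirical p-quantile of the full series, and a seeded random
subsample (default 50 points, without replacement) supplying the tail
data for the MH and IPBMH fits — so the exceedance-based methods see
realistically scarce tails (typically 3–8 points) while BMH maps the
full-series fit through the Gamma relation.

## Numerical choices

* `|ξ| < 1e−8` routes every GPD computation through the exponential
  branch, avoiding catastrophic cancellation in
  `(1 + ξx/σ)^(−1/ξ)`.
* GPD cdf/quantile/sampling wrap the scipy implementations
  (`genpareto`, `expon`); sampling is inverse-transform from a seeded
  generator. Out-of-support arguments clip in the cdf and return
  `−∞` in the log-density.
* `C_α` at α = 2 returns exactly 0 (sin π).
* Calibration excludes replicates whose per-component acceptance rate
  falls outside [0.05, 0.8], with a warning and a provenance record;
  curve fitting requires at least as many usable grid points as
  coefficients (constant ξ and a log–log power law in (1−p) for σ in
  heavy families; linear ξ in p and quadratic σ in (1−p) otherwise).
* All study randomness derives from `numpy` `SeedSequence` children of
  a single seed, so every table is bit-reproducible.

## Known limitations

* Only the three analytic stable families and Gamma are built in;
  anything else goes through `calibrate_relation`.
* The threshold is fixed via `p`; joint Bayesian threshold estimation
  is out of scope, as is light/heavy model choice by marginal
  likelihood (the caller, or the declared family, picks the sampler).
* The IPBMH width constants are inherited, not re-derived; their
  original tuning objective is unknown.
* MH on very small exceedance sets (m ≤ 5) is dominated by the prior;
  this is the regime the baseline methods are designed to rescue, and
  the MAE tables should be read with that in mind.
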