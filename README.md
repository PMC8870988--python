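# gpdbayes

Bayesian estimation of Generalized Pareto Distribution (GPD) tail
parameters under the peaks-over-threshold framework, exploiting
information from the **whole** baseline series rather than only the
exceedances.

## The problem

In extreme value analysis the observations above a high threshold
`u = q_p` (the p-quantile), shifted by `u`, are modelled by a GPD with
shape `ξ` and scale `σ`:

    G(x | ξ, σ) = 1 − (1 + ξ x / σ)^(−1/ξ)        (ξ ≠ 0)
    G(x | 0, σ) = 1 − exp(−x / σ)

`ξ > 0` means a heavy tail, `ξ = 0` exponential, `ξ < 0` a bounded tail
with endpoint `−σ/ξ`. The classical Bayesian estimator runs
Metropolis–Hastings (MH) on the exceedances alone — which, at a tail
level of `p = 0.9` and a series of 32 points, means fitting two
parameters to three observations.

When the baseline family is known, much more can be said. For a stable
baseline `X = aZ + b` with index of stability `α < 2`, the exceedances
of the standard member `Z` above its p-quantile follow a GPD with

    ξ_Z = 1/α,    σ_Z = (1/α) · [C_α (1+β) / (1−p)]^(1/α),
    C_α = Γ(α) sin(απ/2) / π,

and the observed-scale tail is simply `(ξ, σ) = (ξ_Z, a·σ_Z)`. For the
analytic stable families this gives `ξ_Z = 2` (Lévy, α=1/2, β=1) and
`ξ_Z = 1` (Cauchy, α=1, β=0) — independent of `p`. The Normal baseline
(no power-law tail) uses simulation-calibrated polynomials, valid for
`p ∈ [0.90, 0.995]`:

    ξ_Z = −0.7 + 0.61 p,    σ_Z = 0.34 + 3.18(1−p) − 12.4(1−p)².

Three estimators are provided:

* **MH** — classical componentwise random-walk MH on the exceedances:
  light tails via `(k, δ) = (−ξ, −σ/ξ)` with Gamma priors; heavy tails
  via `(ξ, σ)` with a type-I Pareto prior on `ξ` and an inverse-Gamma
  prior on `σ`.
* **BMH** (baseline MH) — MH on the baseline scale `a` using *all* the
  data, then the deterministic relation above maps `â` to `(ξ̂, σ̂)`.
* **IPBMH** (informative-priors baseline MH) — MH on `(ξ, σ)` of the
  exceedances with Normal priors `ξ ~ N(ξ_Z, b1)`, `σ ~ N(â·σ_Z, b2)`
  centred at the BMH mapping, with family-tuned widths
  (`b1` = 0.03/0.065/0.1 for Normal/Cauchy/Lévy;
  `b2 = exp(c1 p² + c2 p + c3)`).

A Gamma baseline (the natural model for, e.g., daily PM2.5
concentrations) maps through `ξ = 0`, `σ = (1 + 0.22 ln²shape)/rate`,
exact at shape 1 where the exponential tail equals the baseline. A
simulation-calibration routine re-derives such relations for any
standard baseline.

## Worked example

Thirty-two standard-Cauchy observations leave three exceedances over
the 0.9-quantile (`examples/04_informative_priors.py`):

```
n = 32 observations, m = 3 exceedances over u = 1.447
truth:  xi = 1.000, sigma = 3.183
MH:     xi = 0.038, sigma = 10.640   (tail data only)
BMH:    xi = 1.000, sigma = 3.169   (all data via the relation)
IPBMH:  xi = 1.000, sigma = 3.153   (prior widths b1 = 0.065, b2 = 0.238)
```

With three tail points the classical estimator returns prior noise; the
baseline methods stay on the truth because all 32 observations inform
`â` and the Cauchy shape is pinned at 1 by stable-law theory. The other
scripts in `examples/` cover the closed-form relations, each fitter,
simulation calibration, the desk-scale MAE study, and the PM2.5-style
Gamma application; each prints its numbers with a line on what they
mean.

A thin CLI wraps the same calls:

```sh
gpdbayes simulate --family cauchy --n 512 --seed 1 --out series.txt
gpdbayes fit-bmh series.txt --family cauchy --p 0.9 --out fit.json
```

## Layout

```
src/gpdbayes/
  distributions.py   GPD + stable/Gamma baselines, exceedance extraction, I/O
  relations.py       closed-form and calibrated baseline-to-GPD mappings
  mh.py              componentwise random-walk MH engine
  estimators.py      the MH, BMH and IPBMH fitters
  experiments.py     synthetic data, MAE/mixture studies, application pipeline
  cli.py             thin command-line interface
docs/methods.md      modelling assumptions, defaults, numerical choices
examples/            one narrative script per capability
```
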