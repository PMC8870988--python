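"""Classical Metropolis--Hastings fit of GPD exceedances.

Simulates exceedances from a known heavy-tailed GPD and recovers the
parameters from the tail data alone — this is the conventional
peaks-over-threshold estimator the baseline methods improve on.
"""

from gpdbayes import ExceedanceSample, GPDParams, MHConfig, fit_mh_heavy, gpd_sample

TRUE = GPDParams(xi=1.0, sigma=3.1831)  # the Cauchy tail at p = 0.9
values = gpd_sample(1000, TRUE, seed=7)
tail = ExceedanceSample(u=0.0, p=0.9, values=values, n_source=10_000)

fit = fit_mh_heavy(tail, config=MHConfig(n_keep=2000, burn_in=1000, thinning=5, seed=8))
print(f"true     xi={TRUE.xi:.3f}  sigma={TRUE.sigma:.3f}")
print(f"estimate xi={fit.xi:.3f}  sigma={fit.sigma:.3f}")
print(f"95% CI   xi=({fit.xi_interval[0]:.3f}, {fit.xi_interval[1]:.3f})  "
      f"sigma=({fit.sigma_interval[0]:.3f}, {fit.sigma_interval[1]:.3f})")
print(f"acceptance rates: {fit.posterior.chain.acceptance_rates.round(2)}")
print("With m=1000 exceedances the posterior means sit close to the truth; "
      "the MAE study shows how badly this degrades when only a handful of "
      "observations exceed the threshold.")
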