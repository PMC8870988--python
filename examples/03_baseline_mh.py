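"""Baseline MH (BMH): estimate the tail from ALL the data.

Rather than discarding everything below the threshold, BMH fits the
baseline family's scale parameter on the full series by MH, then maps
it through the closed-form relation to the GPD tail parameters.
"""

from gpdbayes import MHConfig, StableSpec, fit_bmh, stable_sample

# 512 standard-Cauchy draws, scale a = 2: the exceedances above the
# 0.9-quantile follow GPD(1, 2/(0.1*pi)) = GPD(1, 6.366)
data = stable_sample(512, StableSpec.from_family("cauchy", a=2.0), seed=11)
fit = fit_bmh(data, "cauchy", p=0.9, config=MHConfig(n_keep=2000, burn_in=1000, thinning=5, seed=12))

print(f"posterior mean of the baseline scale: a_hat = {fit.a_hat:.3f}  (truth 2.0)")
print(f"tail parameters: xi = {fit.xi:.3f} (exactly the family shape), "
      f"sigma = {fit.sigma:.3f} (truth 6.366)")
print(f"sigma 95% interval from propagated a-draws: "
      f"({fit.sigma_interval[0]:.3f}, {fit.sigma_interval[1]:.3f})")
print("The shape carries no estimation error at all: for a stable family "
      "it is pinned by the index of stability.")
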