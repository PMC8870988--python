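"""Three-method comparison on a Gamma-baseline series.

Emulates the analysis of daily PM2.5 concentrations: the full series
fits a Gamma baseline, the threshold is the empirical 0.9-quantile,
and a random 50-point subsample supplies the (scarce) tail data for
the exceedance-based fits.  The Gamma relation maps the fitted
baseline to an exponential tail: xi = 0, sigma = (1 + 0.22 ln^2
shape) / rate.
"""

from gpdbayes import GammaSpec, MHConfig, run_application, synth_baseline

# synthetic stand-in for ten years of daily PM2.5 (mug/m^3), Gamma(2, 0.2)
series = synth_baseline(GammaSpec(shape_g=2.0, rate_g=0.2), n=1066, seed=51)

result = run_application(
    series, p=0.9, subsample=50, seed=52,
    mh_settings=MHConfig(n_keep=2000, burn_in=1000, thinning=5),
)
print(f"fitted baseline: Gamma(shape={result.gamma.shape_g:.3f}, rate={result.gamma.rate_g:.4f})")
print(f"threshold u = {result.u:.2f} (p = {result.p}); "
      f"subsample of {result.subsample} leaves m = {result.m_tail} tail points")
print(f"MH:     xi = {result.mh.xi:+.3f}, sigma = {result.mh.sigma:.3f}")
print(f"BMH:    xi = {result.bmh.xi:+.3f}, sigma = {result.bmh.sigma:.3f}")
print(f"IPBMH:  xi = {result.ipbmh.xi:+.3f}, sigma = {result.ipbmh.sigma:.3f}")
print("Truth for this generator: sigma = (1 + 0.22 ln^2 2)/0.2 = 5.53 with an "
      "exponential (xi = 0) tail.  BMH lands on it from the full series; the "
      "exceedance-based fits work from only a handful of points.")
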