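"""IPBMH: tail MH with priors centred at the baseline mapping.

The informative-priors method runs MH on the exceedances like the
classical estimator, but its Normal priors are centred at the BMH
estimate with family-tuned widths — tail data are used twice, once
through the prior and once through the likelihood.  With very little
tail data the three methods differ sharply.
"""

from gpdbayes import (
    MHConfig,
    StableSpec,
    build_informative_prior,
    extract_exceedances,
    fit_bmh,
    fit_ipbmh,
    fit_mh_for_family,
    stable_sample,
)

cfg = MHConfig(n_keep=2000, burn_in=1000, thinning=5, seed=21)
data = stable_sample(32, StableSpec.from_family("cauchy"), seed=20)  # tiny series
tail = extract_exceedances(data, p=0.9)  # only a few exceedances survive

mh = fit_mh_for_family(tail, "cauchy", config=cfg)
bmh = fit_bmh(data, "cauchy", p=0.9, config=cfg.replace(seed=22))
prior = build_informative_prior("cauchy", p=0.9, a_hat=bmh.a_hat)
ipbmh = fit_ipbmh(tail, prior, config=cfg.replace(seed=23))

print(f"n = {len(data)} observations, m = {tail.m} exceedances over u = {tail.u:.3f}")
print(f"truth:  xi = 1.000, sigma = 3.183")
print(f"MH:     xi = {mh.xi:.3f}, sigma = {mh.sigma:.3f}   (tail data only)")
print(f"BMH:    xi = {bmh.xi:.3f}, sigma = {bmh.sigma:.3f}   (all data via the relation)")
print(f"IPBMH:  xi = {ipbmh.xi:.3f}, sigma = {ipbmh.sigma:.3f}   (prior widths "
      f"b1 = {prior.xi_sd}, b2 = {prior.sigma_sd:.3f})")
print("With m this small the classical MH estimate is essentially prior noise, "
      "while both baseline methods stay near the truth.")
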