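"""Re-derive a baseline-to-GPD relation by simulation.

The closed forms for Lévy and Cauchy come from stable-law theory; for
any other standard baseline the same curves can be obtained by
repeatedly fitting simulated exceedance samples and regressing the
posterior means on the tail level p.  Here the calibration is run on
the standard Cauchy, where the answer (xi = 1) is known.
"""

from gpdbayes import MHConfig, calibrate_relation

fit = calibrate_relation(
    "cauchy",
    p_grid=[0.90, 0.95, 0.99],
    reps=5,          # desk-scale; the reference protocol uses 100
    m=500,
    mh_settings=MHConfig(n_keep=1000, burn_in=1000, thinning=2),
    seed=31,
)
print(f"fitted shape curve (constant): xi = {fit.xi_curve[0]:.3f}   (theory: 1)")
for p in (0.90, 0.95, 0.99):
    print(f"  p={p}: calibrated sigma_Z = {fit.sigma_at(p):8.3f}   "
          f"theory 1/(pi(1-p)) = {1/(3.141592653589793*(1-p)):8.3f}")
print(f"sigma model: {fit.sigma_model} with coefficients {[round(c, 3) for c in fit.sigma_curve]}")
print("The power-law slope near -1 reproduces the (1-p)^-1 scale growth "
      "the closed form predicts for the Cauchy family.")
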