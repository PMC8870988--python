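"""A miniature MAE comparison: BMH vs classical MH.

Draws replicate Cauchy series at two sample sizes, estimates the tail
parameters by both methods, and tabulates mean absolute errors
against the known family relation.  Even this desk-scale version
shows the ordering the full study establishes: using all the data
beats using only the exceedances, dramatically so at small n.
"""

from gpdbayes import MHConfig, StudyConfig, run_mae_study

config = StudyConfig(
    families=("cauchy",),
    n_values=(32, 512),
    a_values=(1.0,),
    p=0.9,
    reps=10,
    methods=("mh", "bmh"),
    seed=41,
    mh_settings=MHConfig(n_keep=1000, burn_in=500, thinning=2),
)
result = run_mae_study(config)
cols = ["family", "method", "n", "a", "mae_xi", "mae_sigma"]
print(result.table[cols].round(3).to_string(index=False))
print(f"\n{len(result.failures)} replicate fits failed (recorded, excluded from the averages).")
print("mae_xi for BMH is zero by construction here: the Cauchy tail shape "
      "is the data-independent constant 1.  The sigma errors show the real "
      "contrast between thresholded and full-data estimation.")
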