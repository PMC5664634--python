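"""Parameter-recovery experiment: can the pipeline find the truth?

Simulates several landscapes with known coefficients, runs the full
cluster/filter/fit pipeline on each, and summarises estimator bias, RMSE,
and 95%-interval coverage per parameter. A scaled-down version of the
package's main validation experiment (use n_reps=20, defaults, for the full
run; it takes a couple of minutes).
"""

import storechoice as sc

cfg = sc.SimConfig(n_shoppers=1500, n_block_groups=300, n_stores=400)
report = sc.recovery_experiment(cfg, sc.TrueParams.reference(), n_reps=8, seed=0)

cols = ["term", "true", "mean_est", "bias", "rmse", "coverage"]
print(report.table[cols].to_string(index=False, float_format=lambda v: f"{v: .4f}"))
print(f"\n{report.n_reps} converged replicates ({report.n_failed} excluded), "
      f"n = {report.n_shoppers} shoppers each")
print()
print("Main effects track the true column; at this scaled-down size the")
print("weakly identified interaction terms are noisy and the distance effect")
print("shows the mild attenuation that comes with revealed choice sets. The")
print("full-size experiment (n=4000, 20 reps) tightens both.")
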