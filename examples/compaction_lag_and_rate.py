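"""Lag time and rate of protein-driven DNA compaction.

Wild-type ParB (Spo0J) bridges DNA and compacts flow-stretched
molecules after a molecule-to-molecule variable lag.  This script
simulates length trajectories (Gaussian lag 3.3 +/- 0.7 s, rate
0.51 +/- 0.14 um/s across molecules), fits each with the two-segment
changepoint model, and compares the recovered ensemble means to the
generator truth.
"""

import pifeflow as pf
from pifeflow.pipeline import run_compaction_experiment

preset = pf.get_preset("spo0j_wt")
res = run_compaction_experiment(preset, n_dna=50, duration_s=20.0, seed=7)
s = res["summary"]

print(f"{s['n']} of 50 molecules compacted")
print(f"mean lag  = {s['mean_lag_s']:.2f} +/- {s['sem_lag_s']:.2f} s "
      f"(generator mean {preset.lag_mean_s})")
print(f"mean rate = {s['mean_rate_um_s']:.3f} +/- {s['sem_rate_um_s']:.3f} "
      f"um/s (generator mean {preset.rate_mean_um_s})")
print("\nThe lag separates protein-association onset from compaction "
      "onset; the rate\nis the slope of the linear length decline found "
      "by exhaustive changepoint search.")
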