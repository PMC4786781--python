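"""Recover Langmuir rate constants from simulated PIFE association data.

Simulates fold-intensity trajectories of sparsely Cy3-labelled DNAs at
five protein concentrations (bridging-deficient ParB mutant preset:
k_on = 2.1e6 /M/s, k_off = 0.16 /s), fits each ensemble with
F(t) = c0 + c1(1 - exp(-k_obs t)), and regresses k_obs on concentration.
The slope is k_on, the k_off-vs-concentration intercept is k_off, and
K_d = k_off/k_on (the generator's ratio is 76.2 nM).
"""

import pifeflow as pf
from pifeflow.pipeline import run_rate_constant_recovery

preset = pf.get_preset("r82a")
rc, details = run_rate_constant_recovery(
    preset,
    association_concs_nM=(25, 50, 100, 150, 200),
    dissociation_concs_nM=(25, 50, 100),
    n_dna=25, n_replicates=3, duration_s=60.0, seed=7,
)

print("per-concentration k_obs (mean +/- s.e.m. over replicate fields):")
for c, (k, sem) in sorted(details["association"]["kobs_by_conc"].items()):
    print(f"  {c:6.0f} nM : {k:.3f} +/- {sem:.3f} /s")
print(f"k_on  = {rc.k_on_per_M_s:.3g} +/- {rc.k_on_se:.2g} /M/s "
      f"(generator: {preset.k_on_per_M_s:.3g})")
print(f"k_off = {rc.k_off_per_s:.3f} +/- {rc.k_off_se:.3f} /s "
      f"(generator: {preset.k_off_per_s})")
print(f"K_d   = {rc.kd_nM:.1f} +/- {rc.kd_se_nM:.1f} nM "
      f"(generator ratio: {preset.kd_nM:.1f})")
print("\nK_d is the equilibrium dissociation constant; agreement of the "
      "kinetic ratio\nwith the generator value validates the full "
      "simulate -> detect -> fit -> regress chain.")
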