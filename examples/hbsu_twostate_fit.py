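"""Joint two-state fit of HBsu steady-state intensity and length curves.

HBsu (a bacterial HU homolog) bends DNA at low concentration and forms a
re-extending filament at high concentration.  Each DNA segment binds up
to two dimers with stepwise dissociation constants K1 (high affinity,
bending) and K2 (low affinity, filament); each bound state has its own
fold intensity (I1, I2) and fold length (L1, L2).  The paired
steady-state curves versus concentration are fit jointly for all six
parameters.
"""

import numpy as np

import pifeflow as pf
from pifeflow.simgen import simulate_hbsu_steady_state
from pifeflow.twostate import fit_twostate, predict_curves

true = pf.get_preset("hbsu").twostate
grid = np.geomspace(1, 5000, 12)
fi, fl, _ = simulate_hbsu_steady_state(true, grid, noise_frac=0.03, rng=7)
res = fit_twostate(grid, fi, fl, n_starts=20, seed=7)
p = res.params

print("          fitted   generator")
for name, got, want in [("K1 (nM)", p.K1, true.K1), ("K2 (nM)", p.K2, true.K2),
                        ("I1", p.I1, true.I1), ("I2", p.I2, true.I2),
                        ("L1", p.L1, true.L1), ("L2", p.L2, true.L2)]:
    print(f"{name:8s} {got:8.2f} {want:10.2f}")
print(f"SSE = {res.sse:.4g}")
print("\nK1 << K2 reproduces the observed sequence: compaction (bending "
      "mode) saturates\nfirst, then further binding re-extends the DNA "
      "while intensity keeps rising.")
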