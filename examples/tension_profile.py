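"""Tension along a flow-stretched DNA from quantum-dot motion capture.

Buffer flow drags a tethered DNA, so tension falls from the tether to
the free end.  QDs at four known sites of an XbaI-digested lambda DNA
(3,530 / 9,334 / 16,755 / 22,398 bp of 23,994) report each segment's
differential extension xi = dz/ds, which maps to force through the
Marko-Siggia worm-like chain (P = 50 nm).
"""

import numpy as np

from pifeflow.simgen import simulate_qd_track
from pifeflow.tension import (MotionCaptureGeometry, WLCModel,
                              differential_extension, tensions_from_extension)

geom = MotionCaptureGeometry()
wlc = WLCModel()
true_tensions = [1.0, 0.6, 0.3, 0.1]  # pN, tether -> free end

track, _ = simulate_qd_track(geom, true_tensions, wlc=wlc, loc_sd_um=0.02,
                             n_frames=200, rng=7)
xi, xi_raw, clipped = differential_extension(track.positions_um, geom)
profile = tensions_from_extension(xi, wlc, xi_raw=xi_raw, clipped=clipped)

print("segment   xi      F (pN)   true F (pN)")
for i, (x, f, t) in enumerate(zip(profile.xi, profile.force_pN, true_tensions)):
    print(f"   {i}    {x:.3f}   {f:6.3f}    {t:6.3f}")
print("\nxi is the fractional extension of each inter-QD segment; the "
      "recovered forces\nreproduce the ~1 pN (tether) to ~0.1 pN (free end) "
      "profile despite 20 nm\nlocalization noise, averaged over 200 frames.")
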