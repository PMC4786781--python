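# Methods

`pifeflow` analyses single-molecule experiments in which surface-tethered,
flow-stretched DNA is sparsely labelled with Cy3 (about one dye per
kilobase on a 20 kb molecule) and imaged at 10 Hz. Protein binding near a
dye raises its quantum yield (protein-induced fluorescence enhancement,
PIFE), so the integrated intensity of a DNA reports protein occupancy
without labelling the protein, while the DNA's apparent length under flow
reports its conformation. Because no raw data accompany the study this
package models, every analysis stage is exercised against a synthetic-data
generator whose defaults encode the study conditions; ground-truth tables
travel with all generated data and are the only source of truth in
recovery tests.

## Models

### Langmuir binding kinetics

Binding of a non-bridging protein (the ParB/Spo0J R82A mutant is the
reference case) to independent DNA sites is reversible 1:1 binding with
free protein in vast excess. The bound fraction relaxes exponentially with
observed rate

    k_obs = k_on [protein] + k_off.

The fold increase of integrated intensity during association is fit with
F(t) = c0 + c1(1 − exp(−k_obs t)) (F_min = c0, F_max = c0 + c1); after a
wash, the normalized, photobleach-corrected intensity is fit with
I(t) = A + B exp(−k_off t) (plateau I_min = A). Regressing k_obs on
concentration (error-weighted, restricted to the linear range
≤ 200 nM — above that the relaxation outruns the 10 Hz frame rate) gives
k_on as the slope; the intercept of the k_off-versus-concentration
regression gives the concentration-independent off rate, with the slope's
p-value reported as a check that it does not differ from zero. K_d is
defined as k_off/k_on exactly. Steady-state signals are alternatively fit
with the Hill equation θ = θ_max c^n/(K_d^n + c^n) on baseline-subtracted
fold increases.

Photobleaching is corrected multiplicatively, I(t) = I0(t)·2^(t/t_half),
the unique multiplicative form consistent with a bleaching *half-life*
parameter; t_half defaults to 300 s, the lower bound of the measured
half-life, so the correction is conservative.

### Compaction changepoint model

Bridging-competent proteins compact flow-stretched DNA after a lag. A
length trajectory is fit with a continuous two-segment model — flat at L0
until the lag ends, then a linear decline at rate r — by exhaustive
search over all candidate changepoint frames (the model is linear in
(L0, r) at fixed changepoint, so each candidate is solved in closed
form). Exhaustive search is robust to the objective's non-smoothness; a
fitted slope ≤ 0 is reported as a no-compaction verdict rather than a
rate. Because a fully compacted DNA clamps at a residual length near the
tether, trajectories are trimmed at the first entry into the terminal
floor plateau (within 3 estimated noise s.d. of the running-mean minimum)
before fitting; without trimming the plateau drags the fitted slope
toward zero.

### Sequential two-dimer segment model

For HBsu (HU family), a DNA is an infinite string of identical independent
segments, each binding 0, 1 or 2 dimers with stepwise dissociation
constants K1 and K2 (nM). Occupancy weights are w = (1, c/K1, c²/(K1·K2)),
normalized to probabilities p0, p1, p2 (p0+p1+p2 = 1 identically). Whole-
DNA fold intensity and fold length are the occupancy-weighted averages of
per-state folds (I1, I2; L1, L2), with the unbound state fixed at 1. The
six parameters are fit jointly to paired intensity/length isotherms by
bounded least squares (K's in log space), minimizing SSE_I + SSE_L with
equal channel weights — both channels are order-one fold quantities, and
the relative weight is configurable since no weighting convention is
established for this fit. Twenty multi-starts (log-uniform K seeds over
the data's concentration range) guard against local minima. Mean-field
independence between segments is assumed; no inter-segment cooperativity
is modelled.

### Tension from differential extension

With point labels (quantum dots) at known sequence positions N_i of an
XbaI-digested λ DNA (defaults 3,530/9,334/16,755/22,398 bp of 23,994),
contour positions are s_i = L·N_i/N_total with L = 0.34 nm/bp · N_total =
8.158 μm by default. The differential extension of segment i is
ξ_i = (⟨z_i⟩ − ⟨z_{i−1}⟩)/(s_i − s_{i−1}) with z_0 = s_0 = 0 at the
tether; ⟨·⟩ is a time average. ξ maps to tension through the Marko–Siggia
worm-like-chain interpolation

    F(ξ) = (kBT/P)·[1/(4(1−ξ)²) − 1/4 + ξ],

with persistence length P = 50 nm and kBT = 4.114 pN·nm (25 °C), both
configurable; the inverse map (used by the simulator) is bisection to
10⁻¹² on the strictly increasing branch. Measured ξ is clipped into
[0, 1−10⁻⁶) with flags, and raw values are preserved, because
localization noise or tether-position error can push ξ past the physical
range; the first segment is the one sensitive to tether-position error,
so the tether is an explicit input (ROI metadata or simulation truth).

## Synthetic-data generator

The generator emulates, per molecule: (i) one binding site per dye (one
per kb), each an independent two-state Markov chain with per-frame
switching probabilities 1 − exp(−k_on c dt) and 1 − exp(−k_off dt); (ii)
binary PIFE — a dye is `pife_factor` (default 4.5 for the R82A preset)
times brighter while its site is occupied, collapsing the 0–4 nm distance
dependence of PIFE to site adjacency since only aggregate DNA intensity
is analysed; (iii) irreversible per-dye bleaching with per-frame
probability 1 − 2^(−dt/t_half); (iv) additive Gaussian camera noise
(default 60 counts ≈ 3% of a 20-dye baseline); (v) per-molecule Gaussian
lag and compaction rate, truncated at zero (defaults 3.3 ± 0.7 s and
0.51 ± 0.14 μm/s; the means are the study's measured values, the widths
are plausible molecule-to-molecule s.d. for tens of molecules and are
configurable — ensemble-mean recoveries do not depend on them); (vi)
movie rendering of dyes as 2-D Gaussian PSFs on a 16-bit frame (0.167 μm
pixels by default); (vii) QD tracks whose mean positions derive from a
prescribed tension profile through the inverse WLC, plus Gaussian
localization noise. All generators are reproducible given (preset, seed);
per-molecule sub-streams are spawned deterministically from the master
seed.

What the generator does *not* emulate: dye blinking and cis–trans
photophysics beyond binary PIFE, hydrodynamic coupling between flow rate
and tension (tensions are inputs), inter-site cooperativity, drift, and
non-Gaussian camera noise. Passing recovery tests therefore demonstrate
the correctness and calibration of the analysis chain under the stated
noise model, not robustness to every artefact of real movies.

## Analysis conventions and numerical choices

- Pixel coordinates are 0-based with half-open ranges; the flow axis is
  the increasing column direction with the tether on the low-column side.
- ROI background is the per-frame median of a 2-pixel border ring around
  the ROI; ROIs touching the frame edge fall back to the global
  lowest-decile median with a logged warning. Integrated intensities are
  not clipped at zero.
- The kymograph length threshold is set once per kymograph at
  b + f·(q95 − b), where b is the median of the lowest decile (an
  offset-robust background) and q95 the 95th percentile; f defaults to
  0.3. The rule is offset-invariant by construction. For compaction
  movies, dye pile-up at the tether stretches the intensity range by an
  order of magnitude, so a lower fraction (f ≈ 0.1) keeps extended frames
  above threshold — f is exposed for exactly this reason. A 3-pixel
  median filter along the position axis (default on) suppresses isolated
  pixels that would otherwise fragment or inflate the count.
- Association onset: baseline statistics come from a protein-free window
  ("first few seconds"; 2 s by default). Association is confirmed when a
  5-frame running mean exceeds baseline + 4 s.d. for 5 consecutive frames
  (< 1% false triggers on 100-frame pure-noise baselines); the reported
  onset then backtracks to the last frame inside the baseline + 1 s.d.
  band, which removes the latency the 4σ crossing accumulates on slow
  rises while leaving a clean step detected at its exact frame.
- Ensemble strategy: fits run per molecule (giving molecule-to-molecule
  spread) and on the ensemble-averaged trajectory of a 20–30-molecule
  field of view; reported per-concentration rates are the mean ± s.e.m.
  of the ensemble fits over independent replicate fields, matching how
  such measurements are replicated in practice (three or more fields per
  condition). The experiment drivers default to ten replicate fields:
  per-point s.e.m. estimates — and hence the 1/s.e.m.² regression
  weights — are unstable with only a handful, and ten brings the
  k_on recovery's sampling error to roughly half the study's own
  reported standard error. The rate regression propagates the per-point
  s.e.m.s as known variances, inflated by the standard sqrt(chi2/dof)
  scale factor whenever the line's chi-square exceeds its degrees of
  freedom. Ensemble exponential fits under occupancy noise whose
  correlation time equals the relaxation time carry a small intrinsic
  upward bias (about +2-3% of k_obs at 25-molecule fields); it is a
  property of nonlinear least squares on such data, affects slope and
  intercept proportionally, and is well inside the recovery tolerances.
- Sub-pixel localization fits offset + A·Gaussian by least squares,
  initialized at the argmax; a profile without a peak above
  background + 3 robust s.d. is an error, and a non-converged fit falls
  back to the argmax with a warning.
- Hill and association fits are bounded (n ∈ [0.1, 10];
  K_d ∈ (0, 100·max c]; k_obs ≤ 10× frame rate, above which a relaxation
  is unresolvable at 10 Hz) and multi-started where the objective has
  local minima.

## Problem sizes

The bundled experiments use the study's printed parameters at desk scale:
rate-constant recovery simulates 25 molecules per replicate field (ten
fields per point) at {25, 50, 100, 150, 200} nM (association) and
{25, 50, 100} nM (wash), 60 s at 10 Hz; compaction uses 100 molecules
over 20 s; Hill and two-state recoveries use 50 replicate fits of 8- and
12-point concentration grids. These sizes give parameter recoveries whose
uncertainties match the study's reported standard errors while each
experiment completes in seconds to a couple of minutes.

## Known limitations

- The per-dye PIFE magnitude is a free preset knob; only DNA-level fold
  changes are constrained by the study, so `pife_factor` defaults are
  chosen to reproduce those aggregate folds.
- Biphasic HBsu dissociation is outside the fitted model family (the
  steady-state two-state model is equilibrium-only), matching the scope
  of the original analysis.
- The changepoint estimator quantizes the lag to the frame grid
  (±0.05 s at 10 Hz) and assumes a single compaction event.
- `measure_length` counts all above-threshold pixels, so disconnected
  bright specks inflate length; the median filter mitigates but does not
  eliminate this.
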