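# pifeflow

Analysis of single-molecule experiments that watch **unlabelled** proteins
bind DNA. Surface-tethered, flow-stretched DNA is sparsely labelled with
Cy3 (~1 dye/kb on a 20 kb molecule); a bound protein within a few nm of a
dye raises its quantum yield (protein-induced fluorescence enhancement,
PIFE), so the DNA's integrated intensity reports protein occupancy while
its apparent length under flow reports conformation — both from the same
10 Hz movie, with no protein label. The package targets nucleoid-
associated proteins such as ParB/Spo0J (DNA bridging and compaction) and
HBsu/HU (bending-to-filament switching), but the machinery is generic.

`pifeflow` provides the full chain as a library plus a thin CLI:

- **simgen** — synthetic movies, trajectories and quantum-dot (QD) tracks
  with ground truth: per-site two-state Markov binding, binary PIFE,
  per-dye photobleaching, camera noise, Gaussian-PSF rendering.
- **imaging** — ROI integrated intensity with ring-median background,
  kymographs, thresholded DNA length, sub-pixel Gaussian localization,
  association-onset detection.
- **kinetics** — Langmuir association `F(t) = c0 + c1(1 − e^{−k_obs t})`
  and dissociation `I(t) = A + B e^{−k_off t}` fits, photobleach
  correction `I = I0·2^{t/t_half}`, weighted `k_obs = k_on[P] + k_off`
  regression (K_d = k_off/k_on), Hill isotherm
  `θ = θ_max c^n/(K_d^n + c^n)`, and a two-segment changepoint fit for
  compaction lag and rate.
- **twostate** — sequential two-dimer segment model for HBsu: weights
  (1, c/K1, c²/K1K2) give p0, p1, p2; whole-DNA fold intensity/length are
  occupancy-weighted state folds, fit jointly for
  (K1, K2, I1, I2, L1, L2).
- **tension** — differential extension ξᵢ = Δ⟨z⟩ᵢ/Δsᵢ between labelled
  sites and Marko–Siggia worm-like-chain tension
  `F = (kBT/P)[1/(4(1−ξ)²) − 1/4 + ξ]`.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Recover the Langmuir rate constants of a bridging-deficient ParB mutant
from simulated PIFE association/dissociation data
(`examples/association_kinetics.py`):

```
$ python examples/association_kinetics.py
per-concentration k_obs (mean +/- s.e.m. over replicate fields):
      25 nM : 0.229 +/- 0.030 /s
      50 nM : 0.296 +/- 0.036 /s
     100 nM : 0.395 +/- 0.060 /s
     150 nM : 0.442 +/- 0.030 /s
     200 nM : 0.657 +/- 0.053 /s
k_on  = 2e+06 +/- 3.1e+05 /M/s (generator: 2.1e+06)
k_off = 0.167 +/- 0.013 /s (generator: 0.16)
K_d   = 83.6 +/- 14.4 nM (generator ratio: 76.2)
```

k_obs grows linearly with concentration; its slope is the association
rate constant k_on, the concentration-independent dissociation rate
k_off comes from wash-phase decays, and their ratio is the equilibrium
dissociation constant K_d — recovered here within error of the values
the data were generated with, validating the whole
simulate → detect → fit → regress chain. Other examples cover compaction
lag/rate, the Hill isotherm, the HBsu two-state fit, movie rendering and
extraction, and QD tension profiles.

The CLI mirrors the library:

```
pifeflow simulate --preset spo0j_wt --out sim/ --seed 1 --n-dna 20
pifeflow extract  --stack movie.tif --rois rois.csv --out traj/
pifeflow fit compaction --in sim/trajectories.csv
pifeflow tension  --track track.csv
pifeflow run      --config experiment.yaml --out results/
```

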