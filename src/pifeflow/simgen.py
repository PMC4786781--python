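"""Synthetic-data generators for the flow-stretched PIFE assay.

Every downstream stage of the pipeline (trajectory extraction, kinetic
fitting, two-state fitting, tension estimation) is exercised on data
produced here, with ground-truth tables recording the parameters each
realization was drawn from.  The generators emulate:

* per-site reversible protein binding as independent two-state Markov
  chains (one binding site per dye, ~1 dye/kb on a 20 kb DNA);
* binary PIFE: a dye is ``pife_factor`` times brighter while its site is
  occupied;
* irreversible per-dye photobleaching with half-life ``t_half_bleach_s``;
* Gaussian camera noise on integrated intensities;
* DNA compaction with molecule-to-molecule Gaussian variation of onset
  lag and compaction rate (truncated at zero);
* steady-state intensity/length isotherms of the sequential two-dimer
  segment model;
* movie rendering of dyes as 2-D Gaussian point-spread functions on a
  16-bit camera frame;
* QD motion-capture tracks with a prescribed tension profile mapped
  through the worm-like chain to mean positions, plus localization noise.

All generators are deterministic given (preset, seed); per-molecule
randomness is drawn from sub-streams spawned from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ImageStack, OccupancyMatrix, QDTrack, Trajectory
from .presets import SimPreset
from .tension import MotionCaptureGeometry, WLCModel, invert_wlc
from .twostate import TwoStateParams, predict_curves

__all__ = [
    "GroundTruth",
    "simulate_occupancy",
    "simulate_intensity_trajectory",
    "simulate_association_trajectory",
    "simulate_dissociation_trajectory",
    "simulate_compaction_trajectory",
    "simulate_hbsu_steady_state",
    "render_movie",
    "simulate_qd_track",
]


@dataclass
class GroundTruth:
    """True per-realization parameters recorded alongside generated data."""

    lag_s: float | None = None
    rate_um_s: float | None = None
    l0_um: float | None = None
    k_obs_per_s: float | None = None
    k_off_per_s: float | None = None
    equilibrium_occupancy: float | None = None
    occupancy_fraction: np.ndarray | None = None
    per_dye_brightness: np.ndarray | None = None
    onset_s: float | None = None
    tensions_pN: np.ndarray | None = None
    dye_fractions: np.ndarray | None = None
    twostate: TwoStateParams | None = None


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def equilibrium_occupancy(preset: SimPreset, concentration_nM: float | None = None) -> float:
    """Stationary bound fraction c/(c + K_d) of the per-site Langmuir chain."""
    c = preset.concentration_nM if concentration_nM is None else concentration_nM
    return c / (c + preset.kd_nM) if c > 0 else 0.0


def simulate_occupancy(
    preset: SimPreset,
    duration_s: float,
    rng=None,
    concentration_nM: float | None = None,
    initial_occupancy: float = 0.0,
) -> OccupancyMatrix:
    """Per-site binding history as independent two-state Markov chains.

    Each of the ``preset.n_sites`` sites flips with per-frame
    probabilities p_on = 1 - exp(-k_on c dt) and
    p_off = 1 - exp(-k_off dt).  ``initial_occupancy`` sets the Bernoulli
    probability of starting bound (use the stationary value to begin a
    wash phase at equilibrium).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(rng)
    dt = preset.dt
    c_M = (preset.concentration_nM if concentration_nM is None else concentration_nM) * 1e-9
    n_frames = max(1, round(duration_s / dt))
    n_sites = preset.n_sites
    p_on = 1.0 - np.exp(-preset.k_on_per_M_s * c_M * dt)
    p_off = 1.0 - np.exp(-preset.k_off_per_s * dt)

    occ = np.empty((n_frames, n_sites), dtype=np.uint8)
    state = (rng.random(n_sites) < initial_occupancy).astype(np.uint8)
    occ[0] = state
    for t in range(1, n_frames):
        u = rng.random(n_sites)
        state = np.where(state == 1, (u >= p_off), (u < p_on)).astype(np.uint8)
        occ[t] = state
    return OccupancyMatrix(values=occ, dt=dt)


def simulate_intensity_trajectory(
    occ: OccupancyMatrix,
    preset: SimPreset,
    rng=None,
    dna_id: str = "dna0",
    concentration_nM: float | None = None,
    bleaching: bool = True,
) -> tuple[Trajectory, GroundTruth]:
    """Integrated DNA intensity from a site-occupancy history.

    Dye j in frame t contributes
    b0 * (1 + (pife_factor - 1) * occ[t, j]) * survival[t, j]; survival
    is an irreversible per-dye Bernoulli bleaching process with
    per-frame probability 1 - 2**(-dt / t_half).  The trajectory is the
    dye sum plus Gaussian camera noise.
    """
    if occ.values.size == 0:
        raise ValueError("occupancy matrix is empty")
    rng = _rng(rng)
    T, n = occ.values.shape
    dt = occ.dt
    if bleaching and np.isfinite(preset.t_half_bleach_s):
        p_bleach = 1.0 - 2.0 ** (-dt / preset.t_half_bleach_s)
        # geometric bleach frame per dye; frame k is the first dark frame
        bleach_frame = rng.geometric(p_bleach, size=n) if p_bleach > 0 else np.full(n, T + 1)
        survival = (np.arange(T)[:, None] < bleach_frame[None, :]).astype(float)
    else:
        survival = np.ones((T, n))
    per_dye = preset.dye_brightness * (
        1.0 + (preset.pife_factor - 1.0) * occ.values
    ) * survival
    total = per_dye.sum(axis=1)
    if preset.noise_sd > 0:
        total = total + rng.normal(0.0, preset.noise_sd, size=T)
    conc = preset.concentration_nM if concentration_nM is None else concentration_nM
    traj = Trajectory(time_s=np.arange(T) * dt, values=total, kind="intensity",
                      dna_id=dna_id, concentration_nM=conc)
    truth = GroundTruth(
        k_obs_per_s=preset.k_on_per_M_s * conc * 1e-9 + preset.k_off_per_s,
        k_off_per_s=preset.k_off_per_s,
        equilibrium_occupancy=conc / (conc + preset.kd_nM) if conc > 0 else 0.0,
        occupancy_fraction=occ.fraction,
        per_dye_brightness=per_dye,
    )
    return traj, truth


def simulate_association_trajectory(
    preset: SimPreset,
    duration_s: float,
    baseline_s: float = 5.0,
    rng=None,
    dna_id: str = "dna0",
    concentration_nM: float | None = None,
    bleaching: bool = False,
) -> tuple[Trajectory, GroundTruth]:
    """Protein-free baseline followed by association from empty sites.

    Protein arrives at t = ``baseline_s``; the recorded ground-truth
    onset is that time.  Bleaching is off by default: association phases
    are short (tens of seconds) next to the >=300 s bleach half-life.
    """
    rng = _rng(rng)
    n_base = round(baseline_s / preset.dt)
    occ_assoc = simulate_occupancy(preset, duration_s, rng=rng,
                                   concentration_nM=concentration_nM)
    values = np.vstack([np.zeros((n_base, preset.n_sites), dtype=np.uint8),
                        occ_assoc.values])
    occ = OccupancyMatrix(values=values, dt=preset.dt)
    traj, truth = simulate_intensity_trajectory(
        occ, preset, rng=rng, dna_id=dna_id,
        concentration_nM=concentration_nM, bleaching=bleaching)
    truth.onset_s = n_base * preset.dt
    return traj, truth


def simulate_dissociation_trajectory(
    preset: SimPreset,
    duration_s: float,
    prewash_concentration_nM: float,
    rng=None,
    dna_id: str = "dna0",
    bleaching: bool = True,
) -> tuple[Trajectory, GroundTruth]:
    """Wash phase: sites start at the pre-wash equilibrium, free protein = 0."""
    rng = _rng(rng)
    p0 = equilibrium_occupancy(preset, prewash_concentration_nM)
    occ = simulate_occupancy(preset, duration_s, rng=rng, concentration_nM=0.0,
                             initial_occupancy=p0)
    traj, truth = simulate_intensity_trajectory(
        occ, preset, rng=rng, dna_id=dna_id,
        concentration_nM=prewash_concentration_nM, bleaching=bleaching)
    truth.equilibrium_occupancy = p0
    return traj, truth


def _truncated_normal(rng, mean, sd):
    """Gaussian draw rejected below zero (degenerate sd = 0 allowed)."""
    if sd == 0:
        return float(max(mean, 0.0))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0  # pragma: no cover - pathological mean << -sd


def simulate_compaction_trajectory(
    preset: SimPreset,
    duration_s: float,
    rng=None,
    dna_id: str = "dna0",
) -> tuple[Trajectory, GroundTruth]:
    """DNA length during protein-driven compaction.

    Onset lag and compaction rate are drawn per molecule from Gaussians
    (truncated at zero) with the preset means and s.d.; the length is
    flat at L0 before the lag, declines linearly at the drawn rate, and
    clamps at the residual floor near the tether.  Additive Gaussian
    measurement noise on length.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if duration_s <= preset.lag_mean_s:
        raise ValueError("duration must exceed the mean lag time")
    rng = _rng(rng)
    lag = _truncated_normal(rng, preset.lag_mean_s, preset.lag_sd_s)
    rate = _truncated_normal(rng, preset.rate_mean_um_s, preset.rate_sd_um_s)
    t = np.arange(round(duration_s / preset.dt)) * preset.dt
    length = np.where(t < lag, preset.l0_um,
                      np.maximum(preset.l_floor_um,
                                 preset.l0_um - rate * (t - lag)))
    if preset.length_noise_sd_um > 0:
        length = length + rng.normal(0.0, preset.length_noise_sd_um, size=t.size)
    traj = Trajectory(time_s=t, values=length, kind="length", dna_id=dna_id,
                      concentration_nM=preset.concentration_nM)
    truth = GroundTruth(lag_s=lag, rate_um_s=rate, l0_um=preset.l0_um, onset_s=0.0)
    return traj, truth


def simulate_hbsu_steady_state(
    params: TwoStateParams,
    conc_grid_nM,
    noise_frac: float = 0.03,
    rng=None,
):
    """Noisy paired steady-state fold-intensity and fold-length curves.

    Evaluates the sequential two-dimer model on the concentration grid
    and applies multiplicative Gaussian noise of fractional s.d.
    ``noise_frac`` (e.g. 0.03 for 3% measurement scatter) to each point.
    Returns (fold_intensity, fold_length, true_params).
    """
    c = np.asarray(conc_grid_nM, dtype=float)
    if c.size == 0:
        raise ValueError("concentration grid is empty")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    rng = _rng(rng)
    fi, fl = predict_curves(c, params)
    if noise_frac > 0:
        fi = fi * (1.0 + rng.normal(0.0, noise_frac, size=c.shape))
        fl = fl * (1.0 + rng.normal(0.0, noise_frac, size=c.shape))
    return fi, fl, params


def simulate_hill_steady_state(
    preset: SimPreset,
    conc_grid_nM,
    n_replicates: int = 25,
    noise_frac: float = 0.05,
    rng=None,
) -> np.ndarray:
    """Baseline-subtracted steady-state binding signals from a Hill isotherm.

    Evaluates theta = theta_max c^n / (K_d^n + c^n) with the preset's
    apparent Hill parameters, draws ``n_replicates`` noisy molecules per
    concentration (fractional Gaussian noise ``noise_frac``), and
    returns the per-concentration replicate means.
    """
    if preset.hill_kd_nM is None:
        raise ValueError("preset has no apparent Hill parameters")
    c = np.asarray(conc_grid_nM, dtype=float)
    rng = _rng(rng)
    cn = np.power(c, preset.hill_n)
    theta = preset.hill_theta_max * cn / (preset.hill_kd_nM ** preset.hill_n + cn)
    reps = theta[None, :] * (1.0 + rng.normal(0.0, noise_frac,
                                              size=(n_replicates, c.size)))
    return reps.mean(axis=0)


def render_movie(
    dnas: list[dict],
    preset: SimPreset,
    frame_shape: tuple[int, int] = (32, 96),
    psf_sigma_px: float = 1.0,
    baseline_counts: float = 100.0,
    read_noise_sd: float = 0.0,
    rng=None,
) -> tuple[ImageStack, list[GroundTruth]]:
    """Render DNAs as rows of Gaussian-PSF dyes on a 16-bit camera frame.

    Each entry of ``dnas`` is a dict with keys ``tether_rc`` (row, col of
    the tether pixel), ``lengths_um`` (per-frame extension) and
    ``per_dye_brightness`` ([T x n_dyes] counts, e.g. the ground truth of
    :func:`simulate_intensity_trajectory`).  Dye j sits at contour
    fraction (j + 0.5)/n and projects to
    x = tether_col + fraction * L(t)/pixel_size along the flow axis.
    """
    if psf_sigma_px <= 0 or preset.pixel_size_um <= 0:
        raise ValueError("pixel size and PSF width must be positive")
    rng = _rng(rng)
    H, W = frame_shape
    truths = []
    T = None
    for d in dnas:
        lengths = np.asarray(d["lengths_um"], float)
        bright = np.asarray(d["per_dye_brightness"], float)
        if T is None:
            T = lengths.size
        if lengths.size != T or bright.shape[0] != T:
            raise ValueError("all DNAs must share the same number of frames")
        r, c0 = d["tether_rc"]
        if c0 + lengths.max() / preset.pixel_size_um >= W - 1:
            raise ValueError("DNA extends past the frame width")

    frames = np.full((T, H, W), baseline_counts, dtype=float)
    yy = np.arange(H)[:, None]
    xx = np.arange(W)[None, :]
    for d in dnas:
        lengths = np.asarray(d["lengths_um"], float)
        bright = np.asarray(d["per_dye_brightness"], float)
        n_dyes = bright.shape[1]
        fractions = (np.arange(n_dyes) + 0.5) / n_dyes
        r, c0 = d["tether_rc"]
        for t in range(T):
            x_px = c0 + fractions * lengths[t] / preset.pixel_size_um
            for j in range(n_dyes):
                if bright[t, j] == 0:
                    continue
                g = np.exp(-((yy - r) ** 2 + (xx - x_px[j]) ** 2)
                           / (2.0 * psf_sigma_px ** 2))
                frames[t] += bright[t, j] * g / (2.0 * np.pi * psf_sigma_px ** 2)
        truths.append(GroundTruth(dye_fractions=fractions,
                                  per_dye_brightness=bright))
    if read_noise_sd > 0:
        frames = frames + rng.normal(0.0, read_noise_sd, size=frames.shape)
    pixels = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    stack = ImageStack(pixels=pixels, frame_interval_s=preset.dt,
                       pixel_size_um=preset.pixel_size_um)
    return stack, truths


def simulate_qd_track(
    geometry: MotionCaptureGeometry,
    tensions_pN,
    wlc: WLCModel = WLCModel(),
    loc_sd_um: float = 0.02,
    n_frames: int = 100,
    rng=None,
) -> tuple[QDTrack, GroundTruth]:
    """QD positions along a flow-stretched DNA with a given tension profile.

    Segment i (between labelled sites i-1 and i) carries tension F_i; its
    fractional extension is the WLC inverse of F_i, so the mean position
    of site i is the cumulative sum of extension * contour length over
    the segments up to it.  Observed positions add Gaussian localization
    noise of s.d. ``loc_sd_um``.
    """
    tensions = np.asarray(tensions_pN, dtype=float)
    ds = geometry.segment_lengths_um
    if tensions.size != ds.size:
        raise ValueError("need one tension per inter-site segment")
    if np.any(tensions <= 0):
        raise ValueError("tensions must be positive")
    rng = _rng(rng)
    x = np.asarray(invert_wlc(tensions, wlc))
    z_mean = np.cumsum(x * ds)
    positions = np.tile(z_mean, (n_frames, 1))
    if loc_sd_um > 0:
        positions = positions + rng.normal(0.0, loc_sd_um, size=positions.shape)
    track = QDTrack(positions_um=positions, localization_sd_um=loc_sd_um)
    truth = GroundTruth(tensions_pN=tensions)
    return track, truth
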