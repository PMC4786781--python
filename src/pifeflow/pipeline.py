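"""End-to-end synthetic experiments and pipeline orchestration.

Each ``run_*_experiment`` function generates data with
:mod:`pifeflow.simgen` under a master seed, pushes it through the
analysis chain, and returns the recovered quantities next to the
generator truth, mirroring how the corresponding wet experiment is
analysed:

* association/dissociation: per-DNA trajectories are fit individually
  (giving the molecule-to-molecule s.e.m.) while the reported rate at
  each concentration comes from the fit of the ensemble-averaged
  trajectory, the same averaging used for measured 20-30-DNA fields of
  view;
* rate constants: error-weighted regression of k_obs (and k_off) on
  concentration within the linear range, K_d = k_off / k_on;
* compaction: per-molecule changepoint fits summarized by mean lag and
  rate;
* Hill and two-state: steady-state isotherm fits, replicated to measure
  fit-to-fit scatter.

:func:`run_pipeline` dispatches a config dict (or YAML file) to these
experiments and writes CSV/JSON outputs deterministically under
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import simgen
from .containers import Trajectory
from .imaging import detect_association_start
from .kinetics import (
    PhotobleachModel,
    RateConstants,
    correct_photobleaching,
    estimate_lag_and_rate,
    estimate_rate_constants,
    fit_association,
    fit_dissociation,
    fit_hill,
    normalize_fold,
)
from .presets import SimPreset, get_preset, load_preset
from .twostate import fit_twostate

log = logging.getLogger(__name__)

__all__ = [
    "run_association_experiment",
    "run_dissociation_experiment",
    "run_rate_constant_recovery",
    "run_compaction_experiment",
    "run_hill_experiment",
    "run_twostate_experiment",
    "run_qd_tension_experiment",
    "run_pipeline",
]

DEFAULT_BASELINE_S = 2.0  # "first few seconds" used for fold normalization


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# association / dissociation kinetics


def run_association_experiment(
    preset: SimPreset,
    concentrations_nM,
    n_dna: int = 25,
    n_replicates: int = 10,
    duration_s: float = 60.0,
    baseline_s: float = 5.0,
    seed: int = 0,
) -> dict:
    """Simulate association at several concentrations and recover k_obs.

    Per concentration, ``n_replicates`` independent fields of view of
    ``n_dna`` molecules each are simulated with a protein-free baseline.
    Within a replicate every fold trajectory is fit from its detected
    onset (recorded per DNA), and the replicate's k_obs comes from the
    fit of the ensemble-averaged fold trajectory — the same 20-30-DNA
    averaging applied to measured fields of view.  Each concentration
    reports mean +/- s.e.m. of k_obs over the replicate fields.

    Returns ``{"kobs_by_conc": {c: (mean, sem)}, "per_dna": DataFrame,
    "excluded": int}``.
    """
    bw = round(DEFAULT_BASELINE_S / preset.dt)
    concs = list(concentrations_nM)
    rngs = _spawn(seed, len(concs) * n_replicates)
    kobs_by_conc: dict[float, tuple[float, float]] = {}
    rows = []
    excluded = 0
    for ci, c in enumerate(concs):
        rep_kobs = []
        for r in range(n_replicates):
            rng = rngs[ci * n_replicates + r]
            folds = []
            for i in range(n_dna):
                traj, truth = simgen.simulate_association_trajectory(
                    preset, duration_s, baseline_s=baseline_s, rng=rng,
                    dna_id=f"c{c:g}_r{r}_dna{i}", concentration_nM=c)
                try:
                    fold = normalize_fold(traj, bw)
                except ValueError:
                    excluded += 1
                    continue
                folds.append(fold)
                t0 = detect_association_start(fold, baseline_window=bw)
                if t0 is None:
                    excluded += 1
                    continue
                fit = fit_association(_slice_from(fold, t0))
                if not fit.converged:
                    excluded += 1
                    continue
                rows.append({"conc_nM": c, "replicate": r,
                             "dna_id": traj.dna_id,
                             "kobs_per_s": fit.k_obs_per_s,
                             "true_kobs_per_s": truth.k_obs_per_s})
            mean_fold = _ensemble_mean(folds)
            t0 = detect_association_start(mean_fold, baseline_window=bw)
            if t0 is None:
                log.warning("no onset detected in ensemble at %g nM", c)
                continue
            ens_fit = fit_association(_slice_from(mean_fold, t0))
            if ens_fit.converged:
                rep_kobs.append(ens_fit.k_obs_per_s)
        if not rep_kobs:
            continue
        sem = (float(np.std(rep_kobs, ddof=1) / np.sqrt(len(rep_kobs)))
               if len(rep_kobs) > 1 else 0.0)
        kobs_by_conc[float(c)] = (float(np.mean(rep_kobs)), sem)
    return {"kobs_by_conc": kobs_by_conc,
            "per_dna": pd.DataFrame(rows), "excluded": excluded}


def run_dissociation_experiment(
    preset: SimPreset,
    prewash_concentrations_nM,
    n_dna: int = 25,
    n_replicates: int = 10,
    duration_s: float = 60.0,
    seed: int = 0,
) -> dict:
    """Simulate wash phases and recover k_off per pre-wash concentration.

    Trajectories include photobleaching and are corrected with the
    preset's bleach half-life before normalization and fitting.  As for
    association, each concentration is measured as mean +/- s.e.m. of the
    ensemble-fit k_off over ``n_replicates`` replicate fields of view.
    """
    model = PhotobleachModel(preset.t_half_bleach_s)
    norm_frames = max(3, round(0.5 / preset.dt))
    concs = list(prewash_concentrations_nM)
    rngs = _spawn(seed, len(concs) * n_replicates)
    koff_by_conc: dict[float, tuple[float, float]] = {}
    rows = []
    for ci, c in enumerate(concs):
        rep_koff = []
        for r in range(n_replicates):
            rng = rngs[ci * n_replicates + r]
            trajs = []
            for i in range(n_dna):
                traj, _ = simgen.simulate_dissociation_trajectory(
                    preset, duration_s, prewash_concentration_nM=c, rng=rng,
                    dna_id=f"c{c:g}_r{r}_dna{i}")
                corrected = correct_photobleaching(traj, model)
                norm = normalize_fold(corrected, norm_frames)
                trajs.append(norm)
                fit = fit_dissociation(norm)
                if fit.converged and not fit.degenerate:
                    rows.append({"conc_nM": c, "replicate": r,
                                 "dna_id": traj.dna_id,
                                 "koff_per_s": fit.k_off_per_s})
            ens = fit_dissociation(_ensemble_mean(trajs))
            if ens.converged and not ens.degenerate:
                rep_koff.append(ens.k_off_per_s)
        if not rep_koff:
            continue
        sem = (float(np.std(rep_koff, ddof=1) / np.sqrt(len(rep_koff)))
               if len(rep_koff) > 1 else 0.0)
        koff_by_conc[float(c)] = (float(np.mean(rep_koff)), sem)
    return {"koff_by_conc": koff_by_conc, "per_dna": pd.DataFrame(rows)}


def run_rate_constant_recovery(
    preset: SimPreset,
    association_concs_nM=(25.0, 50.0, 100.0, 150.0, 200.0),
    dissociation_concs_nM=(25.0, 50.0, 100.0),
    n_dna: int = 25,
    n_replicates: int = 10,
    duration_s: float = 60.0,
    seed: int = 0,
) -> tuple[RateConstants, dict]:
    """Full kinetic recovery: association + dissociation + regression."""
    assoc = run_association_experiment(preset, association_concs_nM,
                                       n_dna=n_dna, n_replicates=n_replicates,
                                       duration_s=duration_s, seed=seed)
    dissoc = run_dissociation_experiment(preset, dissociation_concs_nM,
                                         n_dna=n_dna, n_replicates=n_replicates,
                                         duration_s=duration_s, seed=seed + 1)
    rc = estimate_rate_constants(assoc["kobs_by_conc"], dissoc["koff_by_conc"])
    return rc, {"association": assoc, "dissociation": dissoc}


def _slice_from(traj: Trajectory, index: int) -> Trajectory:
    return Trajectory(time_s=traj.time_s[index:], values=traj.values[index:],
                      kind=traj.kind, dna_id=traj.dna_id,
                      concentration_nM=traj.concentration_nM)


def _ensemble_mean(trajs: list[Trajectory]) -> Trajectory:
    n = min(t.values.size for t in trajs)
    stackv = np.vstack([t.values[:n] for t in trajs])
    return Trajectory(time_s=trajs[0].time_s[:n], values=stackv.mean(axis=0),
                      kind=trajs[0].kind, dna_id="ensemble",
                      concentration_nM=trajs[0].concentration_nM)


# ---------------------------------------------------------------------------
# compaction


def run_compaction_experiment(
    preset: SimPreset,
    n_dna: int = 100,
    duration_s: float = 20.0,
    seed: int = 0,
) -> dict:
    """Simulate compaction trajectories and recover lag and rate per DNA.

    Returns per-DNA recovered/true values plus the ensemble summary
    (mean and s.e.m. of lag and rate over compacting molecules).
    """
    rngs = _spawn(seed, n_dna)
    rows = []
    for i, rng in enumerate(rngs):
        traj, truth = simgen.simulate_compaction_trajectory(
            preset, duration_s, rng=rng, dna_id=f"dna{i}")
        fit = estimate_lag_and_rate(traj, t0_s=0.0)
        rows.append({"dna_id": traj.dna_id, "lag_s": fit.t_lag_s,
                     "rate_um_s": fit.rate_um_s,
                     "no_compaction": fit.no_compaction,
                     "true_lag_s": truth.lag_s,
                     "true_rate_um_s": truth.rate_um_s})
    df = pd.DataFrame(rows)
    ok = df[~df.no_compaction]
    summary = {
        "n": int(len(ok)),
        "mean_lag_s": float(ok.lag_s.mean()),
        "sem_lag_s": float(ok.lag_s.std(ddof=1) / np.sqrt(len(ok))),
        "mean_rate_um_s": float(ok.rate_um_s.mean()),
        "sem_rate_um_s": float(ok.rate_um_s.std(ddof=1) / np.sqrt(len(ok))),
    }
    return {"per_dna": df, "summary": summary}


# ---------------------------------------------------------------------------
# steady-state isotherms


def run_hill_experiment(
    preset: SimPreset,
    conc_grid_nM=None,
    n_replicates: int = 25,
    noise_frac: float = 0.05,
    n_fits: int = 50,
    seed: int = 0,
) -> dict:
    """Replicated Hill fits of synthetic steady-state binding signals."""
    if conc_grid_nM is None:
        conc_grid_nM = np.geomspace(10.0, 1000.0, 8)
    c = np.asarray(conc_grid_nM, float)
    rngs = _spawn(seed, n_fits)
    kds, ns = [], []
    for rng in rngs:
        theta = simgen.simulate_hill_steady_state(
            preset, c, n_replicates=n_replicates, noise_frac=noise_frac,
            rng=rng)
        fit = fit_hill(c, theta)
        if fit.converged:
            kds.append(fit.kd_nM)
            ns.append(fit.n)
    kds, ns = np.array(kds), np.array(ns)
    return {
        "kd_nM": float(kds.mean()),
        "kd_se": float(kds.std(ddof=1) / np.sqrt(kds.size)),
        "n": float(ns.mean()),
        "n_se": float(ns.std(ddof=1) / np.sqrt(ns.size)),
        "n_fits": int(kds.size),
        "true_kd_nM": preset.hill_kd_nM,
        "true_n": preset.hill_n,
    }


def run_twostate_experiment(
    preset: SimPreset,
    conc_grid_nM=None,
    noise_frac: float = 0.03,
    n_fits: int = 50,
    n_starts: int = 20,
    seed: int = 0,
) -> dict:
    """Replicated joint two-state fits of paired noisy isotherms."""
    if preset.twostate is None:
        raise ValueError("preset carries no two-state parameters")
    if conc_grid_nM is None:
        conc_grid_nM = np.geomspace(1.0, 5000.0, 12)
    c = np.asarray(conc_grid_nM, float)
    rngs = _spawn(seed, n_fits)
    k1s, k2s = [], []
    for j, rng in enumerate(rngs):
        fi, fl, _ = simgen.simulate_hbsu_steady_state(
            preset.twostate, c, noise_frac=noise_frac, rng=rng)
        res = fit_twostate(c, fi, fl, n_starts=n_starts,
                           seed=int(rng.integers(2**31)))
        if res.converged:
            k1s.append(res.params.K1)
            k2s.append(res.params.K2)
    k1s, k2s = np.array(k1s), np.array(k2s)
    return {
        "k1_nM": float(np.median(k1s)),
        "k1_se": float(k1s.std(ddof=1) / np.sqrt(k1s.size)),
        "k2_nM": float(np.median(k2s)),
        "k2_se": float(k2s.std(ddof=1) / np.sqrt(k2s.size)),
        "n_fits": int(k1s.size),
        "true_k1_nM": preset.twostate.K1,
        "true_k2_nM": preset.twostate.K2,
    }


# ---------------------------------------------------------------------------
# tension


def run_qd_tension_experiment(
    tensions_pN=(1.0, 0.6, 0.3, 0.1),
    loc_sd_um: float = 0.02,
    n_frames: int = 200,
    seed: int = 0,
) -> dict:
    """Simulate a QD motion-capture track and recover segment tensions."""
    from .tension import (MotionCaptureGeometry, WLCModel,
                          differential_extension, tensions_from_extension)
    geom = MotionCaptureGeometry()
    wlc = WLCModel()
    track, truth = simgen.simulate_qd_track(
        geom, tensions_pN, wlc=wlc, loc_sd_um=loc_sd_um, n_frames=n_frames,
        rng=np.random.default_rng(seed))
    xi, xi_raw, clipped = differential_extension(track.positions_um, geom)
    profile = tensions_from_extension(xi, wlc, xi_raw=xi_raw, clipped=clipped)
    return {"recovered_pN": profile.force_pN.tolist(),
            "true_pN": list(tensions_pN), "xi": xi.tolist()}


# ---------------------------------------------------------------------------
# orchestration


_EXPERIMENTS = {
    "association", "dissociation", "rates", "compaction", "hill",
    "twostate", "tension",
}


def _resolve_preset(config: dict) -> SimPreset:
    name = config.get("preset", "r82a")
    if isinstance(name, str) and Path(name).suffix in (".yml", ".yaml"):
        preset = load_preset(name)
    else:
        preset = get_preset(name)
    overrides = config.get("overrides") or {}
    return preset.replace(**overrides) if overrides else preset


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run one experiment described by a config dict or YAML file.

    Config keys: ``experiment`` (one of association, dissociation, rates,
    compaction, hill, twostate, tension), ``preset`` (name or YAML path),
    ``seed``, optional ``overrides`` (preset field overrides) and
    experiment-specific keyword arguments under ``params``.  Writes
    ``report.json`` (plus per-DNA CSVs where applicable) into
    ``out_dir`` and returns the report dict.  All randomness derives
    from the master seed, so (config, seed) determines every output.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    exp = config.get("experiment")
    if exp not in _EXPERIMENTS:
        raise ValueError(
            f"config error at 'experiment': got {exp!r}, "
            f"expected one of {sorted(_EXPERIMENTS)}")
    seed = int(config.get("seed", 0))
    if seed < 0:
        raise ValueError("config error at 'seed': must be a nonnegative integer")
    params = dict(config.get("params") or {})
    preset = _resolve_preset(config) if exp != "tension" else None

    report: dict = {
        "experiment": exp,
        "seed": seed,
        "preset": preset.name if preset is not None else None,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "version": _version,
    }
    tables: dict[str, pd.DataFrame] = {}

    if exp == "association":
        res = run_association_experiment(preset, seed=seed, **params)
        report["kobs_by_conc"] = {str(k): list(v)
                                  for k, v in res["kobs_by_conc"].items()}
        report["excluded"] = res["excluded"]
        tables["per_dna_kobs"] = res["per_dna"]
    elif exp == "dissociation":
        res = run_dissociation_experiment(preset, seed=seed, **params)
        report["koff_by_conc"] = {str(k): list(v)
                                  for k, v in res["koff_by_conc"].items()}
        tables["per_dna_koff"] = res["per_dna"]
    elif exp == "rates":
        rc, details = run_rate_constant_recovery(preset, seed=seed, **params)
        report["rate_constants"] = {
            "kon_per_M_s": rc.k_on_per_M_s, "kon_se": rc.k_on_se,
            "koff_per_s": rc.k_off_per_s, "koff_se": rc.k_off_se,
            "kd_nM": rc.kd_nM, "kd_se_nM": rc.kd_se_nM,
        }
        tables["per_dna_kobs"] = details["association"]["per_dna"]
        tables["per_dna_koff"] = details["dissociation"]["per_dna"]
    elif exp == "compaction":
        res = run_compaction_experiment(preset, seed=seed, **params)
        report["summary"] = res["summary"]
        tables["per_dna_compaction"] = res["per_dna"]
    elif exp == "hill":
        report["hill"] = run_hill_experiment(preset, seed=seed, **params)
    elif exp == "twostate":
        report["twostate"] = run_twostate_experiment(preset, seed=seed, **params)
    elif exp == "tension":
        report["tension"] = run_qd_tension_experiment(seed=seed, **params)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.12g")
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
    return report
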