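"""Langmuir binding kinetics, Hill isotherms and compaction fitting.

For a protein binding independent DNA sites in a reversible 1:1
(Langmuir) reaction with free protein in vast excess, the bound fraction
relaxes exponentially with observed rate k_obs = k_on [protein] + k_off.
The fold increase of integrated DNA intensity during association is fit
with

    F(t) = c0 + c1 * (1 - exp(-k_obs t)),

where F_min = c0 at t = 0 and F_max = c0 + c1 at steady state.  After a
wash (free protein removed), the normalized, photobleach-corrected
intensity decays as

    I(t) = A + B * exp(-k_off t),

with I_max = A + B and plateau I_min = A.  Regressing k_obs on
concentration gives k_on (slope); the k_off-versus-concentration
intercept gives the concentration-independent dissociation rate, and
K_d = k_off / k_on.  Steady-state binding signals versus concentration
are fit with the Hill equation
theta = theta_max c^n / (K_d^n + c^n).

Compaction trajectories (DNA length versus time) are fit with a
continuous two-segment changepoint model: flat at L0 until the lag ends,
then a linear decline at the compaction rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy import stats

from .containers import Trajectory

__all__ = [
    "LangmuirAssociationFit",
    "DissociationFit",
    "RateConstants",
    "HillFit",
    "PhotobleachModel",
    "CompactionFit",
    "normalize_fold",
    "correct_photobleaching",
    "fit_association",
    "fit_dissociation",
    "estimate_rate_constants",
    "fit_hill",
    "estimate_lag_and_rate",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class LangmuirAssociationFit:
    c0: float                 # F at t = 0
    c1: float                 # amplitude; F_max = c0 + c1
    k_obs_per_s: float
    sse: float
    cov: np.ndarray | None = None
    converged: bool = True

    @property
    def f_min(self) -> float:
        return self.c0

    @property
    def f_max(self) -> float:
        return self.c0 + self.c1

    @property
    def k_obs_se(self) -> float:
        return float(np.sqrt(self.cov[2, 2])) if self.cov is not None else float("nan")


@dataclass
class DissociationFit:
    A: float                  # plateau I_min
    B: float                  # I_max = A + B
    k_off_per_s: float
    sse: float
    cov: np.ndarray | None = None
    converged: bool = True
    degenerate: bool = False  # B ~ 0: k_off unidentifiable

    @property
    def i_max(self) -> float:
        return self.A + self.B

    @property
    def i_min(self) -> float:
        return self.A


@dataclass
class RateConstants:
    """k_on, k_off and K_d from the concentration dependence of the rates."""

    k_on_per_M_s: float
    k_on_se: float
    k_off_per_s: float
    k_off_se: float
    kobs_intercept_per_s: float
    koff_slope_per_nM_s: float = float("nan")
    koff_slope_pvalue: float = float("nan")

    @property
    def kd_M(self) -> float:
        return self.k_off_per_s / self.k_on_per_M_s

    @property
    def kd_nM(self) -> float:
        return self.kd_M * 1e9

    @property
    def kd_se_nM(self) -> float:
        """Propagated s.e. of the ratio k_off/k_on (independent errors)."""
        rel = np.sqrt((self.k_off_se / self.k_off_per_s) ** 2
                      + (self.k_on_se / self.k_on_per_M_s) ** 2)
        return float(self.kd_nM * rel)


@dataclass
class HillFit:
    theta_max: float
    kd_nM: float
    n: float
    sse: float
    cov: np.ndarray | None = None
    converged: bool = True

    @property
    def kd_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1])) if self.cov is not None else float("nan")

    @property
    def n_se(self) -> float:
        return float(np.sqrt(self.cov[2, 2])) if self.cov is not None else float("nan")


@dataclass(frozen=True)
class PhotobleachModel:
    """Single-exponential bleaching with half-life t_half (s)."""

    t_half_s: float = 300.0

    def __post_init__(self) -> None:
        if self.t_half_s <= 0:
            raise ValueError("t_half must be positive")


@dataclass
class CompactionFit:
    t_lag_s: float            # time from t0 to compaction onset
    rate_um_s: float
    l0_um: float
    sse: float
    no_compaction: bool = False
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trajectory transforms


def normalize_fold(traj: Trajectory, baseline_window: int) -> Trajectory:
    """Fold trajectory F(t) = I(t) / mean(first ``baseline_window`` frames).

    The baseline is the protein-free stretch before association; its mean
    must be positive (otherwise the trajectory is rejected).
    """
    base = traj.values[:baseline_window]
    mu = float(base.mean())
    if not mu > 0:
        raise ValueError("baseline mean must be positive to normalize")
    return Trajectory(time_s=traj.time_s, values=traj.values / mu, kind="fold",
                      dna_id=traj.dna_id, concentration_nM=traj.concentration_nM,
                      flags=dict(traj.flags))


def correct_photobleaching(traj: Trajectory,
                           model: PhotobleachModel) -> Trajectory:
    """Undo exponential bleaching: I(t) = I0(t) * 2**(t / t_half)."""
    factor = 2.0 ** (traj.time_s / model.t_half_s)
    return Trajectory(time_s=traj.time_s, values=traj.values * factor,
                      kind=traj.kind, dna_id=traj.dna_id,
                      concentration_nM=traj.concentration_nM,
                      flags=dict(traj.flags))


# ---------------------------------------------------------------------------
# exponential relaxation fits


def _assoc_model(t, c0, c1, k):
    return c0 + c1 * (1.0 - np.exp(-k * t))


def fit_association(traj: Trajectory) -> LangmuirAssociationFit:
    """Fit F(t) = c0 + c1 (1 - exp(-k_obs t)) to a fold trajectory.

    Time is taken relative to the first sample (detected onset t0).
    Initialization: c0 = F(0), c1 = max(F) - F(0), k_obs = 1/(time to
    half amplitude); k_obs is bounded by 10x the frame rate, above which
    a relaxation cannot be resolved.
    """
    t = traj.time_s - traj.time_s[0]
    y = traj.values
    if t.size < 20:
        raise ValueError("need at least 20 frames to fit association")
    c0_0 = float(y[0])
    c1_0 = max(float(y.max() - y[0]), 1e-6)
    half = c0_0 + 0.5 * c1_0
    above = np.flatnonzero(y >= half)
    t_half = t[above[0]] if above.size and above[0] > 0 else (t[1] or 1.0)
    k0 = min(1.0 / max(t_half, t[1] if t.size > 1 else 0.1), 1.0 / traj.dt)
    k_max = 10.0 / traj.dt
    try:
        popt, pcov = curve_fit(
            _assoc_model, t, y, p0=[c0_0, c1_0, k0],
            bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, k_max]),
            maxfev=10000,
        )
    except RuntimeError:
        return LangmuirAssociationFit(c0=np.nan, c1=np.nan, k_obs_per_s=np.nan,
                                      sse=np.inf, converged=False)
    sse = float(np.sum((_assoc_model(t, *popt) - y) ** 2))
    return LangmuirAssociationFit(c0=float(popt[0]), c1=float(popt[1]),
                                  k_obs_per_s=float(popt[2]), sse=sse, cov=pcov)


def _dissoc_model(t, a, b, k):
    return a + b * np.exp(-k * t)


def fit_dissociation(traj: Trajectory) -> DissociationFit:
    """Fit I(t) = A + B exp(-k_off t) to a normalized wash-phase trajectory.

    The trajectory should start at wash onset (I(0) near 1) and be
    photobleach-corrected first.  A flat trajectory (B ~ 0) leaves k_off
    unidentifiable and is flagged degenerate.
    """
    t = traj.time_s - traj.time_s[0]
    y = traj.values
    a0 = float(y[-1])
    b0 = float(y[0] - y[-1])
    if abs(b0) < 1e-3 * max(abs(a0), 1.0) and np.ptp(y) < 1e-6 * max(abs(a0), 1.0):
        return DissociationFit(A=a0, B=0.0, k_off_per_s=np.nan, sse=0.0,
                               degenerate=True)
    drop = a0 + 0.5 * b0
    below = np.flatnonzero(y <= drop)
    t_half = t[below[0]] if below.size and below[0] > 0 else (t[-1] / 4 or 1.0)
    k0 = 1.0 / max(t_half, traj.dt)
    try:
        popt, pcov = curve_fit(
            _dissoc_model, t, y, p0=[a0, max(b0, 1e-6), k0],
            bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, 10.0 / traj.dt]),
            maxfev=10000,
        )
    except RuntimeError:
        return DissociationFit(A=np.nan, B=np.nan, k_off_per_s=np.nan,
                               sse=np.inf, converged=False)
    sse = float(np.sum((_dissoc_model(t, *popt) - y) ** 2))
    return DissociationFit(A=float(popt[0]), B=float(popt[1]),
                           k_off_per_s=float(popt[2]), sse=sse, cov=pcov)


# ---------------------------------------------------------------------------
# concentration dependence


def _weighted_line(x, y, sem):
    """Error-weighted least-squares line.

    With per-point standard errors the parameter errors are propagated
    from them directly (known-variance weighting) — residual-based
    rescaling alone would rest on the 1-2 degrees of freedom such
    calibration lines leave and be wildly unstable.  When the fit's
    chi-square exceeds its degrees of freedom, the propagated errors are
    inflated by sqrt(chi2/dof) (the standard scale-factor treatment for
    point errors that underestimate the true scatter).  Without errors,
    an ordinary unweighted fit with residual-based parameter errors is
    used.  Returns (slope, intercept, slope_se, intercept_se, p_slope).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    have_sem = sem is not None and not np.any(np.asarray(sem) <= 0)
    w = 1.0 / np.asarray(sem, float) ** 2 if have_sem else np.ones_like(x)
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    dof = x.size - 2
    resid = y - (intercept + slope * x)
    chi2 = np.sum(w * resid ** 2)
    if have_sem:
        s2 = max(1.0, chi2 / dof) if dof > 0 else 1.0
    else:
        s2 = chi2 / dof if dof > 0 else np.nan
    slope_se = np.sqrt(s2 / sxx)
    intercept_se = np.sqrt(s2 * (1.0 / W + xbar ** 2 / sxx))
    tstat = slope / slope_se if slope_se > 0 else np.inf
    df_test = dof if dof > 0 else 1
    pval = 2.0 * stats.t.sf(abs(tstat), df_test) if dof > 0 else np.nan
    return slope, intercept, slope_se, intercept_se, float(pval)


def estimate_rate_constants(
    kobs_by_conc: dict[float, tuple[float, float]],
    koff_by_conc: dict[float, tuple[float, float]],
    linear_range_max_nM: float = 200.0,
) -> RateConstants:
    """k_on, k_off and K_d from per-concentration rate estimates.

    ``kobs_by_conc`` maps concentration (nM) to (mean k_obs, s.e.m.);
    k_on is the slope of the error-weighted k_obs-versus-concentration
    line restricted to concentrations <= ``linear_range_max_nM`` (above
    which relaxation outruns the frame rate and k_obs saturates).
    ``koff_by_conc`` likewise; k_off is taken from the intercept of its
    regression since the slope should not differ from zero for a
    concentration-independent off-rate (its p-value is reported).
    K_d = k_off / k_on by construction.
    """
    sel = {c: v for c, v in kobs_by_conc.items() if c <= linear_range_max_nM}
    if len(sel) < 3:
        raise ValueError("need at least 3 concentrations in the linear range")
    c_nM = np.array(sorted(sel))
    kobs = np.array([sel[c][0] for c in c_nM])
    kobs_sem = np.array([sel[c][1] for c in c_nM])
    slope, intercept, slope_se, _, _ = _weighted_line(c_nM, kobs, kobs_sem)

    if len(koff_by_conc) >= 3:
        c2 = np.array(sorted(koff_by_conc))
        koff = np.array([koff_by_conc[c][0] for c in c2])
        koff_sem = np.array([koff_by_conc[c][1] for c in c2])
        kslope, kint, _, kint_se, pval = _weighted_line(c2, koff, koff_sem)
        koff_mean, koff_se = kint, kint_se
    elif koff_by_conc:
        vals = np.array([v[0] for v in koff_by_conc.values()])
        koff_mean = float(vals.mean())
        koff_se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        kslope, pval = np.nan, np.nan
    else:
        raise ValueError("no dissociation-rate data supplied")

    return RateConstants(
        k_on_per_M_s=float(slope * 1e9),      # per-nM slope -> per-M
        k_on_se=float(slope_se * 1e9),
        k_off_per_s=float(koff_mean),
        k_off_se=float(koff_se),
        kobs_intercept_per_s=float(intercept),
        koff_slope_per_nM_s=float(kslope),
        koff_slope_pvalue=float(pval),
    )


# ---------------------------------------------------------------------------
# Hill isotherm


def _hill_model(c, theta_max, kd, n):
    cn = np.power(c, n)
    return theta_max * cn / (np.power(kd, n) + cn)


def fit_hill(conc_nM, theta, subtract_baseline: bool = False,
             fix_n: float | None = None) -> HillFit:
    """Fit theta = theta_max c^n / (K_d^n + c^n) to steady-state signals.

    ``subtract_baseline`` removes the unbound onefold reference from
    fold-increase data before fitting.  Multi-start over 5 log-spaced
    K_d seeds spanning the concentration range; bounds n in [0.1, 10]
    and K_d in (0, 100 max(c)].  ``fix_n`` pins the Hill coefficient
    (n = 1 gives the two-parameter Langmuir isotherm).
    """
    c = np.asarray(conc_nM, dtype=float)
    y = np.asarray(theta, dtype=float)
    if subtract_baseline:
        y = y - 1.0
    if np.unique(c[c > 0]).size < 4:
        raise ValueError("need at least 4 positive concentrations")
    span = c[c > 0].max() / c[c > 0].min()
    if span < 10:
        raise ValueError("concentrations must span at least a 10-fold range")
    kd_seeds = np.geomspace(c[c > 0].min(), c[c > 0].max(), 5)
    best = None
    for kd0 in kd_seeds:
        try:
            if fix_n is None:
                popt, pcov = curve_fit(
                    _hill_model, c, y,
                    p0=[float(y.max()), float(kd0), 1.0],
                    bounds=([1e-12, 1e-12, 0.1], [np.inf, 100 * c.max(), 10.0]),
                    maxfev=20000,
                )
                pred = _hill_model(c, *popt)
            else:
                model = lambda cc, tmax, kd: _hill_model(cc, tmax, kd, fix_n)
                popt2, pcov2 = curve_fit(
                    model, c, y, p0=[float(y.max()), float(kd0)],
                    bounds=([1e-12, 1e-12], [np.inf, 100 * c.max()]),
                    maxfev=20000,
                )
                popt = [popt2[0], popt2[1], fix_n]
                pcov = np.full((3, 3), np.nan)
                pcov[:2, :2] = pcov2
                pred = model(c, *popt2)
        except RuntimeError:
            continue
        sse = float(np.sum((pred - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return HillFit(theta_max=np.nan, kd_nM=np.nan, n=np.nan, sse=np.inf,
                       converged=False)
    sse, popt, pcov = best
    return HillFit(theta_max=float(popt[0]), kd_nM=float(popt[1]),
                   n=float(popt[2]), sse=sse, cov=pcov)


# ---------------------------------------------------------------------------
# compaction changepoint fit


def _trim_floor_plateau(t, y, run: int = 5, n_sigma: float = 3.0):
    """Drop trailing frames where the length sits at its terminal floor.

    Compacted DNA piles up at the tether, so trajectories that run long
    enough flatten at a residual length; including that plateau would
    bias the linear-decline slope.  The floor is the minimum of a
    ``run``-frame running mean; frames after the first time the running
    mean comes within ``n_sigma`` noise s.d. of it are discarded
    (noise s.d. estimated from first differences).  If the minimum is
    only reached at the end, nothing is trimmed.
    """
    if y.size < 3 * run:
        return t, y
    smooth = np.convolve(y, np.ones(run) / run, mode="valid")
    noise = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2)
    floor = smooth.min()
    near = np.flatnonzero(smooth <= floor + n_sigma * max(noise, 1e-12))
    first = near[0] + run - 1  # trailing frame of that window
    if first >= y.size - run:
        return t, y
    keep = first + 1
    return t[:keep], y[:keep]


def estimate_lag_and_rate(traj: Trajectory, t0_s: float = 0.0,
                          trim_floor: bool = True) -> CompactionFit:
    """Two-segment changepoint fit of a length trajectory.

    Model: L(t) = L0 for t <= t0 + t_lag, then L0 - r (t - t0 - t_lag);
    continuous at the changepoint.  The changepoint is found by
    exhaustive search over frames (for each candidate the model is
    linear in (L0, r) and solved in closed form), minimizing SSE.  A
    best-fit slope <= 0 means the DNA never compacted (flat or rising
    length) and yields a no-compaction verdict.
    """
    mask = traj.time_s >= t0_s
    t = traj.time_s[mask] - t0_s
    y = traj.values[mask]
    if t.size < 30:
        raise ValueError("need at least 30 frames from t0 to fit compaction")
    if trim_floor:
        t, y = _trim_floor_plateau(t, y)
    n = t.size
    best = None
    for k in range(0, n - 2):
        tc = t[k]
        ramp = np.maximum(0.0, t - tc)
        # L(t) = L0 - r * ramp, linear in (L0, r)
        A = np.column_stack([np.ones(n), -ramp])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((A @ coef - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, tc, coef)
    sse, tc, (l0, r) = best
    if r <= 0:
        return CompactionFit(t_lag_s=np.nan, rate_um_s=0.0, l0_um=float(l0),
                             sse=sse, no_compaction=True)
    return CompactionFit(t_lag_s=float(tc), rate_um_s=float(r),
                         l0_um=float(l0), sse=sse)
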