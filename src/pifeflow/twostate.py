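"""Sequential two-site equilibrium binding model for HBsu-like proteins.

A long DNA is modelled as an infinite string of identical, independent
segments, each of which can bind zero, one, or two protein dimers with
stepwise dissociation constants ``K1`` (first dimer, high affinity) and
``K2`` (second dimer, low affinity).  Each bound state carries its own
fold change of integrated fluorescence intensity (``I1``, ``I2``) and of
DNA extension (``L1``, ``L2``) relative to the unbound state, whose fold
values are identically 1.  Observed DNA-level fold changes are the
occupancy-weighted averages over segments, so steady-state intensity and
length curves versus concentration constrain all six parameters jointly.

The physical picture: first-dimer binding bends (compacts) DNA while
brightening nearby dyes; second-dimer binding builds a nucleoprotein
filament that re-extends the DNA and brightens it further.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TwoStateParams",
    "OccupancyProbs",
    "TwoStateFitResult",
    "occupancy_probs",
    "predict_curves",
    "fit_twostate",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the sequential two-dimer segment model.

    K1, K2 are dissociation constants in nM; I1, I2 and L1, L2 are fold
    intensity and fold length of the singly and doubly bound segment
    states (the unbound state is the reference, fold 1).
    """

    K1: float
    K2: float
    I1: float
    I2: float
    L1: float
    L2: float

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("dissociation constants K1, K2 must be positive")
        if min(self.I1, self.I2, self.L1, self.L2) < 0:
            raise ValueError("fold intensities and lengths must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.K2, self.I1, self.I2, self.L1, self.L2])


@dataclass(frozen=True)
class OccupancyProbs:
    """Proportions of segments bound by 0, 1 or 2 dimers; p0+p1+p2 = 1."""

    p0: np.ndarray | float
    p1: np.ndarray | float
    p2: np.ndarray | float


def occupancy_probs(c, params: TwoStateParams) -> OccupancyProbs:
    """Equilibrium occupancy proportions at free concentration ``c`` (nM).

    Sequential binding gives statistical weights w0 = 1, w1 = c/K1,
    w2 = c^2/(K1*K2); probabilities are the normalized weights.  ``c``
    may be a scalar or array; entries must be nonnegative.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    w1 = c / params.K1
    w2 = c * c / (params.K1 * params.K2)
    z = 1.0 + w1 + w2
    probs = OccupancyProbs(p0=1.0 / z, p1=w1 / z, p2=w2 / z)
    return probs


def predict_curves(c_grid, params: TwoStateParams):
    """Fold-intensity and fold-length curves of the whole DNA.

    F_I(c) = p0 + p1*I1 + p2*I2 and F_L(c) = p0 + p1*L1 + p2*L2.
    Returns a pair of arrays matching the shape of ``c_grid``.
    """
    p = occupancy_probs(c_grid, params)
    fold_intensity = p.p0 + p.p1 * params.I1 + p.p2 * params.I2
    fold_length = p.p0 + p.p1 * params.L1 + p.p2 * params.L2
    return np.asarray(fold_intensity, float), np.asarray(fold_length, float)


DEFAULT_BOUNDS = {
    "K": (0.1, 1e5),  # nM
    "I": (0.5, 20.0),
    "L": (0.05, 2.0),
}


@dataclass
class TwoStateFitResult:
    params: TwoStateParams
    sse: float
    converged: bool
    n_starts: int
    start_sse: list[float] = field(default_factory=list)


def _residuals(theta, c, fi, fl, weight_length):
    # theta = [log10 K1, log10 K2, I1, I2, L1, L2]
    params = TwoStateParams(10.0 ** theta[0], 10.0 ** theta[1], *theta[2:])
    pred_i, pred_l = predict_curves(c, params)
    return np.concatenate([pred_i - fi, np.sqrt(weight_length) * (pred_l - fl)])


def fit_twostate(
    c_grid,
    intensity_data,
    length_data,
    bounds: dict | None = None,
    n_starts: int = 20,
    weight_length: float = 1.0,
    seed: int | None = None,
) -> TwoStateFitResult:
    """Joint bounded least-squares fit of the six segment-model parameters.

    Minimizes SSE_intensity + weight_length * SSE_length over
    (K1, K2, I1, I2, L1, L2), with K1 and K2 searched in log space.
    Multi-start: K seeds log-uniform inside the bounds, fold seeds near 1;
    the start with the lowest SSE wins.  Requires at least 6 distinct
    concentrations (6 free parameters).
    """
    c = np.asarray(c_grid, dtype=float)
    fi = np.asarray(intensity_data, dtype=float)
    fl = np.asarray(length_data, dtype=float)
    if not (c.shape == fi.shape == fl.shape):
        raise ValueError("concentration, intensity and length arrays must align")
    if np.unique(c).size < 6:
        raise ValueError("need at least 6 distinct concentrations for 6 parameters")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([np.log10(b["K"][0]), np.log10(b["K"][0]),
                   b["I"][0], b["I"][0], b["L"][0], b["L"][0]])
    hi = np.array([np.log10(b["K"][1]), np.log10(b["K"][1]),
                   b["I"][1], b["I"][1], b["L"][1], b["L"][1]])

    rng = np.random.default_rng(seed)
    cpos = c[c > 0]
    lg_lo = np.log10(max(cpos.min(), b["K"][0])) if cpos.size else lo[0]
    lg_hi = np.log10(min(cpos.max(), b["K"][1])) if cpos.size else hi[0]

    best = None
    start_sse: list[float] = []
    for k in range(n_starts):
        if k == 0:
            # deterministic start: K spread over the data range, folds at data
            k1_0, k2_0 = 10 ** (lg_lo + 0.25 * (lg_hi - lg_lo)), 10 ** (lg_lo + 0.75 * (lg_hi - lg_lo))
            theta0 = np.array([np.log10(k1_0), np.log10(k2_0),
                               np.clip(fi.max(), *b["I"]), np.clip(fi.max(), *b["I"]),
                               np.clip(fl.min(), *b["L"]), np.clip(fl[-1], *b["L"])])
        else:
            theta0 = np.array([
                rng.uniform(lg_lo, lg_hi),
                rng.uniform(lg_lo, lg_hi),
                rng.uniform(*b["I"]),
                rng.uniform(*b["I"]),
                rng.uniform(*b["L"]),
                rng.uniform(*b["L"]),
            ])
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = least_squares(
                _residuals, theta0, args=(c, fi, fl, weight_length),
                bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer hard failure
            continue
        sse = float(np.sum(res.fun ** 2))
        start_sse.append(sse)
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        return TwoStateFitResult(
            params=TwoStateParams(1, 1, 1, 1, 1, 1), sse=np.inf,
            converged=False, n_starts=n_starts, start_sse=start_sse,
        )
    sse, theta = best
    params = TwoStateParams(10.0 ** theta[0], 10.0 ** theta[1], *theta[2:])
    return TwoStateFitResult(params=params, sse=sse, converged=True,
                             n_starts=n_starts, start_sse=start_sse)
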