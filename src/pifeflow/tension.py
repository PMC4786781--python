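"""Tension along flow-stretched DNA from sparse fiducial (QD) tracks.

Under buffer flow, hydrodynamic drag accumulates along a tethered DNA, so
tension decreases from the tether point toward the free end.  With
point labels (quantum dots) at known sequence positions, the *differential
extension* of each inter-label segment,

    xi_i = (<z_i> - <z_{i-1}>) / (s_i - s_{i-1}),

compares the observed distance between adjacent labels to the contour
length between them (s_i = L * N_i / N_total for the i-th site at
sequence position N_i).  Each xi maps to a segment tension through the
worm-like-chain (WLC) force-extension relation, here the Marko-Siggia
interpolation formula

    F(x) = (kBT / P) * [ 1/(4 (1-x)^2) - 1/4 + x ],

with persistence length P (default 50 nm) and thermal energy kBT
(default 4.114 pN nm, 25 C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "WLCModel",
    "MotionCaptureGeometry",
    "TensionProfile",
    "wlc_force",
    "invert_wlc",
    "differential_extension",
    "tensions_from_extension",
]

#: default EcoRI-site positions (bp from tether) on XbaI-digested lambda DNA
LAMBDA_XBA_SITES_BP = (3530, 9334, 16755, 22398)
LAMBDA_XBA_TOTAL_BP = 23994
BP_TO_UM = 0.34e-3  # contour length per basepair, 0.34 nm/bp

XI_CLIP = 1.0 - 1e-6


@dataclass(frozen=True)
class WLCModel:
    """Worm-like-chain elasticity: persistence length P (nm), kBT (pN nm)."""

    persistence_length_nm: float = 50.0
    kBT_pN_nm: float = 4.114

    def __post_init__(self) -> None:
        if self.persistence_length_nm <= 0 or self.kBT_pN_nm <= 0:
            raise ValueError("persistence length and kBT must be positive")


@dataclass(frozen=True)
class MotionCaptureGeometry:
    """Positions of labelled sites along the contour of a tethered DNA.

    ``sites_bp`` are sequence positions from the tether (strictly
    increasing); ``total_bp`` the full construct length.  ``contour_um``
    defaults to total_bp * 0.34 nm/bp.
    """

    sites_bp: tuple[int, ...] = LAMBDA_XBA_SITES_BP
    total_bp: int = LAMBDA_XBA_TOTAL_BP
    contour_um: float | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.sites_bp, float)
        if not (np.all(np.diff(s) > 0) and s[0] > 0 and s[-1] <= self.total_bp):
            raise ValueError("sites must be strictly increasing within (0, total_bp]")

    @property
    def contour_length_um(self) -> float:
        if self.contour_um is not None:
            return self.contour_um
        return self.total_bp * BP_TO_UM

    @property
    def s_um(self) -> np.ndarray:
        """Contour positions s_i = L * N_i / N_total of the labelled sites (um)."""
        return self.contour_length_um * np.asarray(self.sites_bp, float) / self.total_bp

    @property
    def segment_lengths_um(self) -> np.ndarray:
        """Contour length of each segment (tether->site1, site1->site2, ...)."""
        return np.diff(np.concatenate([[0.0], self.s_um]))


@dataclass
class TensionProfile:
    """Per-segment differential extension and WLC tension estimates."""

    xi: np.ndarray                  # clipped into [0, 1)
    xi_raw: np.ndarray              # as measured, may be <0 or >=1
    force_pN: np.ndarray
    clipped: np.ndarray             # bool flags per segment
    mean_positions_um: np.ndarray | None = None
    model: WLCModel = field(default_factory=WLCModel)


def wlc_force(x, model: WLCModel = WLCModel()):
    """Marko-Siggia force (pN) at fractional extension ``x`` in [0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("fractional extension must lie in [0, 1)")
    f = (model.kBT_pN_nm / model.persistence_length_nm) * (
        1.0 / (4.0 * (1.0 - x) ** 2) - 0.25 + x
    )
    return f if f.ndim else float(f)


def invert_wlc(force_pN, model: WLCModel = WLCModel(), tol: float = 1e-12):
    """Fractional extension at force ``force_pN`` (> 0), by bisection.

    wlc_force is strictly increasing on [0, 1), so the root is unique.
    """
    forces = np.atleast_1d(np.asarray(force_pN, dtype=float))
    if np.any(forces <= 0):
        raise ValueError("force must be positive")
    out = np.empty_like(forces)
    for i, f in enumerate(forces):
        out[i] = brentq(lambda x: wlc_force(x, model) - f, 0.0, 1.0 - 1e-9,
                        xtol=tol)
    return out if np.ndim(force_pN) else float(out[0])


def differential_extension(positions_um, geom: MotionCaptureGeometry):
    """Per-segment differential extension from a [T x n_sites] track.

    Positions are distances of each labelled site from the tether point,
    time-averaged before differencing; z_0 = s_0 = 0 at the tether.
    Returns (xi_clipped, xi_raw, clipped_flags).  Raw values outside
    [0, 1) (tether-point error, localization noise) are preserved and
    flagged; the clipped copy is safe to feed to the WLC map.
    """
    z = np.asarray(positions_um, dtype=float)
    if z.ndim != 2:
        raise ValueError("track must be a [T x n_sites] array")
    if z.shape[0] < 10:
        raise ValueError("need at least 10 frames to average positions")
    s = geom.s_um
    if z.shape[1] != s.size:
        raise ValueError("track has %d sites, geometry %d" % (z.shape[1], s.size))
    zbar = z.mean(axis=0)
    dz = np.diff(np.concatenate([[0.0], zbar]))
    ds = geom.segment_lengths_um
    xi_raw = dz / ds
    xi = np.clip(xi_raw, 0.0, XI_CLIP)
    clipped = (xi_raw < 0.0) | (xi_raw > XI_CLIP)
    return xi, xi_raw, clipped


def tensions_from_extension(xi, model: WLCModel = WLCModel(),
                            xi_raw=None, clipped=None,
                            mean_positions_um=None) -> TensionProfile:
    """Map per-segment differential extensions to WLC tensions (pN)."""
    xi = np.asarray(xi, dtype=float)
    if np.any((xi < 0) | (xi >= 1)):
        raise ValueError("xi must lie in [0, 1); clip before calling")
    force = wlc_force(xi, model)
    if xi_raw is None:
        xi_raw = xi.copy()
    if clipped is None:
        clipped = np.zeros(xi.shape, dtype=bool)
    return TensionProfile(
        xi=xi, xi_raw=np.asarray(xi_raw, float), force_pN=np.atleast_1d(force),
        clipped=np.asarray(clipped, bool), mean_positions_um=mean_positions_um,
        model=model,
    )
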