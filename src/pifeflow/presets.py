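"""Simulation presets: named parameter bundles for the synthetic generators.

Each preset encodes one experimental condition of the flow-stretched
PIFE assay — dye density, imaging rate, binding rate constants, PIFE
brightness enhancement, compaction statistics, photobleaching — so that
every generated dataset is fully described by (preset, seed).

Built-in presets:

``spo0j_wt``
    Wild-type Spo0J (ParB): binds with the same kinetics as the R82A
    mutant but bridges and compacts DNA; compaction onset lag and rate
    are Gaussian across molecules (means 3.3 s and 0.51 um/s).
``r82a``
    Bridging-deficient Spo0J R82A: 1:1 Langmuir binding with
    k_on = 2.1e6 /M/s and k_off = 0.16 /s (K_d = 76.2 nM); no
    compaction.  Also carries the apparent Hill parameters of its
    steady-state fold-intensity isotherm (K_d 60.5 nM, n 0.8).
``hbsu``
    HBsu nucleoid protein: sequential two-dimer segment model with
    K1 = 13 nM (bending, compacting) and K2 = 390 nM (filament,
    re-extending).
``qd``
    DNA motion capture: QD labels on XbaI-digested lambda DNA with a
    tether-to-free-end tension profile of roughly 1 -> 0.1 pN at
    100 ul/min flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .twostate import TwoStateParams

__all__ = ["SimPreset", "get_preset", "builtin_presets", "load_preset", "save_preset"]


@dataclass(frozen=True)
class SimPreset:
    """Parameters defining one synthetic experimental condition.

    Rates and concentrations are nonnegative; ``pife_factor`` is the
    fold brightness of a dye adjacent to a bound protein (>= 1);
    ``t_half_bleach_s`` the photobleaching half-life per dye.
    """

    name: str
    concentration_nM: float = 100.0
    k_on_per_M_s: float = 2.1e6
    k_off_per_s: float = 0.16
    pife_factor: float = 4.5
    lag_mean_s: float = 3.3
    lag_sd_s: float = 0.7
    rate_mean_um_s: float = 0.51
    rate_sd_um_s: float = 0.14
    twostate: TwoStateParams | None = None
    t_half_bleach_s: float = 300.0
    frame_rate_hz: float = 10.0
    n_dyes_per_kb: float = 1.0
    dna_length_bp: int = 20_000
    pixel_size_um: float = 0.167
    dye_brightness: float = 100.0     # mean counts/frame of one unenhanced dye
    noise_sd: float = 60.0            # additive camera noise on integrated counts
    l0_um: float = 6.0                # flow-stretched extension of the 20 kb DNA
    l_floor_um: float = 0.5           # residual length when compacted to tether
    length_noise_sd_um: float = 0.05
    # apparent Hill parameters of the steady-state fold-intensity isotherm
    hill_kd_nM: float | None = None
    hill_n: float | None = None
    hill_theta_max: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.concentration_nM, self.k_on_per_M_s, self.k_off_per_s,
               self.lag_mean_s, self.lag_sd_s, self.rate_mean_um_s,
               self.rate_sd_um_s, self.dna_length_bp, self.noise_sd) < 0:
            raise ValueError("rates, lengths and concentrations must be >= 0")
        if self.pife_factor < 1:
            raise ValueError("pife_factor must be >= 1")
        if self.frame_rate_hz <= 0 or self.t_half_bleach_s <= 0:
            raise ValueError("frame_rate and bleach half-life must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def n_sites(self) -> int:
        """One binding site per dye, one dye per kb on average."""
        return max(1, round(self.dna_length_bp / 1000 * self.n_dyes_per_kb))

    @property
    def kd_nM(self) -> float:
        return self.k_off_per_s / self.k_on_per_M_s * 1e9

    def replace(self, **kw) -> "SimPreset":
        from dataclasses import replace
        return replace(self, **kw)


def builtin_presets() -> dict[str, SimPreset]:
    return {
        "spo0j_wt": SimPreset(
            name="spo0j_wt", concentration_nM=100.0, pife_factor=5.0,
            lag_mean_s=3.3, lag_sd_s=0.7, rate_mean_um_s=0.51, rate_sd_um_s=0.14,
        ),
        "r82a": SimPreset(
            name="r82a", concentration_nM=100.0,
            k_on_per_M_s=2.1e6, k_off_per_s=0.16, pife_factor=4.5,
            hill_kd_nM=60.5, hill_n=0.8, hill_theta_max=2.0,
        ),
        "hbsu": SimPreset(
            name="hbsu", concentration_nM=1000.0, pife_factor=4.0,
            twostate=TwoStateParams(K1=13.0, K2=390.0, I1=2.0, I2=4.0,
                                    L1=0.4, L2=0.95),
        ),
        "qd": SimPreset(
            name="qd", concentration_nM=0.0, pife_factor=1.0,
            dna_length_bp=23_994,
        ),
    }


def get_preset(name: str) -> SimPreset:
    presets = builtin_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]


def save_preset(preset: SimPreset, path: str | Path) -> None:
    d = asdict(preset)
    if preset.twostate is not None:
        d["twostate"] = asdict(preset.twostate)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_preset(path: str | Path) -> SimPreset:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("twostate") is not None:
        d["twostate"] = TwoStateParams(**d["twostate"])
    return SimPreset(**d)
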