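"""Shared in-memory containers for stacks, trajectories and tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImageStack",
    "ROI",
    "Kymograph",
    "Trajectory",
    "QDTrack",
    "OccupancyMatrix",
]


@dataclass
class ImageStack:
    """A T x H x W grayscale movie with frame interval (s) and pixel size (um)."""

    pixels: np.ndarray
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a T x H x W array")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest; 0-based half-open pixel ranges.

    The tether column is where the DNA is anchored; flow (and the free
    end) runs toward increasing column index.
    """

    row0: int
    row1: int
    col0: int
    col1: int
    tether_col: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError("ROI ranges must be non-empty half-open intervals")
        if not (self.col0 <= self.tether_col < self.col1):
            raise ValueError("tether column must lie inside the ROI column range")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    def validate_for(self, stack: ImageStack) -> None:
        _, h, w = stack.shape
        if self.row0 < 0 or self.col0 < 0 or self.row1 > h or self.col1 > w:
            raise ValueError("ROI exceeds frame bounds")


@dataclass
class Kymograph:
    """Time x position image: 1-D flow-axis projections of an ROI per frame."""

    values: np.ndarray  # [T, X], background-subtracted
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kymograph must be a T x X array")


@dataclass
class Trajectory:
    """Per-DNA time series (integrated intensity in counts, or length in um)."""

    time_s: np.ndarray
    values: np.ndarray
    kind: str  # "intensity" | "length"
    dna_id: str = "dna0"
    concentration_nM: float = float("nan")
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.shape != self.values.shape:
            raise ValueError("time and value arrays must have the same shape")
        if self.kind not in ("intensity", "length", "fold"):
            raise ValueError("kind must be 'intensity', 'length' or 'fold'")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_s))) if self.time_s.size > 1 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        value_col = {"intensity": "intensity_counts",
                     "length": "length_um",
                     "fold": "fold"}[self.kind]
        return pd.DataFrame({
            "time_s": self.time_s,
            value_col: self.values,
            "dna_id": self.dna_id,
            "concentration_nM": self.concentration_nM,
        })


@dataclass
class QDTrack:
    """Sub-pixel positions (um from the tether) of labelled sites over time."""

    positions_um: np.ndarray  # [T, n_sites]
    localization_sd_um: float = 0.0
    frame_interval_s: float = 0.1

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.positions_um.ndim != 2:
            raise ValueError("positions must be a T x n_sites array")


@dataclass
class OccupancyMatrix:
    """Binary site-occupancy history [T x n_sites] with frame spacing dt (s)."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")

    @property
    def fraction(self) -> np.ndarray:
        """Per-frame occupied fraction across sites."""
        return self.values.mean(axis=1)
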