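"""File formats: multi-page TIFF stacks, trajectory/track CSVs, YAML sidecars.

All tables carry units in their column headers (time_s, length_um,
conc_nM, ...) so files are self-describing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import ImageStack, ROI, QDTrack, Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_trajectories",
    "read_trajectories",
    "write_qd_track",
    "read_qd_track",
    "read_rois",
    "write_rois",
]

_DEFAULT_FRAME_INTERVAL_S = 0.1
_DEFAULT_PIXEL_SIZE_UM = 0.167


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page 16-bit grayscale TIFF plus YAML sidecar."""
    path = Path(path)
    pixels = stack.pixels
    if pixels.dtype != np.uint16:
        pixels = np.clip(pixels, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pixels, photometric="minisblack")
    _sidecar(path).write_text(yaml.safe_dump({
        "frame_interval_s": stack.frame_interval_s,
        "pixel_size_um": stack.pixel_size_um,
    }))
    return path


def read_image_stack(path: str | Path,
                     frame_interval_s: float | None = None,
                     pixel_size_um: float | None = None) -> ImageStack:
    """Read a grayscale multi-page TIFF; metadata from sidecar YAML.

    Explicit keyword metadata overrides the sidecar; if neither is
    available, defaults (10 Hz, 0.167 um) are used with a warning.
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise ValueError(f"{path} is not a grayscale multi-page TIFF "
                         f"(got shape {pixels.shape})")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    fi = frame_interval_s or meta.get("frame_interval_s")
    ps = pixel_size_um or meta.get("pixel_size_um")
    if fi is None or ps is None:
        log.warning("no metadata for %s; using defaults 10 Hz, 0.167 um/px", path)
        fi = fi or _DEFAULT_FRAME_INTERVAL_S
        ps = ps or _DEFAULT_PIXEL_SIZE_UM
    return ImageStack(pixels=pixels, frame_interval_s=float(fi),
                      pixel_size_um=float(ps))


def write_trajectories(trajs: list[Trajectory], path: str | Path) -> Path:
    path = Path(path)
    frames = [t.to_frame() for t in trajs]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12g")
    return path


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    value_col = next(c for c in ("intensity_counts", "length_um", "fold")
                     if c in df.columns)
    kind = {"intensity_counts": "intensity", "length_um": "length",
            "fold": "fold"}[value_col]
    out = []
    for dna_id, g in df.groupby("dna_id", sort=False):
        out.append(Trajectory(
            time_s=g["time_s"].to_numpy(), values=g[value_col].to_numpy(),
            kind=kind, dna_id=str(dna_id),
            concentration_nM=float(g["concentration_nM"].iloc[0]),
        ))
    return out


def write_qd_track(track: QDTrack, path: str | Path) -> Path:
    path = Path(path)
    T, n = track.positions_um.shape
    rows = {
        "frame": np.repeat(np.arange(T), n),
        "site_index": np.tile(np.arange(n), T),
        "z_um": track.positions_um.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    return path


def read_qd_track(path: str | Path, frame_interval_s: float = 0.1) -> QDTrack:
    df = pd.read_csv(path)
    wide = df.pivot(index="frame", columns="site_index", values="z_um")
    return QDTrack(positions_um=wide.to_numpy(),
                   frame_interval_s=frame_interval_s)


def read_rois(path: str | Path) -> dict[str, ROI]:
    """ROI list CSV with columns dna_id, row0, row1, col0, col1, tether_col."""
    df = pd.read_csv(path)
    return {
        str(r.dna_id): ROI(int(r.row0), int(r.row1), int(r.col0), int(r.col1),
                           int(r.tether_col))
        for r in df.itertuples()
    }


def write_rois(rois: dict[str, ROI], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([
        {"dna_id": k, "row0": v.row0, "row1": v.row1, "col0": v.col0,
         "col1": v.col1, "tether_col": v.tether_col}
        for k, v in rois.items()
    ]).to_csv(path, index=False)
    return path
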