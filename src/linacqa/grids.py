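"""Voxelized dose grids and 1D scan containers, with their file formats.

A DoseGrid is a rectilinear water-phantom dose distribution: per-voxel dose
plus per-voxel relative statistical uncertainty, with the position of the
center of voxel (0,0,0) and the voxel pitch given explicitly.  Depth z is
measured from the phantom surface at SSD 100 cm; x is crossline, y inline.

On disk a grid is three files sharing a base name: a plain-text sidecar
``<base>.grid`` (origin, voxel sizes, counts) and two little-endian float32
rasters ``<base>.dose.f32`` / ``<base>.unc.f32`` in x-fastest order.

ProfilePoints hold an ordered scan (depth dose or lateral profile) as
(position, dose) samples; sets of scans round-trip through a single CSV with
columns scan_type, field_cm, depth_cm, position_cm, dose_rel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["DoseGrid", "ProfilePoints", "write_dose_grid", "read_dose_grid",
           "write_profiles_csv", "read_profiles_csv"]


@dataclass
class DoseGrid:
    """3D dose + relative uncertainty on a rectilinear grid.

    dose and rel_unc are (nx, ny, nz) arrays; origin is the position (cm) of
    the CENTER of voxel (0, 0, 0); voxel the pitch (dx, dy, dz) in cm.
    """

    origin: Tuple[float, float, float]
    voxel: Tuple[float, float, float]
    dose: np.ndarray
    rel_unc: Optional[np.ndarray] = None

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 3:
            raise ValueError("dose must be a 3D array")
        if any(d <= 0 for d in self.voxel):
            raise ValueError("voxel sizes must be positive")
        if (self.dose < 0).any():
            raise ValueError("dose must be non-negative")
        if self.rel_unc is not None:
            self.rel_unc = np.asarray(self.rel_unc, dtype=float)
            if self.rel_unc.shape != self.dose.shape:
                raise ValueError("rel_unc shape must match dose shape")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.dose.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.dose.shape[axis]
        return self.origin[axis] + self.voxel[axis] * np.arange(n)


@dataclass
class ProfilePoints:
    """An ordered scan of relative dose samples.

    axis: 'depth' (along the CAX), 'crossline' (x at fixed depth) or
    'inline' (y at fixed depth).  normalization records the scale: 'max'
    (curve maximum = 100), 'cax' (central-axis value = 100) or 'raw'.
    """

    axis: str
    positions: np.ndarray
    doses: np.ndarray
    field_cm: float
    depth_cm: Optional[float] = None
    normalization: str = "raw"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.axis not in ("depth", "crossline", "inline"):
            raise ValueError(f"unknown scan axis {self.axis!r}")
        if self.positions.shape != self.doses.shape or self.positions.ndim != 1:
            raise ValueError("positions and doses must be matching 1D arrays")
        if len(self.positions) and (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if (self.doses < 0).any():
            raise ValueError("doses must be non-negative")

    def __len__(self) -> int:
        return len(self.positions)


def write_dose_grid(grid: DoseGrid, base: str) -> None:
    """Write sidecar + float32 rasters (x-fastest order)."""
    with open(base + ".grid", "w") as fh:
        fh.write(f"ORIGIN_CM = {grid.origin[0]!r} {grid.origin[1]!r} {grid.origin[2]!r}\n")
        fh.write(f"VOXEL_CM = {grid.voxel[0]!r} {grid.voxel[1]!r} {grid.voxel[2]!r}\n")
        fh.write(f"DIMS = {grid.dims[0]} {grid.dims[1]} {grid.dims[2]}\n")
        fh.write(f"HAS_UNC = {int(grid.rel_unc is not None)}\n")
    grid.dose.astype("<f4").ravel(order="F").tofile(base + ".dose.f32")
    if grid.rel_unc is not None:
        grid.rel_unc.astype("<f4").ravel(order="F").tofile(base + ".unc.f32")


def read_dose_grid(base: str) -> DoseGrid:
    meta = {}
    with open(base + ".grid") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    origin = tuple(float(t) for t in meta["ORIGIN_CM"].split())
    voxel = tuple(float(t) for t in meta["VOXEL_CM"].split())
    dims = tuple(int(t) for t in meta["DIMS"].split())
    n = dims[0] * dims[1] * dims[2]
    dose = np.fromfile(base + ".dose.f32", dtype="<f4", count=n)
    dose = dose.reshape(dims, order="F").astype(float)
    rel_unc = None
    if int(meta.get("HAS_UNC", "0")):
        rel_unc = np.fromfile(base + ".unc.f32", dtype="<f4", count=n)
        rel_unc = rel_unc.reshape(dims, order="F").astype(float)
    return DoseGrid(origin=origin, voxel=voxel, dose=dose, rel_unc=rel_unc)


def write_profiles_csv(profiles: Sequence[ProfilePoints], path: str) -> None:
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "scan_type": p.axis,
            "field_cm": p.field_cm,
            "depth_cm": np.nan if p.depth_cm is None else p.depth_cm,
            "position_cm": p.positions,
            "dose_rel": p.doses,
            "normalization": p.normalization,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path: str) -> List[ProfilePoints]:
    df = pd.read_csv(path)
    out = []
    keys = ["scan_type", "field_cm", "depth_cm"]
    for (axis, field_cm, depth_cm), grp in df.groupby(keys, dropna=False, sort=False):
        grp = grp.sort_values("position_cm")
        norm = grp["normalization"].iloc[0] if "normalization" in grp else "raw"
        out.append(ProfilePoints(
            axis=axis,
            positions=grp["position_cm"].to_numpy(),
            doses=grp["dose_rel"].to_numpy(),
            field_cm=float(field_cm),
            depth_cm=None if pd.isna(depth_cm) else float(depth_cm),
            normalization=norm,
        ))
    return out
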