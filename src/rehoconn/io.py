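"""Reading and writing the volume formats the pipeline touches.

All spatial data move through two small containers: :class:`VolumeGrid`
(dimensions, voxel size and a RAS+ affine) and :class:`BoldSeries` (a 4D
time-series volume plus its brain mask).  Voxel indices are 0-based
everywhere inside the package; any coordinate that leaves the package
(cluster tables, logs) is in millimetres via the grid affine, which removes
the usual 0/1-based ambiguity from reports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "BoldSeries",
    "load_series",
    "save_map",
    "read_motion_params",
    "write_cluster_table",
    "CLUSTER_TABLE_COLUMNS",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel grid geometry: dimensions, voxel size and voxel->mm affine (RAS+)."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d <= 0 for d in self.dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", affine)

    @classmethod
    def centered(cls, dims: tuple[int, int, int],
                 voxel_size_mm: float | tuple[float, float, float]) -> "VolumeGrid":
        """Synthetic RAS+ grid with the mm origin at the grid centre.

        Gives reproducible MNI-like coordinates for simulated data without
        any registration step.
        """
        if np.isscalar(voxel_size_mm):
            vs = (float(voxel_size_mm),) * 3
        else:
            vs = tuple(float(v) for v in voxel_size_mm)
        affine = np.eye(4)
        for ax in range(3):
            affine[ax, ax] = vs[ax]
            affine[ax, 3] = -vs[ax] * (dims[ax] - 1) / 2.0
        return cls(tuple(int(d) for d in dims), vs, affine)

    @classmethod
    def from_affine(cls, dims: tuple[int, int, int], affine: np.ndarray) -> "VolumeGrid":
        affine = np.asarray(affine, dtype=float)
        vs = tuple(float(v) for v in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
        return cls(tuple(int(d) for d in dims), vs, affine)

    def voxel_to_mm(self, idx) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        hom = np.hstack([idx, np.ones((idx.shape[0], 1))])
        mm = hom @ self.affine.T
        return np.squeeze(mm[:, :3])

    def mm_to_voxel(self, mm) -> np.ndarray:
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        hom = np.hstack([mm, np.ones((mm.shape[0], 1))])
        vox = hom @ np.linalg.inv(self.affine).T
        return np.squeeze(vox[:, :3])


@dataclass
class BoldSeries:
    """One subject's 4D BOLD run with grid geometry, TR and brain mask."""

    grid: VolumeGrid
    tr_s: float
    data: np.ndarray  # (x, y, z, t)
    mask: np.ndarray  # (x, y, z) boolean

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"series data must be 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != tuple(self.grid.dims):
            raise ValueError("series spatial shape does not match grid dims")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match series "
                f"spatial shape {self.data.shape[:3]}")
        if self.data.shape[3] < 2:
            raise ValueError("series needs at least 2 volumes")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite values inside the brain mask")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return dataclasses.replace(self, data=data)


def load_series(path, mask_path, tr_s: float | None = None) -> BoldSeries:
    """Load a 4D NIfTI series plus its 3D mask.

    The TR is taken from the NIfTI header (4th zoom) unless ``tr_s`` is
    given explicitly.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {img.ndim}D")
    mask_img = nib.load(str(mask_path))
    if mask_img.ndim != 3:
        raise ValueError(f"{mask_path}: mask must be 3D, got {mask_img.ndim}D")
    if tuple(mask_img.shape) != tuple(img.shape[:3]):
        raise ValueError(
            f"mask shape {tuple(mask_img.shape)} does not match series "
            f"spatial shape {tuple(img.shape[:3])}")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
        if tr_s <= 0:
            raise ValueError(f"{path}: TR missing from header; pass tr_s")
    grid = VolumeGrid.from_affine(tuple(img.shape[:3]), img.affine)
    data = np.asarray(img.get_fdata(), dtype=float)
    mask = np.asarray(mask_img.get_fdata()) > 0.5
    return BoldSeries(grid=grid, tr_s=tr_s, data=data, mask=mask)


def save_series(series: BoldSeries, path) -> Path:
    """Write a BoldSeries to NIfTI-1 with the TR recorded in the header."""
    img = nib.Nifti1Image(series.data.astype(np.float32), series.grid.affine)
    zooms = list(series.grid.voxel_size_mm) + [series.tr_s]
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return Path(path)


def save_map(field3d: np.ndarray, grid: VolumeGrid, path) -> Path:
    """Write a 3D field to NIfTI-1 using the grid's affine.

    NaNs (the conventional out-of-mask fill) are stored as-is in float32.
    """
    field3d = np.asarray(field3d)
    if field3d.shape != tuple(grid.dims):
        raise ValueError(f"field shape {field3d.shape} does not match grid {grid.dims}")
    img = nib.Nifti1Image(field3d.astype(np.float32), grid.affine)
    nib.save(img, str(path))
    return Path(path)


def read_motion_params(path) -> np.ndarray:
    """Read a rigid-motion parameter file: one row per volume, 6 columns
    (x/y/z translation in mm then x/y/z rotation in degrees)."""
    table = np.loadtxt(str(path), ndmin=2)
    if table.shape[1] != 6:
        raise ValueError(
            f"{path}: motion file must have 6 columns, got {table.shape[1]}")
    return table


CLUSTER_TABLE_COLUMNS = ["region_id", "x_mm", "y_mm", "z_mm", "peak_t", "n_voxels"]


def write_cluster_table(clusters, path) -> Path:
    """Write a cluster table as TSV: peak coordinate (mm), peak t, extent.

    ``clusters`` is a sequence of :class:`rehoconn.inference.Cluster`.
    An empty sequence yields a header-only file.
    """
    rows = []
    for c in clusters:
        rows.append({
            "region_id": c.cluster_id,
            "x_mm": c.peak_mm[0],
            "y_mm": c.peak_mm[1],
            "z_mm": c.peak_mm[2],
            "peak_t": c.peak_t,
            "n_voxels": c.n_voxels,
        })
    df = pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)
    df.to_csv(str(path), sep="\t", index=False, float_format="%.4f")
    return Path(path)
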