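"""Seed-based interregional synchrony.

A seed region of interest (ROI) — here typically a cluster of elevated
regional homogeneity — is summarised by its unweighted mean time course;
every in-mask voxel's series is then correlated (Pearson) with that
reference and the correlation map is variance-stabilised with the Fisher
z-transform, z = atanh(r).  Correlations are clamped at |r| = 1 - 1e-7
before the transform so that seed voxels (which correlate perfectly with a
single-voxel seed) do not inject infinities into group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BoldSeries

__all__ = ["SeedROI", "ConnectivityMap", "roi_mean_timeseries",
           "seed_correlation_map", "fisher_z", "R_CLAMP"]

R_CLAMP = 1.0 - 1e-7


@dataclass
class SeedROI:
    """A seed region: a set of 0-based voxel indices inside the mask."""

    roi_id: str
    voxel_indices: np.ndarray  # (n_voxels, 3) integer array
    source: str = "manual"     # "reho_cluster" or "manual"
    label: str = ""

    def __post_init__(self) -> None:
        self.voxel_indices = np.atleast_2d(np.asarray(self.voxel_indices, dtype=int))
        if self.voxel_indices.size == 0:
            raise ValueError(f"ROI {self.roi_id} is empty")
        if self.voxel_indices.shape[1] != 3:
            raise ValueError("voxel_indices must be (n, 3)")


@dataclass
class ConnectivityMap:
    """Per-subject seed-correlation field and its Fisher-z counterpart."""

    subject_id: str
    roi_id: str
    r_values: np.ndarray
    z_values: np.ndarray
    mask: np.ndarray = field(repr=False, default=None)


def fisher_z(r):
    """Fisher z-transform z = atanh(r) = 0.5*ln((1+r)/(1-r)), clamped.

    Accepts scalars or arrays with |r| <= 1; |r| is clamped at 1 - 1e-7 so
    perfect correlations map to a large finite z.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr[np.isfinite(r_arr)]) > 1 + 1e-12):
        raise ValueError("|r| must not exceed 1")
    clipped = np.clip(r_arr, -R_CLAMP, R_CLAMP)
    z = np.arctanh(clipped)
    return float(z) if np.isscalar(r) else z


def roi_mean_timeseries(series: BoldSeries, roi: SeedROI) -> np.ndarray:
    """Unweighted mean of the ROI voxels' series at each time point."""
    idx = roi.voxel_indices
    in_mask = series.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not in_mask.all():
        raise ValueError(f"ROI {roi.roi_id} has voxels outside the mask")
    return series.data[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)


def seed_correlation_map(series: BoldSeries, roi: SeedROI) -> ConnectivityMap:
    """Pearson correlation of every in-mask voxel with the ROI mean course.

    Voxels with a constant series get NaN; a constant reference raises.
    Seed voxels are retained in the map.
    """
    ref = roi_mean_timeseries(series, roi)
    ref_c = ref - ref.mean()
    ref_norm = np.sqrt((ref_c ** 2).sum())
    if ref_norm == 0:
        raise ValueError(f"ROI {roi.roi_id} reference series has zero variance")

    Y = series.data[series.mask]            # (V, T)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((Yc ** 2).sum(axis=1))
    constant = (Y.max(axis=1) - Y.min(axis=1)) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r_in = (Yc @ ref_c) / (ynorm * ref_norm)
    r_in[constant | (ynorm == 0)] = np.nan
    r_in = np.clip(r_in, -1.0, 1.0)

    r = np.full(series.mask.shape, np.nan)
    r[series.mask] = r_in
    z = np.full(series.mask.shape, np.nan)
    z[series.mask] = fisher_z(r_in)
    return ConnectivityMap(subject_id="", roi_id=roi.roi_id,
                           r_values=r, z_values=z, mask=series.mask)
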