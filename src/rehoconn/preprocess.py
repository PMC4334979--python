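"""Temporal and spatial conditioning of BOLD series.

The stages mirror a standard resting-state stream: drop dummy volumes,
screen subjects on head motion, remove a per-voxel linear trend, band-pass
to the low-frequency BOLD band (0.01-0.08 Hz by default), smooth spatially,
and regress out nuisance time courses (6 motion parameters plus global /
white-matter / CSF means).

The band-pass is an ideal discrete-Fourier filter: frequency bins with
``low <= f <= high`` are kept, everything else (including DC) is zeroed.
This makes the filter an exact projection (idempotent), matches the
behaviour of the classic resting-state toolboxes, and needs no filter
design parameters.

The temporal operations (detrend, band-pass, nuisance regression) apply
to in-mask voxels; values outside the brain mask pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BoldSeries, VolumeGrid

__all__ = [
    "PreprocessConfig",
    "discard_initial_volumes",
    "motion_screen",
    "linear_detrend",
    "bandpass_filter",
    "spatial_smooth",
    "regress_nuisance",
    "fwhm_to_sigma",
]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / _FWHM_PER_SIGMA


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing settings with the defaults used throughout the package.

    ``n_discard`` dummy volumes are dropped to let magnetisation reach
    steady state; the motion limits implement the per-axis exclusion rule
    (any |translation| > 2 mm or |rotation| > 2 degrees excludes a subject,
    strictly "more than").
    """

    n_discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    smooth_fwhm_mm: float = 4.0
    motion_limit_mm: float = 2.0
    motion_limit_deg: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 < band_low < band_high")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be nonnegative")
        if self.n_discard < 0:
            raise ValueError("n_discard must be nonnegative")


def discard_initial_volumes(series: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` volumes (scanner equilibration dummies)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n} of {series.n_volumes} volumes")
    if n == 0:
        return series
    return series.with_data(series.data[..., n:])


def motion_screen(motion_table: np.ndarray,
                  limit_mm: float = 2.0,
                  limit_deg: float = 2.0) -> dict:
    """Per-axis motion screening.

    Returns ``{"included": bool, "max_abs": 6-vector}`` where ``included``
    is False iff any |translation| exceeds ``limit_mm`` or any |rotation|
    exceeds ``limit_deg`` (strict inequality: a maximum exactly at the
    limit is kept).
    """
    table = np.asarray(motion_table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 6:
        raise ValueError("motion table must be (n_volumes, 6)")
    if table.shape[0] == 0:
        raise ValueError("motion table is empty")
    max_abs = np.abs(table).max(axis=0)
    included = bool(
        (max_abs[:3] <= limit_mm).all() and (max_abs[3:] <= limit_deg).all())
    return {"included": included, "max_abs": max_abs}


def _as_timeseries_matrix(series_or_array) -> tuple[np.ndarray, BoldSeries | None]:
    if isinstance(series_or_array, BoldSeries):
        return series_or_array.data, series_or_array
    return np.asarray(series_or_array, dtype=float), None


def linear_detrend(series: BoldSeries) -> BoldSeries:
    """Remove the least-squares line (intercept + slope) from every voxel."""
    n = series.n_volumes
    if n < 3:
        raise ValueError("need at least 3 volumes to detrend")
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t])
    # residual projector applied along the time axis, in-mask voxels only
    flat = series.data[series.mask]
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    out = series.data.copy()
    out[series.mask] = flat - (X @ beta).T
    return series.with_data(out)


def bandpass_filter(series: BoldSeries,
                    low_hz: float = 0.01,
                    high_hz: float = 0.08) -> BoldSeries:
    """Ideal DFT band-pass: keep bins with low <= f <= high, zero the rest.

    DC is always removed (the band excludes f = 0).  The operation is an
    exact projection in frequency space, so applying it twice equals
    applying it once.
    """
    n = series.n_volumes
    nyquist = 1.0 / (2.0 * series.tr_s)
    if not (0 < low_hz < high_hz <= nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie within (0, {nyquist}] Hz")
    freqs = np.fft.rfftfreq(n, d=series.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():
        raise ValueError("no frequency bin falls inside the band; series too short")
    spec = np.fft.rfft(series.data[series.mask], axis=-1)
    spec[..., ~keep] = 0.0
    out = series.data.copy()
    out[series.mask] = np.fft.irfft(spec, n=n, axis=-1)
    return series.with_data(out)


def spatial_smooth(field_or_series, fwhm_mm: float, grid: VolumeGrid):
    """Separable Gaussian smoothing of a 3D field or a 4D series.

    sigma per axis = fwhm / (2*sqrt(2 ln 2)) in mm, converted to voxels.
    ``fwhm_mm = 0`` is the identity.  NaNs (out-of-mask fill in maps) are
    treated as zeros and restored to NaN afterwards.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if isinstance(field_or_series, BoldSeries):
        if fwhm_mm == 0:
            return field_or_series
        series = field_or_series
        sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in grid.voxel_size_mm]
        out = ndimage.gaussian_filter(
            series.data, sigma=sigma_vox + [0.0], mode="constant")
        return series.with_data(out)
    field = np.asarray(field_or_series, dtype=float)
    if fwhm_mm == 0:
        return field.copy()
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in grid.voxel_size_mm]
    nan_mask = np.isnan(field)
    filled = np.where(nan_mask, 0.0, field)
    out = ndimage.gaussian_filter(filled, sigma=sigma_vox, mode="constant")
    out[nan_mask] = np.nan
    return out


def regress_nuisance(series: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Remove nuisance time courses by voxelwise least squares.

    ``regressors`` is (n_volumes, k); an intercept column is always added.
    Residuals are exactly orthogonal to every regressor.  Raises on a
    rank-deficient design.
    """
    R = np.asarray(regressors, dtype=float)
    if R.ndim != 2 or R.shape[0] != series.n_volumes:
        raise ValueError(
            f"regressors must be ({series.n_volumes}, k), got {R.shape}")
    X = np.column_stack([np.ones(series.n_volumes), R])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("nuisance design is rank deficient")
    flat = series.data[series.mask]
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    out = series.data.copy()
    out[series.mask] = flat - (X @ beta).T
    return series.with_data(out)
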