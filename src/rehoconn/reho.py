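"""Regional homogeneity: voxelwise Kendall's coefficient of concordance.

Regional homogeneity (ReHo) quantifies the local temporal synchrony of the
BOLD signal: for each voxel, Kendall's W is computed over the ranks (across
time) of that voxel's series together with its nearest neighbours (26 by
default, i.e. the full 3x3x3 cube minus the centre).  With K series of n
time points, per-series ranks r_ij and time-point rank sums
R_i = sum_j r_ij,

    W = 12 * sum_i (R_i - K(n+1)/2)^2 / (K^2 (n^3 - n) - K * T)

where T is the standard tie correction, T = sum over series of
sum over tie groups of (t^3 - t).  W lies in [0, 1]; W = 1 means all K
series share an identical rank ordering, and under spatial independence
E[W] = 1/K.

The map computation is fully vectorised: voxel series are ranked once,
then per-voxel neighbourhood sums are accumulated by shifting the rank
volume over the 27 (or 19 / 7) offsets, so K adapts automatically to the
number of in-mask neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import BoldSeries

__all__ = ["kendall_w", "reho_map", "normalize_global_mean", "ReHoMap", "NEIGHBORHOOD_OFFSETS"]


def _offsets(neighborhood: int) -> list[tuple[int, int, int]]:
    if neighborhood not in (7, 19, 27):
        raise ValueError("neighborhood must be 7, 19 or 27")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if neighborhood == 7 and order > 1:
                    continue
                if neighborhood == 19 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


NEIGHBORHOOD_OFFSETS = {k: _offsets(k) for k in (7, 19, 27)}


def _tie_correction_terms(values: np.ndarray) -> np.ndarray:
    """Per-series tie term T_j = sum over tie groups of (t^3 - t).

    ``values`` is (..., n); returns shape (...).  Uses the telescoping
    identity sum_pos (3 L^2 - 3 L) over running tie lengths L, which avoids
    per-series Python loops.
    """
    s = np.sort(values, axis=-1)
    eq = s[..., 1:] == s[..., :-1]
    if not eq.any():
        return np.zeros(values.shape[:-1])
    n = values.shape[-1]
    run = np.ones(values.shape[:-1])
    total = np.zeros(values.shape[:-1])
    for j in range(1, n):
        run = np.where(eq[..., j - 1], run + 1, 1.0)
        total += 3.0 * run * (run - 1.0)
    return total


def kendall_w(block: np.ndarray, tie_correction: bool = True) -> float:
    """Kendall's W for a K x n block of time series (K series, n points).

    Ranks use midranks for ties; with ``tie_correction`` the standard tie
    term is subtracted from the denominator (disable it to mirror legacy
    toolboxes that skip the correction).  Returns 0 when the denominator is
    degenerate (every series constant).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ValueError("block must be 2D (K series x n time points)")
    K, n = block.shape
    if K < 2 or n < 2:
        raise ValueError("need K >= 2 series and n >= 2 time points")
    ranks = rankdata(block, axis=1)
    R = ranks.sum(axis=0)
    S = float(((R - K * (n + 1) / 2.0) ** 2).sum())
    T = float(_tie_correction_terms(block).sum()) if tie_correction else 0.0
    denom = K * K * (n ** 3 - n) - K * T
    if denom <= 0:
        return 0.0
    return 12.0 * S / denom


@dataclass
class ReHoMap:
    """3D field of Kendall's W with its mask and provenance flags."""

    values: np.ndarray
    mask: np.ndarray
    neighborhood: int
    normalized: bool = False


def _box3(arr: np.ndarray, axis: int) -> np.ndarray:
    """3-point sum (self + both neighbours, zero beyond the edge) along axis."""
    out = arr.copy()
    hi = [slice(None)] * arr.ndim
    lo = [slice(None)] * arr.ndim
    hi[axis] = slice(1, None)
    lo[axis] = slice(None, -1)
    out[tuple(lo)] += arr[tuple(hi)]
    out[tuple(hi)] += arr[tuple(lo)]
    return out


def _neighbor_sum(vol: np.ndarray, offsets) -> np.ndarray:
    """Sum of ``vol`` over spatial shifts; works for 3D and 4D arrays.

    The full 3x3x3 cube is separable into three 3-point box sums; other
    neighbourhoods fall back to explicit shifted adds.
    """
    if len(offsets) == 27:
        out = vol
        for ax in range(3):
            out = _box3(out, ax)
        return out
    nx, ny, nz = vol.shape[:3]
    pad_width = [(1, 1), (1, 1), (1, 1)] + [(0, 0)] * (vol.ndim - 3)
    padded = np.pad(vol, pad_width, mode="constant")
    out = np.zeros_like(vol)
    for dx, dy, dz in offsets:
        out += padded[1 + dx:1 + dx + nx, 1 + dy:1 + dy + ny, 1 + dz:1 + dz + nz]
    return out


def _rank_along_time(x: np.ndarray) -> np.ndarray:
    """Midranks along the last axis, with a fast path when there are no ties."""
    order = np.argsort(x, axis=-1, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=-1)
    if not (sorted_vals[..., 1:] == sorted_vals[..., :-1]).any():
        ranks = np.empty_like(x)
        np.put_along_axis(
            ranks, order,
            np.broadcast_to(np.arange(1.0, x.shape[-1] + 1.0), x.shape), axis=-1)
        return ranks
    return rankdata(x, axis=-1)


def reho_map(series: BoldSeries, neighborhood: int = 27,
             tie_correction: bool = True) -> ReHoMap:
    """Voxelwise Kendall's W over each voxel and its in-mask neighbours.

    Neighbours outside the mask are dropped (K adapts); voxels with fewer
    than 2 in-mask series get NaN, as does everything outside the mask.
    """
    offsets = _offsets(neighborhood)
    mask = series.mask
    if not mask.any():
        raise ValueError("mask is empty")
    n = series.n_volumes
    data = np.where(mask[..., None], series.data, 0.0)

    ranks = np.zeros_like(data)
    ranks[mask] = _rank_along_time(data[mask])

    maskf = mask.astype(float)
    K = _neighbor_sum(maskf, offsets)
    Rsum = _neighbor_sum(ranks, offsets)

    if tie_correction:
        tie_terms = np.zeros(mask.shape)
        tie_terms[mask] = _tie_correction_terms(data[mask])
        T = _neighbor_sum(tie_terms, offsets)
    else:
        T = np.zeros(mask.shape)

    S = ((Rsum - K[..., None] * (n + 1) / 2.0) ** 2).sum(axis=-1)
    denom = K * K * (n ** 3 - n) - K * T
    with np.errstate(divide="ignore", invalid="ignore"):
        W = 12.0 * S / denom
    W[denom <= 0] = 0.0
    W[K < 2] = np.nan
    W[~mask] = np.nan
    return ReHoMap(values=W, mask=mask, neighborhood=neighborhood)


def normalize_global_mean(reho: ReHoMap) -> ReHoMap:
    """Divide every in-mask value by the in-mask mean (mean becomes 1).

    Standardises ReHo across subjects before group statistics; invariant to
    rescaling of the input map.
    """
    vals = reho.values[reho.mask]
    mean = np.nanmean(vals)
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError("in-mask mean must be positive for normalization")
    out = reho.values / mean
    out[~reho.mask] = np.nan
    return ReHoMap(values=out, mask=reho.mask,
                   neighborhood=reho.neighborhood, normalized=True)
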