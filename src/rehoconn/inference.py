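"""Voxelwise group inference with Monte-Carlo cluster-extent correction.

Group differences are tested with an ordinary-least-squares GLM at every
voxel: the design holds an intercept, a group indicator and any nuisance
covariates (age, sex, education, gray-matter volume by default), and the
reported statistic is the t value of the group contrast,

    t = c' beta_hat / sqrt(sigma_hat^2 * c' (X'X)^-1 c),   dof = n - p.

Multiple comparisons over voxels are handled by cluster-extent
thresholding calibrated by Monte-Carlo simulation (the AlphaSim approach):
smooth Gaussian null fields matching the residual smoothness are
simulated on the mask's bounding box, thresholded at the voxelwise p, and
the distribution of the largest surviving cluster gives the minimum extent
whose family-wise probability under the null is below alpha.  Residual
smoothness is estimated per axis from the variance of spatial first
differences of the standardised residuals (the Gaussian-autocorrelation
estimator used by the classic AFNI tools).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats

from .connectivity import SeedROI
from .io import VolumeGrid
from .preprocess import fwhm_to_sigma

__all__ = [
    "DesignMatrix", "StatMap", "ClusterCriterion", "SmoothnessEstimate",
    "Cluster", "build_design", "glm_contrast_tmap", "estimate_fwhm",
    "alphasim_min_extent", "extract_clusters", "seeds_from_clusters",
    "build_connectivity_mask", "connectivity_structure",
]


@dataclass
class DesignMatrix:
    """GLM design: (n_subjects, p) matrix, column names and a contrast."""

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design must be 2D")
        if len(self.columns) != self.X.shape[1]:
            raise ValueError("column names do not match design width")
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length must equal number of columns")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if self.X.shape[0] <= self.X.shape[1]:
            raise ValueError("need more subjects than design columns")


def build_design(subjects: pd.DataFrame, covariates: list[str] | None = None,
                 group_col: str = "group", patient_label: str = "patient") -> DesignMatrix:
    """Intercept + group indicator (+ covariates) design with a group contrast.

    ``sex`` is coded 0 = male, 1 = female if still categorical.
    """
    covariates = list(covariates or [])
    n = len(subjects)
    cols = [np.ones(n), (subjects[group_col] == patient_label).to_numpy(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        v = subjects[cov]
        if cov == "sex" and v.dtype == object:
            v = v.map({"male": 0.0, "female": 1.0})
        cols.append(v.to_numpy(float))
        names.append(cov)
    contrast = np.zeros(len(names))
    contrast[1] = 1.0
    return DesignMatrix(np.column_stack(cols), names, contrast)


@dataclass
class StatMap:
    """Voxelwise t field with its degrees of freedom and residual maps."""

    t_values: np.ndarray
    dof: int
    mask: np.ndarray
    residual_maps: np.ndarray = field(repr=False, default=None)  # (n, x, y, z)


def glm_contrast_tmap(maps: np.ndarray, design: DesignMatrix,
                      mask: np.ndarray) -> StatMap:
    """OLS fit of per-subject 3D maps on the design; t map of the contrast.

    ``maps`` is (n_subjects, x, y, z).  Residual maps are kept for the
    smoothness estimate.  Voxels where the residual variance is exactly
    zero get t = 0 if the contrast estimate is 0, else +/- inf.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] != design.X.shape[0]:
        raise ValueError("number of maps does not match design rows")
    X = design.X
    n, p = X.shape
    dof = n - p
    Y = maps[:, mask]                          # (n, V)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                   # (p, V)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    c = design.contrast
    denom2 = sigma2 * float(c @ XtX_inv @ c)
    effect = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t_in = effect / np.sqrt(denom2)
    t_in[(denom2 == 0) & (effect == 0)] = 0.0

    t = np.full(mask.shape, np.nan)
    t[mask] = t_in
    residual_maps = np.zeros((n,) + mask.shape)
    residual_maps[:, mask] = resid
    return StatMap(t_values=t, dof=dof, mask=mask, residual_maps=residual_maps)


@dataclass(frozen=True)
class SmoothnessEstimate:
    """Per-axis spatial FWHM of the residual field, in mm."""

    fwhm_mm: tuple[float, float, float]


def estimate_fwhm(residual_maps: np.ndarray, grid: VolumeGrid,
                  mask: np.ndarray) -> SmoothnessEstimate:
    """Gaussian-autocorrelation smoothness of standardised residual maps.

    For a unit-variance Gaussian field smoothed with kernel sigma, the
    lag-1 autocorrelation along an axis is rho = exp(-1/(4 sigma_vox^2)),
    and var(first difference) = 2(1 - rho).  Inverting gives sigma and
    FWHM = 2 sqrt(2 ln 2) sigma per axis, averaged over maps.  Axes where
    the difference variance reaches or exceeds 2 (no positive lag-1
    correlation) report FWHM 0.
    """
    R = np.asarray(residual_maps, dtype=float)
    if R.ndim != 4 or R.shape[0] < 2:
        raise ValueError("need >= 2 residual maps (n, x, y, z)")
    fwhm = []
    # standardize each map within the mask
    vals = R[:, mask]
    sd = vals.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant residual map; smoothness undefined")
    Z = np.zeros_like(R)
    Z[:, mask] = (vals - vals.mean(axis=1, keepdims=True)) / sd
    for ax in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        pair = mask[tuple(sl_hi)] & mask[tuple(sl_lo)]
        if not pair.any():
            fwhm.append(0.0)
            continue
        diffs = (Z[(slice(None),) + tuple(sl_hi)] - Z[(slice(None),) + tuple(sl_lo)])[:, pair]
        vd = float((diffs ** 2).mean())
        rho = 1.0 - vd / 2.0
        if rho <= 0:
            fwhm.append(0.0)
            continue
        sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(rho)))
        fwhm.append(float(2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_vox
                          * grid.voxel_size_mm[ax]))
    return SmoothnessEstimate(fwhm_mm=tuple(fwhm))


@dataclass(frozen=True)
class ClusterCriterion:
    """Voxelwise threshold + cluster-level alpha for the Monte-Carlo correction."""

    p_voxel: float = 0.01
    alpha: float = 0.05
    sidedness: str = "two"        # "one" or "two"
    connectivity: int = 26        # 6, 18 or 26
    n_iterations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_voxel < 1):
            raise ValueError("p_voxel must be in (0,1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0,1]")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structure for scipy.ndimage.label."""
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def alphasim_min_extent(mask: np.ndarray, smoothness: SmoothnessEstimate,
                        criterion: ClusterCriterion,
                        voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                        ) -> int:
    """Monte-Carlo minimum cluster extent (AlphaSim-style).

    Each iteration draws a standard-normal field on the mask's bounding
    box, smooths it with the per-axis Gaussian kernel matching the target
    FWHM, standardises it within the mask, thresholds (|z| > z_{p/2} two-
    sided, z > z_p one-sided), and records the largest in-mask cluster.
    The returned extent is the smallest s whose family-wise probability
    P(largest cluster >= s) is <= alpha.  Deterministic given rng_seed.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    box_mask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    box_shape = tuple(hi - lo)

    sigma_vox = [fwhm_to_sigma(f) / v
                 for f, v in zip(smoothness.fwhm_mm, voxel_size_mm)]
    if criterion.sidedness == "two":
        z_thr = stats.norm.ppf(1.0 - criterion.p_voxel / 2.0)
    else:
        z_thr = stats.norm.ppf(1.0 - criterion.p_voxel)
    structure = connectivity_structure(criterion.connectivity)

    rng = np.random.default_rng(criterion.rng_seed)
    max_sizes = np.zeros(criterion.n_iterations, dtype=int)
    for it in range(criterion.n_iterations):
        fld = rng.standard_normal(box_shape)
        if any(s > 0 for s in sigma_vox):
            fld = ndimage.gaussian_filter(fld, sigma=sigma_vox, mode="constant")
        vals = fld[box_mask]
        if vals.size > 1:
            fld = (fld - vals.mean()) / vals.std()
        if criterion.sidedness == "two":
            supra = (np.abs(fld) > z_thr) & box_mask
        else:
            supra = (fld > z_thr) & box_mask
        best = 0
        # clusters of each sign separately (a cluster cannot mix signs)
        for signed in ((fld > z_thr) & box_mask, (fld < -z_thr) & box_mask) \
                if criterion.sidedness == "two" else (supra,):
            if not signed.any():
                continue
            labels, n_lab = ndimage.label(signed, structure=structure)
            if n_lab:
                sizes = np.bincount(labels.ravel())[1:]
                best = max(best, int(sizes.max()))
        max_sizes[it] = best

    # smallest s with P(max cluster >= s) <= alpha
    for s in range(1, int(max_sizes.max()) + 2):
        if (max_sizes >= s).mean() <= criterion.alpha:
            return s
    return int(max_sizes.max()) + 1


@dataclass
class Cluster:
    """One supra-threshold connected component of a t map."""

    cluster_id: int
    n_voxels: int
    peak_t: float
    peak_mm: tuple[float, float, float]
    voxel_indices: np.ndarray
    sign: int  # +1 or -1


def extract_clusters(stat: StatMap, p_voxel: float, min_extent: int,
                     connectivity: int, grid: VolumeGrid,
                     analysis_mask: np.ndarray | None = None) -> list[Cluster]:
    """Supra-threshold clusters of each sign, at the t(dof) voxel threshold.

    The voxel threshold is the two-sided p_voxel quantile of t with the
    map's dof; components smaller than ``min_extent`` are dropped.  Peaks
    are reported as the mm coordinate of the max-|t| voxel.  Clusters are
    numbered by descending extent (positive and negative mixed).
    """
    t_thr = stats.t.ppf(1.0 - p_voxel / 2.0, stat.dof)
    tmap = stat.t_values
    base = stat.mask if analysis_mask is None else (stat.mask & analysis_mask)
    structure = connectivity_structure(connectivity)
    clusters: list[Cluster] = []
    with np.errstate(invalid="ignore"):
        for sign in (1, -1):
            signed = np.nan_to_num(sign * tmap, nan=-np.inf)
            supra = base & (signed > t_thr)
            if not supra.any():
                continue
            labels, n_lab = ndimage.label(supra, structure=structure)
            for lab in range(1, n_lab + 1):
                idx = np.argwhere(labels == lab)
                if len(idx) < max(min_extent, 1):
                    continue
                tv = tmap[idx[:, 0], idx[:, 1], idx[:, 2]]
                peak = idx[np.argmax(np.abs(tv))]
                peak_mm = tuple(float(v) for v in np.atleast_1d(
                    grid.voxel_to_mm(peak)))
                clusters.append(Cluster(
                    cluster_id=0, n_voxels=len(idx),
                    peak_t=float(tv[np.argmax(np.abs(tv))]),
                    peak_mm=peak_mm, voxel_indices=idx, sign=sign))
    clusters.sort(key=lambda c: (-c.n_voxels, -abs(c.peak_t)))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i
    return clusters


def seeds_from_clusters(clusters: list[Cluster], sign: int = 1) -> list[SeedROI]:
    """Turn (positive, by default) clusters into seed ROIs for connectivity."""
    seeds = []
    for c in clusters:
        if c.sign != sign:
            continue
        seeds.append(SeedROI(
            roi_id=f"cluster{c.cluster_id}",
            voxel_indices=c.voxel_indices,
            source="reho_cluster",
            label=f"peak t={c.peak_t:.3f} at {c.peak_mm}"))
    return seeds


def build_connectivity_mask(group_statmaps: list[StatMap], p_voxel: float,
                            min_extent: int, connectivity: int,
                            grid: VolumeGrid) -> np.ndarray:
    """Union of corrected supra-threshold voxels over the groups' one-sample maps.

    Restricts the two-sample connectivity contrast to voxels showing
    significant connectivity to the seed in at least one group.
    """
    union = None
    for stat in group_statmaps:
        m = np.zeros(stat.mask.shape, dtype=bool)
        for c in extract_clusters(stat, p_voxel, min_extent, connectivity, grid):
            m[c.voxel_indices[:, 0], c.voxel_indices[:, 1], c.voxel_indices[:, 2]] = True
        union = m if union is None else (union | m)
    if union is None:
        raise ValueError("no group maps given")
    return union
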