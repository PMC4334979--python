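"""Independent reference implementations used only to check the package.

These deliberately avoid the package's vectorised code paths: ranks are
computed from the definition, concordance from the textbook rank-sum
formula, connected components by breadth-first flood fill, and the
Monte-Carlo extent threshold by an independently written simulator (which
shares only the library Gaussian-smoothing primitive and the random draw
protocol: one standard-normal bounding-box field per iteration).
"""

from __future__ import annotations

from collections import Counter, deque

import numpy as np
from scipy import ndimage


def midranks(values) -> list[float]:
    """Ranks over time from the definition: #smaller + (#equal + 1)/2."""
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def kendall_w_bruteforce(block, tie_correction: bool = True) -> float:
    """Textbook Kendall's W: S over its maximum, with the tie term."""
    block = [list(map(float, row)) for row in block]
    K = len(block)
    n = len(block[0])
    ranks = [midranks(row) for row in block]
    R = [sum(ranks[j][i] for j in range(K)) for i in range(n)]
    Rbar = sum(R) / n
    S = sum((Ri - Rbar) ** 2 for Ri in R)
    T = 0.0
    if tie_correction:
        for row in block:
            for t in Counter(row).values():
                T += t ** 3 - t
    denom = (K * K * (n ** 3 - n) - K * T) / 12.0
    return S / denom if denom > 0 else 0.0


_NEIGHBOR_OFFSETS = {
    6: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
        for dz in (-1, 0, 1) if abs(dx) + abs(dy) + abs(dz) == 1],
    18: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1) if 1 <= abs(dx) + abs(dy) + abs(dz) <= 2],
    26: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)],
}


def flood_fill_components(mask3d: np.ndarray, connectivity: int):
    """Connected components by BFS; returns a list of frozensets of voxels."""
    mask3d = np.asarray(mask3d, dtype=bool)
    offsets = _NEIGHBOR_OFFSETS[connectivity]
    seen = np.zeros_like(mask3d)
    comps = []
    for start in map(tuple, np.argwhere(mask3d)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            x, y, z = queue.popleft()
            comp.add((x, y, z))
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if (0 <= p[0] < mask3d.shape[0] and 0 <= p[1] < mask3d.shape[1]
                        and 0 <= p[2] < mask3d.shape[2]
                        and mask3d[p] and not seen[p]):
                    seen[p] = True
                    queue.append(p)
        comps.append(frozenset(comp))
    return comps


def alphasim_bruteforce(mask, fwhm_mm, voxel_size_mm, p_voxel, alpha,
                        sidedness, connectivity, n_iterations, seed) -> int:
    """Independent Monte-Carlo extent threshold.

    Mirrors the draw protocol (one standard-normal field on the mask's
    bounding box per iteration, Gaussian-smoothed, standardised within the
    mask) but thresholds and labels with its own code (BFS flood fill).
    """
    from scipy import stats

    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    box_mask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    box_shape = tuple(hi - lo)
    sigma = [f / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
             for f, v in zip(fwhm_mm, voxel_size_mm)]
    if sidedness == "two":
        z_thr = stats.norm.ppf(1.0 - p_voxel / 2.0)
    else:
        z_thr = stats.norm.ppf(1.0 - p_voxel)

    rng = np.random.default_rng(seed)
    max_sizes = []
    for _ in range(n_iterations):
        fld = rng.standard_normal(box_shape)
        if any(s > 0 for s in sigma):
            fld = ndimage.gaussian_filter(fld, sigma=sigma, mode="constant")
        vals = fld[box_mask]
        fld = (fld - vals.mean()) / vals.std()
        best = 0
        signs = (1, -1) if sidedness == "two" else (1,)
        for sign in signs:
            supra = (sign * fld > z_thr) & box_mask
            for comp in flood_fill_components(supra, connectivity):
                best = max(best, len(comp))
        max_sizes.append(best)
    max_sizes = np.asarray(max_sizes)
    for s in range(1, int(max_sizes.max()) + 2):
        if (max_sizes >= s).mean() <= alpha:
            return s
    return int(max_sizes.max()) + 1


def residualize_normal_equations(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of v on X via explicit normal equations."""
    beta = np.linalg.inv(X.T @ X) @ X.T @ v
    return v - X @ beta
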