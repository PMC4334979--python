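"""Calibration and power experiments run on the package's own pipeline.

These drive the two simulation studies that justify trusting the group
inference on data of this kind:

* ``null_cluster_rate`` — global-null calibration: cohorts with no planted
  effects are analysed end to end (generate -> preprocess -> ReHo ->
  covariate-adjusted group GLM -> Monte-Carlo cluster correction), and the
  fraction of analyses with at least one surviving cluster estimates the
  family-wise error rate, to be compared with the nominal alpha.

* ``planted_recovery`` — power and ground-truth recovery: cohorts with a
  planted high-synchrony sphere (group-dependent coupling), a coupled
  remote sphere and a coupling-driven THQ score are analysed; we record
  whether the ReHo contrast recovers the sphere (Dice overlap of the best
  surviving positive cluster), whether seeded connectivity elevates the
  remote region above background, and whether simulated THQ correlates
  positively with remote-region connectivity.

Monte-Carlo extent thresholds are cached on the rounded smoothness
estimate, since replicates of the same generative process share their
smoothness; this only avoids recomputing identical simulations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import pearson_r_p
from .connectivity import seed_correlation_map, SeedROI
from .inference import (ClusterCriterion, alphasim_min_extent, build_design,
                        estimate_fwhm, extract_clusters, glm_contrast_tmap)
from .pipeline import preprocess_for_connectivity, preprocess_for_reho
from .preprocess import PreprocessConfig
from .reho import normalize_global_mean, reho_map
from .synthetic import Cohort, CohortSpec, PlantedEffect, generate_cohort
from .preprocess import spatial_smooth

__all__ = ["reho_group_analysis", "null_cluster_rate", "planted_recovery",
           "dice"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 0.0


class _AlphasimCache:
    """min_extent cache keyed by (rounded per-axis FWHM, criterion)."""

    def __init__(self) -> None:
        self._store: dict = {}

    def min_extent(self, mask, smoothness, criterion: ClusterCriterion,
                   voxel_size) -> int:
        key = (tuple(round(f / 0.5) for f in smoothness.fwhm_mm),
               criterion.p_voxel, criterion.alpha, criterion.connectivity,
               criterion.sidedness, criterion.n_iterations, criterion.rng_seed)
        if key not in self._store:
            self._store[key] = alphasim_min_extent(
                mask, smoothness, criterion, voxel_size)
        return self._store[key]


def reho_group_analysis(cohort: Cohort, preprocess: PreprocessConfig,
                        criterion: ClusterCriterion,
                        covariates=("age_years", "sex", "education_years",
                                    "gm_volume_ml"),
                        neighborhood: int = 27,
                        cache: _AlphasimCache | None = None):
    """Per-subject ReHo maps -> covariate-adjusted group contrast ->
    corrected clusters.  Returns (clusters, statmap, reho_maps, min_extent)."""
    reho_maps: dict[str, np.ndarray] = {}
    for sub in cohort.subjects:
        prep = preprocess_for_reho(cohort.series[sub.subject_id], preprocess)
        rh = normalize_global_mean(reho_map(prep, neighborhood))
        reho_maps[sub.subject_id] = spatial_smooth(
            rh.values, preprocess.smooth_fwhm_mm, cohort.grid)
    ids = list(reho_maps)
    subj_df = pd.DataFrame([dataclasses.asdict(s) for s in cohort.subjects])
    design = build_design(subj_df, list(covariates))
    arr = np.stack([np.nan_to_num(reho_maps[i]) for i in ids])
    stat = glm_contrast_tmap(arr, design, cohort.mask)
    smooth = estimate_fwhm(stat.residual_maps, cohort.grid, cohort.mask)
    if cache is None:
        min_extent = alphasim_min_extent(cohort.mask, smooth, criterion,
                                         cohort.grid.voxel_size_mm)
    else:
        min_extent = cache.min_extent(cohort.mask, smooth, criterion,
                                      cohort.grid.voxel_size_mm)
    clusters = extract_clusters(stat, criterion.p_voxel, min_extent,
                                criterion.connectivity, cohort.grid)
    return clusters, stat, reho_maps, min_extent


def _null_spec(seed: int, n_a: int, n_b: int, grid_dims, n_volumes: int
               ) -> CohortSpec:
    return CohortSpec(n_group_a=n_a, n_group_b=n_b, grid_dims=grid_dims,
                      n_volumes=n_volumes, mask_radius_mm=28.0,
                      rng_seed=seed)


def null_cluster_rate(n_replicates: int = 200, seed: int = 0,
                      n_a: int = 14, n_b: int = 15,
                      grid_dims=(16, 16, 12), n_volumes: int = 70,
                      alpha: float = 0.05, p_voxel: float = 0.01,
                      n_iterations: int = 1000) -> dict:
    """Family-wise false-positive rate of the full group analysis under the
    global null (no planted effects), over replicate simulated cohorts.

    Returns the empirical rate, its 95% binomial (Wilson) interval, and
    the replicate count.
    """
    root = np.random.SeedSequence(seed)
    alphasim_child, *children = root.spawn(1 + n_replicates)
    # one simulation seed for the whole experiment: the extent threshold is
    # a deterministic function of (mask, smoothness, criterion), so sharing
    # it lets identical-smoothness replicates reuse the same simulation
    alphasim_seed = int(alphasim_child.generate_state(1)[0] % (2 ** 31))
    cache = _AlphasimCache()
    pp = PreprocessConfig(n_discard=10)
    hits = 0
    for rep in range(n_replicates):
        cohort_seed = int(children[rep].generate_state(1)[0] % (2 ** 31))
        spec = _null_spec(cohort_seed, n_a, n_b, tuple(grid_dims), n_volumes)
        cohort = generate_cohort(spec)
        crit = ClusterCriterion(p_voxel=p_voxel, alpha=alpha,
                                n_iterations=n_iterations,
                                rng_seed=alphasim_seed)
        clusters, *_ = reho_group_analysis(cohort, pp, crit, cache=cache)
        hits += bool(clusters)
    rate = hits / n_replicates
    lo, hi = _wilson_interval(hits, n_replicates)
    return {"rate": rate, "ci95": (lo, hi), "n_replicates": n_replicates,
            "alpha": alpha}


def _wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def _planted_spec(seed: int, grid_dims=(20, 20, 14),
                  coupling_a: float = 0.5, coupling_b: float = 0.25,
                  radius_mm: float = 9.0, n_volumes: int = 240,
                  connectivity_slope: float = 0.5,
                  score_link: float = 250.0) -> CohortSpec:
    effect = PlantedEffect(
        center_mm=(-9.0, 9.0, 3.0), radius_mm=radius_mm,
        local_coupling_a=coupling_a, local_coupling_b=coupling_b,
        remote_center_mm=(12.0, -12.0, -3.0), remote_radius_mm=7.5,
        connectivity_slope=connectivity_slope, score_link=score_link)
    return CohortSpec(n_group_a=29, n_group_b=30, grid_dims=tuple(grid_dims),
                      n_volumes=n_volumes, mask_radius_mm=27.0,
                      planted_effects=(effect,), rng_seed=seed)


def planted_recovery(n_seeds: int = 20, seed: int = 0,
                     alpha: float = 0.05, p_voxel: float = 0.01,
                     n_iterations: int = 1000, **spec_kwargs) -> dict:
    """Recovery of the planted effects over ``n_seeds`` generator seeds.

    Per seed: (1) Dice overlap between the planted sphere and the best
    surviving positive ReHo cluster; (2) whether mean seed connectivity
    (Fisher z) in the planted remote sphere exceeds the out-of-sphere
    background (paired t across subjects, one-sided p < 0.01); (3) the
    Pearson correlation sign between patients' remote-sphere mean z and
    their simulated THQ scores.
    """
    root = np.random.SeedSequence(seed)
    alphasim_child, *children = root.spawn(1 + n_seeds)
    alphasim_seed = int(alphasim_child.generate_state(1)[0] % (2 ** 31))
    cache = _AlphasimCache()
    pp = PreprocessConfig(n_discard=10)
    dices, remote_ps, thq_rs = [], [], []
    for rep in range(n_seeds):
        cohort_seed = int(children[rep].generate_state(1)[0] % (2 ** 31))
        spec = _planted_spec(cohort_seed, **spec_kwargs)
        cohort = generate_cohort(spec)
        crit = ClusterCriterion(p_voxel=p_voxel, alpha=alpha,
                                n_iterations=n_iterations,
                                rng_seed=alphasim_seed)
        clusters, stat, _, _ = reho_group_analysis(cohort, pp, crit,
                                                   cache=cache)
        truth_eff = cohort.truth["effects"][0]
        sphere = np.asarray(truth_eff["sphere_voxels"], dtype=int)
        sphere_mask = np.zeros(cohort.mask.shape, dtype=bool)
        sphere_mask[sphere[:, 0], sphere[:, 1], sphere[:, 2]] = True

        best_dice = 0.0
        best_cluster = None
        for c in clusters:
            if c.sign <= 0:
                continue
            cm = np.zeros(cohort.mask.shape, dtype=bool)
            cm[c.voxel_indices[:, 0], c.voxel_indices[:, 1],
               c.voxel_indices[:, 2]] = True
            d = dice(cm, sphere_mask)
            if d > best_dice:
                best_dice, best_cluster = d, c
        dices.append(best_dice)

        # connectivity: seed = recovered cluster (fall back to the truth
        # sphere if the contrast missed), remote recovery vs background
        seed_vox = (best_cluster.voxel_indices if best_cluster is not None
                    else sphere)
        roi = SeedROI(roi_id="seed", voxel_indices=seed_vox,
                      source="reho_cluster")
        remote = np.asarray(truth_eff["remote_voxels"], dtype=int)
        remote_mask = np.zeros(cohort.mask.shape, dtype=bool)
        remote_mask[remote[:, 0], remote[:, 1], remote[:, 2]] = True
        seed_mask = np.zeros(cohort.mask.shape, dtype=bool)
        seed_mask[seed_vox[:, 0], seed_vox[:, 1], seed_vox[:, 2]] = True
        background = cohort.mask & ~remote_mask & ~seed_mask & ~sphere_mask

        remote_means, bg_means = [], []
        thq_vals, thq_z = [], []
        for sub in cohort.subjects:
            nuis = cohort.truth["nuisance"][sub.subject_id][pp.n_discard:]
            conn = preprocess_for_connectivity(
                cohort.series[sub.subject_id], pp,
                cohort.motion[sub.subject_id], nuis)
            z = seed_correlation_map(conn, roi).z_values
            remote_means.append(float(np.nanmean(z[remote_mask])))
            bg_means.append(float(np.nanmean(z[background])))
            if sub.group == "patient":
                thq_vals.append(sub.thq)
                thq_z.append(float(np.nanmean(z[remote_mask])))
        t_res = stats.ttest_rel(remote_means, bg_means, alternative="greater")
        remote_ps.append(float(t_res.pvalue))
        thq_rs.append(pearson_r_p(thq_z, thq_vals).r)

    dices = np.asarray(dices)
    return {
        "n_seeds": n_seeds,
        "dice_values": dices.tolist(),
        "dice_recovery_rate": float((dices > 0.3).mean()),
        "mean_dice": float(dices.mean()),
        "remote_p_values": remote_ps,
        "remote_recovery_rate": float((np.asarray(remote_ps) < 0.01).mean()),
        "thq_r_values": thq_rs,
        "thq_sign_rate": float((np.asarray(thq_rs) > 0).mean()),
    }
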