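"""End-to-end orchestration: simulate/load -> screen -> preprocess ->
ReHo group contrast -> data-driven seeds -> seed connectivity -> masked
group contrasts -> brain-behaviour correlation.

The stages and their defaults follow the standard combined
ReHo + seed-connectivity design: dummy-volume discard (10), per-axis
motion screening (2 mm / 2 deg), detrend + 0.01-0.08 Hz band-pass, ReHo
over the 27-voxel neighbourhood, global-mean normalisation, 4 mm map
smoothing, covariate-adjusted group GLM with Monte-Carlo cluster
correction, positive ReHo clusters as seeds, 9-regressor nuisance removal
(6 motion + global/WM/CSF) before seed correlation, one-sample masks, and
Bonferroni-adjusted correlations of cluster means with clinical scores.

A single top-level seed is fanned out to per-stage child seeds so a rerun
of any stage in isolation is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import correlate_clusters_with_scores, demographic_table
from .connectivity import seed_correlation_map
from .inference import (ClusterCriterion, DesignMatrix, alphasim_min_extent,
                        build_design, build_connectivity_mask, estimate_fwhm,
                        extract_clusters, glm_contrast_tmap,
                        seeds_from_clusters)
from .io import (BoldSeries, load_series, read_motion_params, save_map,
                 write_cluster_table)
from .preprocess import (PreprocessConfig, bandpass_filter,
                         discard_initial_volumes, linear_detrend,
                         motion_screen, regress_nuisance, spatial_smooth)
from .reho import normalize_global_mean, reho_map
from .synthetic import Cohort, CohortSpec, generate_cohort

logger = logging.getLogger("rehoconn")

__all__ = ["PipelineConfig", "run_pipeline", "load_cohort_fixtures",
           "preprocess_for_reho", "preprocess_for_connectivity"]


@dataclass
class PipelineConfig:
    """One config object for the whole run (YAML-serialisable)."""

    out_dir: str = "rehoconn_out"
    input_dir: str | None = None          # if None, simulate
    simulate: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    reho_neighborhood: int = 27
    reho_tie_correction: bool = True
    reho_regress_nuisance: bool = False   # connectivity branch always does
    reho_double_smooth: bool = False      # also smooth data before ReHo
    cluster: ClusterCriterion = field(default_factory=ClusterCriterion)
    covariates: tuple[str, ...] = ("age_years", "sex", "education_years",
                                   "gm_volume_ml")
    scores: tuple[str, ...] = ("thq", "sas", "sds", "duration_months")
    rng_seed: int = 20150205

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "simulate" in kwargs:
            sim = dict(kwargs["simulate"])
            if "planted_effects" in sim:
                from .synthetic import PlantedEffect
                sim["planted_effects"] = tuple(
                    PlantedEffect(**{**e, "center_mm": tuple(e["center_mm"]),
                                    "remote_center_mm": (tuple(e["remote_center_mm"])
                                                         if e.get("remote_center_mm")
                                                         else None)})
                    for e in sim["planted_effects"])
            if "grid_dims" in sim:
                sim["grid_dims"] = tuple(sim["grid_dims"])
            kwargs["simulate"] = CohortSpec(**sim)
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "cluster" in kwargs:
            kwargs["cluster"] = ClusterCriterion(**kwargs["cluster"])
        for key in ("covariates", "scores"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_cohort_fixtures(input_dir) -> Cohort:
    """Rebuild a Cohort from a fixtures directory written by write_fixtures."""
    root = Path(input_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    table = pd.read_csv(root / manifest["subject_table"], sep="\t")
    truth = json.loads((root / manifest["truth"]).read_text())
    truth["nuisance"] = {sid: np.asarray(v)
                         for sid, v in truth.get("nuisance", {}).items()}

    from .synthetic import SubjectRecord
    subjects = [SubjectRecord(**row) for row in table.to_dict("records")]
    series: dict[str, BoldSeries] = {}
    motion: dict[str, np.ndarray] = {}
    mask_path = root / manifest["mask"]
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        series[sid] = load_series(root / entry["bold"], mask_path,
                                  tr_s=manifest["tr_s"])
        motion[sid] = read_motion_params(root / entry["motion"])
    any_series = next(iter(series.values()))
    spec = CohortSpec(n_group_a=sum(s.group == "patient" for s in subjects),
                      n_group_b=sum(s.group == "control" for s in subjects),
                      grid_dims=any_series.grid.dims,
                      voxel_size_mm=any_series.grid.voxel_size_mm[0],
                      tr_s=manifest["tr_s"], n_volumes=manifest["n_volumes"],
                      rng_seed=manifest["rng_seed"])
    return Cohort(spec=spec, grid=any_series.grid, mask=any_series.mask,
                  subjects=subjects, series=series, motion=motion, truth=truth)


def preprocess_for_reho(series: BoldSeries, cfg: PreprocessConfig,
                        double_smooth: bool = False) -> BoldSeries:
    """Discard -> detrend -> band-pass (ReHo is computed on unsmoothed data;
    the ReHo *map* is smoothed afterwards, unless double_smooth)."""
    s = discard_initial_volumes(series, cfg.n_discard)
    s = linear_detrend(s)
    s = bandpass_filter(s, cfg.band_low_hz, cfg.band_high_hz)
    if double_smooth and cfg.smooth_fwhm_mm > 0:
        s = spatial_smooth(s, cfg.smooth_fwhm_mm, s.grid)
    return s


def preprocess_for_connectivity(series: BoldSeries, cfg: PreprocessConfig,
                                motion: np.ndarray,
                                nuisance_signals: np.ndarray | None) -> BoldSeries:
    """Discard -> detrend -> band-pass -> smooth -> 9-regressor nuisance
    removal (6 motion + global/WM/CSF).

    ``nuisance_signals`` is (n_volumes_after_discard, 3) or None, in which
    case the mask-mean signal stands in for all three tissue signals.
    """
    s = preprocess_for_reho(series, cfg)
    if cfg.smooth_fwhm_mm > 0:
        s = spatial_smooth(s, cfg.smooth_fwhm_mm, s.grid)
    mot = motion[cfg.n_discard:]
    if nuisance_signals is None:
        # tissue segmentation is out of reach for synthetic grids: the
        # mask-mean (global) signal stands in as the sole tissue regressor
        gs = s.data[s.mask].mean(axis=0)
        nuisance_signals = gs[:, None]
    regs = np.column_stack([mot, nuisance_signals])
    return regress_nuisance(s, regs)


def _cluster_means(maps: dict[str, np.ndarray], clusters, subject_ids):
    """Per-subject mean map value within each cluster -> DataFrame."""
    data = {}
    for c in clusters:
        idx = c.voxel_indices
        data[f"cluster{c.cluster_id}"] = [
            float(np.nanmean(maps[sid][idx[:, 0], idx[:, 1], idx[:, 2]]))
            for sid in subject_ids]
    return pd.DataFrame(data, index=pd.Index(subject_ids, name="subject_id"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.rng_seed)
    alphasim_seed = int(rng_root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    manifest: dict = {"version": __version__, "rng_seed": config.rng_seed,
                      "stages": {}}

    # --- stage 1: cohort ------------------------------------------------
    if config.input_dir is None:
        cohort = generate_cohort(config.simulate)
        logger.info("simulated cohort: %d subjects", len(cohort.subjects))
    else:
        cohort = load_cohort_fixtures(config.input_dir)
        logger.info("loaded cohort from %s", config.input_dir)
    grid, mask = cohort.grid, cohort.mask
    pp = config.preprocess

    # --- stage 2: motion screening --------------------------------------
    excluded = []
    for sub in cohort.subjects:
        screen = motion_screen(cohort.motion[sub.subject_id],
                               pp.motion_limit_mm, pp.motion_limit_deg)
        if not screen["included"]:
            excluded.append(sub.subject_id)
            logger.info("excluding %s for head motion (max %s)",
                        sub.subject_id, np.round(screen["max_abs"], 2))
    included = [s for s in cohort.subjects if s.subject_id not in excluded]
    subj_df = pd.DataFrame([dataclasses.asdict(s) for s in included]
                           ).set_index("subject_id")
    subj_df.to_csv(out / "subjects_included.tsv", sep="\t")
    demographic_table(subj_df.reset_index()).to_csv(
        out / "demographics.tsv", sep="\t", index=False)
    manifest["stages"]["motion_screen"] = {"n_excluded": len(excluded),
                                           "excluded": excluded}

    # --- stage 3: ReHo maps ---------------------------------------------
    reho_maps: dict[str, np.ndarray] = {}
    for sub in included:
        sid = sub.subject_id
        prep = preprocess_for_reho(cohort.series[sid], pp,
                                   double_smooth=config.reho_double_smooth)
        if config.reho_regress_nuisance:
            nuis = cohort.truth.get("nuisance", {}).get(sid)
            nuis = nuis[pp.n_discard:] if nuis is not None else None
            mot = cohort.motion[sid][pp.n_discard:]
            regs = mot if nuis is None else np.column_stack([mot, nuis])
            prep = regress_nuisance(prep, regs)
        rh = normalize_global_mean(
            reho_map(prep, config.reho_neighborhood, config.reho_tie_correction))
        reho_maps[sid] = spatial_smooth(rh.values, pp.smooth_fwhm_mm, grid)
    subject_ids = list(reho_maps)

    # --- stage 4: ReHo group contrast ------------------------------------
    design = build_design(subj_df.loc[subject_ids].reset_index(),
                          list(config.covariates))
    maps_arr = np.stack([np.nan_to_num(reho_maps[sid]) for sid in subject_ids])
    stat = glm_contrast_tmap(maps_arr, design, mask)
    smooth = estimate_fwhm(stat.residual_maps, grid, mask)
    crit = dataclasses.replace(config.cluster, rng_seed=alphasim_seed)
    min_extent = alphasim_min_extent(mask, smooth, crit, grid.voxel_size_mm)
    clusters = extract_clusters(stat, crit.p_voxel, min_extent,
                                crit.connectivity, grid)
    save_map(stat.t_values, grid, out / "reho_tmap.nii.gz")
    write_cluster_table(clusters, out / "reho_clusters.tsv")
    logger.info("ReHo contrast: min_extent=%d, %d clusters",
                min_extent, len(clusters))
    manifest["stages"]["reho_group"] = {
        "min_extent": min_extent, "fwhm_mm": list(smooth.fwhm_mm),
        "n_clusters": len(clusters),
        "n_positive": sum(c.sign > 0 for c in clusters)}

    # --- stage 5: seeds ---------------------------------------------------
    seeds = seeds_from_clusters(clusters, sign=1)
    if not seeds:
        logger.warning("no positive ReHo clusters; connectivity and "
                       "correlation stages skipped")
        manifest["stages"]["connectivity"] = {"status": "no seeds"}
        manifest["stages"]["correlation"] = {"status": "no seeds"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    # --- stage 6: connectivity -------------------------------------------
    conn_series: dict[str, BoldSeries] = {}
    for sub in included:
        sid = sub.subject_id
        nuis = cohort.truth.get("nuisance", {}).get(sid)
        nuis = nuis[pp.n_discard:] if nuis is not None else None
        conn_series[sid] = preprocess_for_connectivity(
            cohort.series[sid], pp, cohort.motion[sid], nuis)

    patients = [s.subject_id for s in included if s.group == "patient"]
    controls = [s.subject_id for s in included if s.group == "control"]
    conn_results = {}
    all_cluster_means = []
    for seed in seeds:
        zmaps = {sid: seed_correlation_map(conn_series[sid], seed).z_values
                 for sid in subject_ids}
        zarr = np.stack([np.nan_to_num(zmaps[sid]) for sid in subject_ids])

        # one-sample t per group -> combined analysis mask
        group_stats = []
        for ids in (patients, controls):
            gm_arr = zarr[[subject_ids.index(i) for i in ids]]
            one = DesignMatrix(np.ones((len(ids), 1)), ["intercept"],
                               np.array([1.0]))
            group_stats.append(glm_contrast_tmap(gm_arr, one, mask))
        one_smooth = estimate_fwhm(group_stats[0].residual_maps, grid, mask)
        one_extent = alphasim_min_extent(mask, one_smooth, crit,
                                         grid.voxel_size_mm)
        analysis_mask = build_connectivity_mask(
            group_stats, crit.p_voxel, one_extent, crit.connectivity, grid)
        if not analysis_mask.any():
            logger.warning("seed %s: empty connectivity mask; skipped",
                           seed.roi_id)
            conn_results[seed.roi_id] = {"status": "empty mask"}
            continue

        stat2 = glm_contrast_tmap(zarr, design, mask)
        smooth2 = estimate_fwhm(stat2.residual_maps, grid, mask)
        extent2 = alphasim_min_extent(analysis_mask, smooth2, crit,
                                      grid.voxel_size_mm)
        cl2 = extract_clusters(stat2, crit.p_voxel, extent2,
                               crit.connectivity, grid,
                               analysis_mask=analysis_mask)
        save_map(stat2.t_values, grid, out / f"conn_{seed.roi_id}_tmap.nii.gz")
        write_cluster_table(cl2, out / f"conn_{seed.roi_id}_clusters.tsv")
        conn_results[seed.roi_id] = {
            "min_extent": extent2, "n_clusters": len(cl2),
            "mask_voxels": int(analysis_mask.sum())}
        pos = [c for c in cl2 if c.sign > 0]
        if pos:
            cm = _cluster_means(zmaps, pos, patients)
            cm.columns = [f"{seed.roi_id}_{c}" for c in cm.columns]
            all_cluster_means.append(cm)
    manifest["stages"]["connectivity"] = conn_results

    # --- stage 7: brain-behaviour correlation ----------------------------
    # ReHo cluster means for patients join the connectivity cluster means
    pos_reho = [c for c in clusters if c.sign > 0]
    if pos_reho:
        cm = _cluster_means(reho_maps, pos_reho, patients)
        cm.columns = [f"reho_{c}" for c in cm.columns]
        all_cluster_means.insert(0, cm)
    if all_cluster_means:
        values = pd.concat(all_cluster_means, axis=1)
        score_df = subj_df.loc[patients, list(config.scores)].astype(float)
        score_df = score_df.loc[:, score_df.std() > 0]
        cov_df = subj_df.loc[patients, list(config.covariates)]
        corr = correlate_clusters_with_scores(values, score_df, cov_df)
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False,
                    float_format="%.6f")
        manifest["stages"]["correlation"] = {"n_tests": len(corr)}
    else:
        manifest["stages"]["correlation"] = {"status": "no clusters"}

    manifest["parameters"] = {
        "preprocess": dataclasses.asdict(pp),
        "cluster": dataclasses.asdict(config.cluster),
        "reho_neighborhood": config.reho_neighborhood,
        "covariates": list(config.covariates),
        "scores": list(config.scores),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
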