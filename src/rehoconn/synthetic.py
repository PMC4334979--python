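"""Synthetic two-group resting-state cohorts with planted ground truth.

The generator emulates the statistical structure a ReHo + seed-based
connectivity study assumes, on a desk-scale grid:

* two groups (defaults 29 patients, 30 controls) of 4D BOLD runs at
  TR = 2 s, 240 acquired volumes of which the first 10 are dummies;
* spherical regions whose voxels share a band-limited latent signal, with
  a group-specific coupling fraction ``c`` — inside a planted sphere each
  voxel is sqrt(1-c) * noise + sqrt(c) * latent, so the expected pairwise
  correlation between sphere voxels is c;
* an optional remote sphere that receives the seed sphere's cluster
  latent with a per-subject coupling weight beta (so interregional
  synchrony rides on the same signal that makes the seed locally
  coherent, and the seed's local synchrony stays exactly c); beta also
  drives a simulated tinnitus-distress (THQ) score:
  THQ = mean + score_link * (beta - E[beta]) + noise;
* linear drift, global/"white-matter"/"CSF" nuisance time courses, and
  bounded-random-walk motion parameter files (optionally one subject
  planted above the 2 mm exclusion limit);
* demographic covariates (age, sex, education, gray-matter volume) drawn
  from group-specific distributions.

All latents are band-limited to 0.01-0.08 Hz so that planted effects
survive the preprocessing band-pass.  Everything is reproducible from a
single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BoldSeries, VolumeGrid, save_map, save_series

__all__ = ["PlantedEffect", "CohortSpec", "SubjectRecord", "Cohort",
           "generate_cohort", "write_fixtures", "sphere_voxels",
           "DEFAULT_COVARIATES"]


@dataclass(frozen=True)
class PlantedEffect:
    """A spherical locus of elevated local synchrony, optionally coupled
    to a remote sphere with a per-subject strength that drives THQ."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    local_coupling_a: float = 0.0      # patients
    local_coupling_b: float = 0.0      # controls
    remote_center_mm: tuple[float, float, float] | None = None
    remote_radius_mm: float = 0.0
    connectivity_slope: float = 0.0    # mean per-subject seed-remote beta
    score_link: float = 0.0            # weight of beta in simulated THQ

    def __post_init__(self) -> None:
        for c in (self.local_coupling_a, self.local_coupling_b):
            if not (0 <= c < 1):
                raise ValueError("local couplings must lie in [0, 1)")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


# Group-specific covariate distributions (continuous: mean/sd, sex: P(male))
DEFAULT_COVARIATES: dict = {
    "patient": {"age_years": (40.9, 10.5), "education_years": (10.9, 2.2),
                "gm_volume_ml": (581.2, 26.4), "wm_volume_ml": (531.6, 25.6),
                "p_male": 16 / 29},
    "control": {"age_years": (46.2, 11.9), "education_years": (11.1, 1.7),
                "gm_volume_ml": (576.1, 22.1), "wm_volume_ml": (528.8, 25.4),
                "p_male": 15 / 30},
}


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort."""

    n_group_a: int = 29                 # patients
    n_group_b: int = 30                 # controls
    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 240                # first 10 are dummies downstream
    mask_radius_mm: float = 32.0        # ellipsoid semi-axis in x/y
    planted_effects: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    motion_sd_mm: float = 0.05          # random-walk step SD (mm / deg)
    global_signal_weight: float = 0.3
    tissue_signal_weights: tuple[float, float] = (0.2, 0.15)  # "WM", "CSF"
    covariate_distributions: dict = dc_field(default_factory=lambda: DEFAULT_COVARIATES)
    thq_mean: float = 103.5
    thq_noise_sd: float = 50.0
    plant_motion_outlier: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed the 10 dummy volumes")
        if any(d < 8 for d in self.grid_dims):
            raise ValueError("all grid dims must be >= 8")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.motion_sd_mm < 0:
            raise ValueError("motion_sd_mm must be nonnegative")


@dataclass
class SubjectRecord:
    """One participant: group label, covariates and clinical scores."""

    subject_id: str
    group: str                       # "patient" or "control"
    age_years: float
    sex: str                         # "male" or "female"
    education_years: float
    gm_volume_ml: float
    wm_volume_ml: float
    thq: float = np.nan
    sas: float = np.nan
    sds: float = np.nan
    duration_months: float = np.nan
    true_coupling: float = 0.0       # ground truth, simulation only


@dataclass
class Cohort:
    """A generated cohort: subjects, series, mask and ground truth."""

    spec: CohortSpec
    grid: VolumeGrid
    mask: np.ndarray
    subjects: list[SubjectRecord]
    series: dict[str, BoldSeries]
    motion: dict[str, np.ndarray]
    truth: dict

    def subject_table(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(s) for s in self.subjects])
        return df.set_index("subject_id")


def sphere_voxels(grid: VolumeGrid, center_mm, radius_mm: float) -> np.ndarray:
    """0-based indices of voxels whose centre lies within radius of center_mm."""
    dims = grid.dims
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = np.atleast_2d(grid.voxel_to_mm(idx))
    d2 = ((mm - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=1)
    return idx[d2 <= radius_mm ** 2]


def ellipsoid_mask(grid: VolumeGrid, radius_mm: float) -> np.ndarray:
    """Brain-like ellipsoid: semi-axes radius_mm in x/y, scaled to the
    grid's relative z extent (strictly inside the grid)."""
    dims = grid.dims
    vs = grid.voxel_size_mm
    semi = np.array([radius_mm, radius_mm,
                     radius_mm * (dims[2] * vs[2]) / (dims[0] * vs[0])])
    # keep the ellipsoid strictly inside the grid
    half_extent = np.array([(d - 1) / 2 * v for d, v in zip(dims, vs)])
    semi = np.minimum(semi, half_extent * 0.98)
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = np.atleast_2d(grid.voxel_to_mm(idx))
    inside = ((mm / semi) ** 2).sum(axis=1) <= 1.0
    mask = np.zeros(dims, dtype=bool)
    mask[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = True
    return mask


def _band_limited(rng: np.random.Generator, n: int, tr_s: float,
                  low_hz: float = 0.01, high_hz: float = 0.08,
                  size: int | None = None) -> np.ndarray:
    """Unit-variance white noise restricted to the given frequency band."""
    shape = (n,) if size is None else (size, n)
    x = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():
        raise ValueError("band contains no frequency bin at this length/TR")
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / sd


def _bounded_walk(rng: np.random.Generator, n: int, step_sd: float,
                  bound: float) -> np.ndarray:
    steps = rng.normal(0.0, step_sd, size=n)
    walk = np.cumsum(steps)
    return np.clip(walk, -bound, bound)


def _truncated_normal(rng, mean, sd, low=-np.inf, high=np.inf):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if low <= v <= high:
            return v
    return float(np.clip(mean, low, high))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the cohort: subject table, per-subject series, ground truth.

    Deterministic given ``spec.rng_seed``; per-subject randomness is fanned
    out through `numpy.random.SeedSequence.spawn` so adding a subject does
    not perturb the others.
    """
    grid = VolumeGrid.centered(spec.grid_dims, spec.voxel_size_mm)
    mask = ellipsoid_mask(grid, spec.mask_radius_mm)
    if not mask.any():
        raise ValueError("brain mask is empty")
    n_sub = spec.n_group_a + spec.n_group_b
    T = spec.n_volumes

    # resolve planted spheres once, against the mask
    effects = []
    for e_idx, eff in enumerate(spec.planted_effects):
        sphere = sphere_voxels(grid, eff.center_mm, eff.radius_mm)
        in_mask = mask[sphere[:, 0], sphere[:, 1], sphere[:, 2]]
        if len(sphere) == 0 or not in_mask.all():
            raise ValueError(
                f"planted sphere {e_idx} lies (partly) outside the mask")
        remote = None
        if eff.remote_center_mm is not None:
            remote = sphere_voxels(grid, eff.remote_center_mm, eff.remote_radius_mm)
            rin = mask[remote[:, 0], remote[:, 1], remote[:, 2]]
            if len(remote) == 0 or not rin.all():
                raise ValueError(
                    f"remote sphere {e_idx} lies (partly) outside the mask")
        effects.append({"effect": eff, "sphere": sphere, "remote": remote})

    root = np.random.SeedSequence(spec.rng_seed)
    cohort_ss, *subject_ss = root.spawn(1 + n_sub)
    cohort_rng = np.random.default_rng(cohort_ss)

    groups = ["patient"] * spec.n_group_a + ["control"] * spec.n_group_b
    subjects: list[SubjectRecord] = []
    series: dict[str, BoldSeries] = {}
    motion: dict[str, np.ndarray] = {}
    nuisance_truth: dict[str, np.ndarray] = {}
    betas: dict[str, float] = {}

    outlier_id = None
    if spec.plant_motion_outlier and spec.n_group_b > 0:
        outlier_id = f"sub{spec.n_group_a + 1:03d}"   # first control

    flat_mask = np.where(mask.ravel())[0]
    for s_idx, (group, ss) in enumerate(zip(groups, subject_ss)):
        rng = np.random.default_rng(ss)
        sid = f"sub{s_idx + 1:03d}"

        # --- demographics ---------------------------------------------
        dist = spec.covariate_distributions[group]
        age = _truncated_normal(rng, *dist["age_years"], low=18, high=80)
        sex = "male" if rng.random() < dist["p_male"] else "female"
        edu = _truncated_normal(rng, *dist["education_years"], low=8, high=22)
        gm = rng.normal(*dist["gm_volume_ml"])
        wm = rng.normal(*dist["wm_volume_ml"])

        # --- voxel signal ---------------------------------------------
        data = np.zeros(spec.grid_dims + (T,))
        noise = rng.standard_normal((len(flat_mask), T))
        signal = noise.copy()

        beta_total = 0.0
        for e in effects:
            eff: PlantedEffect = e["effect"]
            c = eff.local_coupling_a if group == "patient" else eff.local_coupling_b
            sphere = e["sphere"]
            sphere_flat = np.ravel_multi_index(sphere.T, spec.grid_dims)
            sphere_pos = np.searchsorted(flat_mask, sphere_flat)
            beta = 0.0
            if e["remote"] is not None and eff.connectivity_slope != 0.0:
                beta = eff.connectivity_slope * _truncated_normal(
                    rng, 1.0, 0.35, low=0.0)
            latent = _band_limited(rng, T, spec.tr_s)
            if c > 0:
                signal[sphere_pos] = (np.sqrt(1.0 - c) * noise[sphere_pos]
                                      + np.sqrt(c) * latent)
            if beta != 0.0:
                # the cluster latent itself links the spheres: the remote
                # region receives it with per-subject weight beta, so the
                # seed sphere's local synchrony stays exactly c
                remote = e["remote"]
                remote_flat = np.ravel_multi_index(remote.T, spec.grid_dims)
                remote_pos = np.searchsorted(flat_mask, remote_flat)
                signal[remote_pos] = (np.sqrt(max(0.0, 1.0 - beta ** 2))
                                      * noise[remote_pos] + beta * latent)
                beta_total += beta
        betas[sid] = beta_total

        # --- drift + nuisance -----------------------------------------
        drift = spec.drift_amplitude * np.linspace(-0.5, 0.5, T)
        nuis = _band_limited(rng, T, spec.tr_s, low_hz=0.005, high_hz=0.1,
                             size=3)  # global, "WM", "CSF"
        weights = (spec.global_signal_weight,) + spec.tissue_signal_weights
        nuisance = sum(w * nuis[i] for i, w in enumerate(weights))
        voxels = spec.noise_sd * signal + drift + nuisance
        data.reshape(-1, T)[flat_mask] = voxels
        series[sid] = BoldSeries(grid=grid, tr_s=spec.tr_s, data=data, mask=mask)
        nuisance_truth[sid] = nuis.T.copy()          # (T, 3)

        # --- motion ----------------------------------------------------
        mot = np.column_stack([
            _bounded_walk(rng, T, spec.motion_sd_mm, 1.5) for _ in range(6)])
        if sid == outlier_id:
            mot[T // 2, 0] = 2.5   # plant a supra-limit translation spike
        motion[sid] = mot

        # --- clinical scores -------------------------------------------
        thq = sas = sds = duration = np.nan
        if group == "patient":
            link_total = sum(e["effect"].score_link for e in effects)
            mean_beta = sum(e["effect"].connectivity_slope for e in effects
                            if e["remote"] is not None)
            thq = (spec.thq_mean
                   + (link_total * (beta_total - mean_beta) if link_total else 0.0)
                   + rng.normal(0.0, spec.thq_noise_sd))
            sas = _truncated_normal(rng, 38.0, 6.0, low=20, high=49.9)
            sds = _truncated_normal(rng, 38.0, 6.0, low=20, high=49.9)
            duration = float(np.exp(rng.normal(3.40, 0.74)))  # ~= 39.5 +/- 33.7
        subjects.append(SubjectRecord(
            subject_id=sid, group=group, age_years=age, sex=sex,
            education_years=edu, gm_volume_ml=gm, wm_volume_ml=wm,
            thq=thq, sas=sas, sds=sds, duration_months=duration,
            true_coupling=beta_total))

    truth = {
        "effects": [
            {"center_mm": list(e["effect"].center_mm),
             "radius_mm": e["effect"].radius_mm,
             "local_coupling_a": e["effect"].local_coupling_a,
             "local_coupling_b": e["effect"].local_coupling_b,
             "sphere_voxels": e["sphere"].tolist(),
             "remote_voxels": (e["remote"].tolist()
                               if e["remote"] is not None else None),
             "connectivity_slope": e["effect"].connectivity_slope,
             "score_link": e["effect"].score_link}
            for e in effects],
        "betas": betas,
        "nuisance": nuisance_truth,
        "motion_outlier": outlier_id,
    }
    return Cohort(spec=spec, grid=grid, mask=mask, subjects=subjects,
                  series=series, motion=motion, truth=truth)


SUBJECT_TSV_COLUMNS = ["subject_id", "group", "age_years", "sex",
                       "education_years", "gm_volume_ml", "wm_volume_ml",
                       "thq", "sas", "sds", "duration_months", "true_coupling"]


def write_fixtures(cohort: Cohort, out_dir) -> dict:
    """Write the cohort to disk: NIfTI series + mask, TSV subject table,
    6-column motion files and a JSON ground-truth manifest.

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_map(cohort.mask.astype(np.float32), cohort.grid, out / "mask.nii.gz")
    entries = []
    for sub in cohort.subjects:
        sid = sub.subject_id
        bold_path = out / f"{sid}_bold.nii.gz"
        save_series(cohort.series[sid], bold_path)
        motion_path = out / f"{sid}_motion.txt"
        np.savetxt(motion_path, cohort.motion[sid], fmt="%.6f")
        entries.append({"subject_id": sid, "bold": bold_path.name,
                        "motion": motion_path.name})
    table = pd.DataFrame([dataclasses.asdict(s) for s in cohort.subjects])
    table = table[SUBJECT_TSV_COLUMNS]
    table.to_csv(out / "subjects.tsv", sep="\t", index=False)

    truth = {k: v for k, v in cohort.truth.items() if k != "nuisance"}
    truth["nuisance"] = {sid: arr.tolist()
                         for sid, arr in cohort.truth["nuisance"].items()}
    (out / "truth.json").write_text(json.dumps(truth))

    manifest = {
        "mask": "mask.nii.gz",
        "subject_table": "subjects.tsv",
        "truth": "truth.json",
        "tr_s": cohort.spec.tr_s,
        "n_volumes": cohort.spec.n_volumes,
        "rng_seed": cohort.spec.rng_seed,
        "subjects": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
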