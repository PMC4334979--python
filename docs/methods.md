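# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Pipeline model

The analysis chain is the standard two-group resting-state ReHo +
seed-connectivity design:

1. discard the first 10 volumes (magnetisation equilibration);
2. exclude subjects whose rigid-motion parameters exceed 2.0 mm
   translation or 2.0° rotation on any axis (strict inequality, per axis;
   framewise displacement is deliberately not used);
3. per voxel: linear detrend, then an ideal DFT band-pass keeping
   0.01–0.08 Hz (bins with `low ≤ f ≤ high`; DC always removed). The
   filter is an exact projection — idempotent to machine precision —
   which is also what the classic resting-state toolboxes implement;
4. ReHo: Kendall's W over each in-mask voxel and its 26 neighbours
   (27-voxel cube; 7/19 variants available). Ranks are midranks; the
   standard tie-correction term is subtracted from the denominator (a
   switch disables it to mirror legacy implementations — filtered
   continuous data essentially never tie, so the two agree in practice).
   Neighbours outside the mask are dropped and K adapts; voxels with
   K < 2 are NaN. ReHo is computed on *unsmoothed* filtered data; the map
   is global-mean-normalised and then smoothed at 4 mm FWHM. (A
   `reho_double_smooth` switch additionally smooths the data first, for
   pipelines that smooth within preprocessing.)
5. group inference: voxelwise OLS with intercept, group, age, sex (0 =
   male, 1 = female), education and gray-matter volume;
   `t = c'β̂ / sqrt(σ̂² c'(X'X)⁻¹c)` with dof = n − p. Two-sided voxel
   threshold at p = 0.01 by default (both directions are reported);
6. cluster correction: per-axis residual smoothness is estimated from the
   lag-1 autocorrelation of standardised residual maps
   (`ρ₁ = 1 − var(Δ)/2`, `σ² = −1/(4 ln ρ₁)`, FWHM = 2√(2 ln 2)·σ), and a
   Monte-Carlo simulation (Gaussian fields on the mask's bounding box,
   smoothed to that FWHM, standardised within the mask, 26-connectivity
   components) yields the smallest cluster extent whose family-wise
   probability under the null is ≤ alpha. The Gaussian null is the usual
   large-dof approximation to the t field;
7. connectivity: positive ReHo clusters become seeds. The connectivity
   branch re-preprocesses with smoothing *before* a 9-regressor nuisance
   removal (6 motion + global/WM/CSF; in simulation these are the
   generator's known nuisance series, with the mask-mean as fallback),
   then correlates each voxel with the seed-mean course and applies
   Fisher's z. Correlations are clamped at |r| = 1 − 1e−7 so seed voxels
   cannot inject infinities into group maps. Two-sample contrasts are
   restricted to a mask formed by the union of each group's corrected
   one-sample results for that seed;
8. clinical correlation: per-patient cluster means vs THQ/SAS/SDS/
   duration, as simple Pearson (dof n − 2) and as partial correlations
   residualised on the four covariates (dof n − 2 − k), each family
   Bonferroni-adjusted over clusters × scores. Published r/p pairs of
   this design reproduce under the *simple* Pearson dof, so that variant
   is primary; partials are always reported alongside. The 2×2 sex
   comparison uses the uncorrected Pearson chi-square (the continuity-
   corrected version does not reproduce the published table's p value
   from its printed counts). Demographic summary comparisons use the
   pooled-variance t (Welch available as an option).

A single top-level RNG seed is fanned out (`SeedSequence.spawn`) to
per-stage child seeds, so any stage re-run in isolation is reproducible
and the run manifest suffices to reproduce a run byte-for-byte.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not scanner physics. Defaults: 29 patients + 30 controls, 24×24×16 grid
at 3 mm, TR 2 s, 240 acquired volumes (10 dummies), ellipsoidal brain
mask strictly inside the grid, RAS+ affine with the origin at the grid
centre (so reported mm coordinates are MNI-like without registration).
The acquisition it mimics records ≈243 volumes in 8 min 6 s at TR 2 s but
analyses 230 after dropping 10; the generator rounds to 240 acquired.

Per subject, each in-mask voxel is unit white noise plus:

* **planted local synchrony** — inside a sphere, voxels are
  `sqrt(1−c)·noise + sqrt(c)·L` with a band-limited (0.01–0.08 Hz,
  unit-variance) latent `L` shared across the sphere, so the expected
  within-sphere pairwise correlation is exactly the group-specific
  coupling `c`. Band-limiting matters: the preprocessing filter would
  otherwise destroy the planted effect;
* **interregional coupling** — the *same* cluster latent `L` enters a
  remote sphere as `sqrt(1−β²)·noise + β·L`, with per-subject
  `β = slope · TruncNormal(1, 0.35, ≥0)`. Using one latent (rather than
  adding a second β-weighted latent to both spheres) keeps the seed
  sphere's shared-variance fraction exactly `c`: a two-latent
  construction makes local synchrony `c + β²` with β varying across
  subjects, which corrupts the intraregional ground truth and roughly
  doubles its between-subject variance. The one-latent design is also
  the more physiological reading — the remote region receives the seed
  region's coherent signal;
* **clinical link** — patients' THQ = 103.5 + score_link·(β − E[β]) +
  N(0, 50). With the default slope 0.5 and score_link 250 the analytic
  THQ–β correlation is `s·sd_β / sqrt(s²sd_β² + σ²) ≈ 0.87`. SAS/SDS are
  truncated normals below the clinical cut-off of 50; duration is
  log-normal matching a ≈40 ± 34 month cohort;
* **nuisance structure** — linear drift (amplitude 0.5 over the run) and
  three shared band-limited (0.005–0.1 Hz) time courses standing for the
  global, WM and CSF signals (weights 0.3/0.2/0.15), stored in the truth
  manifest so the pipeline's nuisance regression can use them; motion
  files are bounded random walks (step SD 0.05 mm/deg, clipped at
  ±1.5), with an optional planted supra-limit subject to exercise the
  motion screen;
* **demographics** — group-specific distributions matching a typical
  well-matched tinnitus cohort (patients age 40.9 ± 10.5, controls
  46.2 ± 11.9; education ≈11 ± 2 y; GM 581 ± 26 / 576 ± 22 ml; sex
  ≈ 16:13 / 15:15).

What the generator does **not** emulate: slice timing, k-space/scanner
artifacts, physiological cardiac/respiratory cycles, spatially varying
autocorrelation, hemodynamic response shape, or registration error.
Passing validation therefore shows the *statistical chain* is calibrated
and sensitive under its own assumptions — not that it is robust to the
artefact structure of real scanner data.

A side effect worth knowing: global-mean normalisation makes strong
focal synchrony increases appear as diffuse background *decreases* in the
group contrast (patients' global mean rises). The planted-effect tests
therefore score recovery on the positive clusters only.

## Validation experiments and problem sizes

* **Null calibration** — 200 fully re-simulated no-effect cohorts
  (14 + 15 subjects, 16×16×12 grid, 70 volumes) run through the complete
  ReHo group analysis; the family-wise false-positive rate must be
  statistically compatible (95% Wilson interval) with alpha = 0.05.
  Subject and volume counts are deliberately small — the t threshold
  adapts to dof, so calibration does not depend on them — to keep 200
  end-to-end replicates fast. The AlphaSim extent for a given smoothness
  is deterministic, so replicates share one simulation seed and a cache
  keyed on the rounded smoothness estimate.
* **Planted recovery** — 29 + 30 subjects, 20×20×14 grid, 240 volumes,
  coupling 0.5 vs 0.25 in a 9 mm sphere with a β-coupled remote sphere:
  across 20 generator seeds the ReHo contrast must yield a surviving
  positive cluster with Dice > 0.3 against the sphere in ≥ 80% of seeds,
  remote-sphere mean z must beat background (paired one-sided p < 0.01)
  in ≥ 90%, and the THQ correlation sign must be positive in ≥ 90%.

## Numerical choices and degenerate inputs

* Kendall's W returns 0 when every series is constant (undefined rank
  variance); `kendall_w` requires K ≥ 2 and n ≥ 2.
* Pearson maps mark exactly-constant voxel series NaN; a constant seed
  reference raises. Partial correlation returns r = 0 (p = 1) when a
  variable is numerically fully explained by the covariates, rather than
  correlating roundoff noise.
* The smoothness estimator reports FWHM 0 on any axis without positive
  lag-1 correlation; `estimate_fwhm` refuses constant residual maps.
* GLM voxels with zero residual variance give t = 0 if the contrast
  estimate is also 0, otherwise ±inf (flagged, never silently dropped).
* Cluster extraction separates signs before labelling (adjacent positive
  and negative voxels never merge), sorts by extent, and reports the
  max-|t| voxel's mm coordinate via the grid affine (0-based indices
  internally; only mm leaves the package).
* Smoothing treats NaN (out-of-mask fill) as zero and restores it, with
  zero-padding at the volume edge; interior mass is conserved.
* The band-pass requires at least one DFT bin inside the band and errors
  otherwise (guards very short runs).

## Known limitations

* The Monte-Carlo null uses stationary, axis-aligned Gaussian smoothness;
  strongly non-stationary real data would need per-region calibration.
* The voxelwise p / cluster alpha split of the "corrected P < 0.01"
  convention is not uniquely defined in the literature this mirrors;
  both are explicit config parameters (defaults p_voxel = 0.01,
  alpha = 0.05 per AlphaSim custom; set alpha = 0.01 for the stricter
  joint reading).
* ReHo's nuisance regression is off by default (the connectivity branch
  always regresses); a config switch enables it.
* Partial-correlation connectivity, sliding-window connectivity, ICA,
  GRF/TFCE/FDR corrections, slice-timing, realignment and spatial
  normalisation are out of scope.
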