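import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from rehoconn.inference import (Cluster, ClusterCriterion, DesignMatrix,
                                SmoothnessEstimate, StatMap,
                                alphasim_min_extent, build_connectivity_mask,
                                build_design, estimate_fwhm, extract_clusters,
                                glm_contrast_tmap, seeds_from_clusters)
from rehoconn.io import VolumeGrid
from rehoconn.preprocess import fwhm_to_sigma

from _oracles import alphasim_bruteforce, flood_fill_components


def _one_voxel_maps(values):
    """Wrap a per-subject scalar list as (n, 1, 1, 1) maps + mask."""
    arr = np.asarray(values, float)[:, None, None, None]
    return arr, np.ones((1, 1, 1), bool)


class TestGLM:
    def test_identical_groups_give_zero_t(self):
        maps, mask = _one_voxel_maps([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        X = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0]])
        design = DesignMatrix(X, ["intercept", "group"], [0.0, 1.0])
        stat = glm_contrast_tmap(maps, design, mask)
        assert stat.t_values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_pooled_two_sample_t_closed_form(self):
        # groups {1,2,3} vs {3,4,5}: |t| = sqrt(6) = 2.449, dof 4
        maps, mask = _one_voxel_maps([1, 2, 3, 3, 4, 5])
        X = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0]])
        design = DesignMatrix(X, ["intercept", "group"], [0.0, 1.0])
        stat = glm_contrast_tmap(maps, design, mask)
        assert stat.dof == 4
        assert abs(stat.t_values[0, 0, 0]) == pytest.approx(2.449, abs=1e-3)
        assert abs(stat.t_values[0, 0, 0]) == pytest.approx(np.sqrt(6),
                                                            abs=1e-10)

    def test_equals_classical_pooled_t_on_random_maps(self, rng):
        n1, n2 = 9, 11
        maps = rng.standard_normal((n1 + n2, 4, 4, 3))
        mask = np.ones((4, 4, 3), bool)
        X = np.column_stack([np.ones(n1 + n2), [1] * n1 + [0] * n2])
        design = DesignMatrix(X, ["intercept", "group"], [0.0, 1.0])
        stat = glm_contrast_tmap(maps, design, mask)
        t_ref = stats.ttest_ind(maps[:n1], maps[n1:], axis=0).statistic
        assert np.allclose(stat.t_values, t_ref, atol=1e-10)

    def test_degenerate_zero_variance_flagged_infinite(self):
        maps, mask = _one_voxel_maps([2.0, 2.0, 2.0, 2.0])
        design = DesignMatrix(np.ones((4, 1)), ["intercept"], [1.0])
        stat = glm_contrast_tmap(maps, design, mask)
        assert np.isinf(stat.t_values[0, 0, 0])

    def test_covariate_adjustment_removes_confounded_difference(self, rng):
        """A group 'effect' wholly carried by a covariate vanishes when the
        covariate enters the design."""
        n = 40
        group = np.repeat([1.0, 0.0], n // 2)
        age = 30 + 10 * group + rng.normal(0, 0.5, n)
        maps = (2.0 * age)[:, None, None, None] + rng.normal(0, 0.1,
                                                             (n, 1, 1, 1))
        mask = np.ones((1, 1, 1), bool)
        df = pd.DataFrame({"group": np.where(group == 1, "patient", "control"),
                           "age_years": age})
        raw = glm_contrast_tmap(maps, build_design(df, []), mask)
        adj = glm_contrast_tmap(maps, build_design(df, ["age_years"]), mask)
        assert abs(raw.t_values[0, 0, 0]) > 5 * abs(adj.t_values[0, 0, 0])

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(X, ["a", "b"], [0.0, 1.0])


class TestSmoothness:
    @pytest.fixture
    def grid(self):
        return VolumeGrid.centered((24, 24, 18), 3.0)

    def _smoothed_residuals(self, rng, grid, fwhm_mm, n_maps=12):
        sigma = [fwhm_to_sigma(fwhm_mm) / v for v in grid.voxel_size_mm]
        maps = rng.standard_normal((n_maps,) + grid.dims)
        if fwhm_mm > 0:
            maps = np.stack([ndimage.gaussian_filter(m, sigma) for m in maps])
        return maps

    def test_recovers_applied_smoothing(self, rng, grid):
        """Simulation oracle: white noise smoothed at 8 mm (3 mm voxels,
        zero intrinsic width) must estimate close to 8 mm."""
        mask = np.zeros(grid.dims, bool)
        mask[2:-2, 2:-2, 2:-2] = True
        maps = self._smoothed_residuals(rng, grid, 8.0)
        est = estimate_fwhm(maps, grid, mask)
        assert np.allclose(est.fwhm_mm, 8.0, rtol=0.15)

    def test_unsmoothed_noise_estimates_near_zero(self, rng, grid):
        mask = np.zeros(grid.dims, bool)
        mask[2:-2, 2:-2, 2:-2] = True
        est = estimate_fwhm(self._smoothed_residuals(rng, grid, 0.0),
                            grid, mask)
        # below 1.2 voxel widths (3.6 mm at 3 mm voxels)
        assert max(est.fwhm_mm) <= 1.2 * 3.0

    def test_monotone_in_applied_smoothing(self, rng, grid):
        mask = np.zeros(grid.dims, bool)
        mask[2:-2, 2:-2, 2:-2] = True
        widths = [np.mean(estimate_fwhm(
            self._smoothed_residuals(rng, grid, f), grid, mask).fwhm_mm)
            for f in (0.0, 4.0, 8.0)]
        assert widths[0] < widths[1] < widths[2]


class TestAlphaSim:
    def test_alpha_one_gives_extent_one(self):
        mask = np.ones((8, 8, 6), bool)
        crit = ClusterCriterion(p_voxel=0.01, alpha=1.0, n_iterations=50,
                                rng_seed=1)
        est = SmoothnessEstimate((0.0, 0.0, 0.0))
        assert alphasim_min_extent(mask, est, crit) == 1

    def test_single_voxel_mask_analytic(self):
        # P(|z| > z_{0.005}) = 0.01 <= 0.05, so one voxel suffices
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        crit = ClusterCriterion(p_voxel=0.01, alpha=0.05, n_iterations=2000,
                                rng_seed=3)
        est = SmoothnessEstimate((0.0, 0.0, 0.0))
        assert alphasim_min_extent(mask, est, crit) == 1

    def test_matches_independent_simulator_same_seed(self):
        mask = np.zeros((16, 16, 12), bool)
        mask[1:-1, 1:-1, 1:-1] = True
        fwhm = (2.0, 2.0, 2.0)  # voxels == mm here (voxel size 1)
        crit = ClusterCriterion(p_voxel=0.01, alpha=0.05, n_iterations=1000,
                                rng_seed=77)
        got = alphasim_min_extent(mask, SmoothnessEstimate(fwhm), crit,
                                  (1.0, 1.0, 1.0))
        oracle = alphasim_bruteforce(mask, fwhm, (1.0, 1.0, 1.0), 0.01, 0.05,
                                     "two", 26, 1000, 77)
        assert got == oracle

    def test_stable_across_seeds_within_two_voxels(self):
        mask = np.zeros((16, 16, 12), bool)
        mask[1:-1, 1:-1, 1:-1] = True
        est = SmoothnessEstimate((2.0, 2.0, 2.0))
        extents = [alphasim_min_extent(
            mask, est, ClusterCriterion(p_voxel=0.01, alpha=0.05,
                                        n_iterations=1000, rng_seed=s),
            (1.0, 1.0, 1.0)) for s in (1, 2, 3)]
        assert max(extents) - min(extents) <= 2

    def test_monotone_in_alpha_p_and_smoothness(self):
        mask = np.zeros((12, 12, 10), bool)
        mask[1:-1, 1:-1, 1:-1] = True

        def extent(p_voxel, alpha, fwhm):
            crit = ClusterCriterion(p_voxel=p_voxel, alpha=alpha,
                                    n_iterations=600, rng_seed=5)
            return alphasim_min_extent(mask, SmoothnessEstimate((fwhm,) * 3),
                                       crit, (1.0, 1.0, 1.0))

        assert extent(0.01, 0.01, 2.0) >= extent(0.01, 0.05, 2.0)
        assert extent(0.05, 0.05, 2.0) >= extent(0.01, 0.05, 2.0)
        assert extent(0.01, 0.05, 3.0) >= extent(0.01, 0.05, 1.0)


class TestClusterExtraction:
    @pytest.fixture
    def grid(self):
        return VolumeGrid.centered((12, 12, 10), 3.0)

    def test_zero_map_gives_empty_table(self, grid):
        mask = np.ones(grid.dims, bool)
        stat = StatMap(np.zeros(grid.dims), dof=30, mask=mask)
        assert extract_clusters(stat, 0.01, 1, 26, grid) == []

    def test_two_blobs_min_extent_filters_smaller(self, grid):
        mask = np.ones(grid.dims, bool)
        t = np.zeros(grid.dims)
        t[1:2, 1:6, 1:2] = 9.0   # 5 voxels
        t[8:9, 8:11, 8:9] = 9.0  # 3 voxels
        stat = StatMap(t, dof=30, mask=mask)
        clusters = extract_clusters(stat, 0.01, 4, 26, grid)
        assert len(clusters) == 1
        assert clusters[0].n_voxels == 5
        assert clusters[0].sign == 1

    def test_signs_separate_even_when_adjacent(self, grid):
        mask = np.ones(grid.dims, bool)
        t = np.zeros(grid.dims)
        t[4, 4:7, 4] = 9.0
        t[5, 4:7, 4] = -9.0
        stat = StatMap(t, dof=30, mask=mask)
        clusters = extract_clusters(stat, 0.01, 1, 26, grid)
        assert sorted(c.sign for c in clusters) == [-1, 1]

    def test_membership_matches_flood_fill_oracle(self, rng, grid):
        mask = np.ones(grid.dims, bool)
        t = rng.standard_normal(grid.dims) * 2.0
        dof = 40
        stat = StatMap(t, dof=dof, mask=mask)
        clusters = extract_clusters(stat, 0.05, 1, 26, grid)
        thr = stats.t.ppf(1 - 0.05 / 2, dof)
        expected = set()
        for sign in (1, -1):
            for comp in flood_fill_components((sign * t > thr) & mask, 26):
                expected.add(comp)
        got = {frozenset(map(tuple, c.voxel_indices)) for c in clusters}
        assert got == expected

    def test_peak_is_max_abs_t_within_cluster(self, rng, grid):
        mask = np.ones(grid.dims, bool)
        t = np.zeros(grid.dims)
        t[3:6, 3:6, 3:6] = rng.uniform(3.0, 6.0, (3, 3, 3))
        stat = StatMap(t, dof=30, mask=mask)
        (c,) = extract_clusters(stat, 0.01, 1, 26, grid)
        assert c.peak_t == pytest.approx(t[3:6, 3:6, 3:6].max())


class TestSeedsAndMasks:
    def _cluster(self, cid, sign, vox):
        vox = np.asarray(vox)
        return Cluster(cluster_id=cid, n_voxels=len(vox), peak_t=3.0 * sign,
                       peak_mm=(0, 0, 0), voxel_indices=vox, sign=sign)

    def test_four_positive_one_negative_gives_four_seeds(self):
        clusters = [self._cluster(i, 1, [[i, 0, 0]]) for i in range(1, 5)]
        clusters.append(self._cluster(5, -1, [[9, 9, 9]]))
        seeds = seeds_from_clusters(clusters)
        assert len(seeds) == 4
        assert all(s.source == "reho_cluster" for s in seeds)

    def test_empty_clusters_give_empty_seed_list(self):
        assert seeds_from_clusters([]) == []

    def test_seed_voxel_sets_disjoint(self):
        clusters = [self._cluster(1, 1, [[1, 1, 1], [1, 1, 2]]),
                    self._cluster(2, 1, [[5, 5, 5]])]
        seeds = seeds_from_clusters(clusters)
        sets = [set(map(tuple, s.voxel_indices)) for s in seeds]
        assert sets[0].isdisjoint(sets[1])

    def test_connectivity_mask_is_union_of_group_masks(self, rng):
        grid = VolumeGrid.centered((10, 10, 8), 3.0)
        mask = np.ones(grid.dims, bool)
        t1 = np.zeros(grid.dims)
        t1[1:4, 1:4, 1:4] = 9.0
        t2 = np.zeros(grid.dims)
        t2[6:9, 6:9, 5:7] = 9.0
        s1 = StatMap(t1, dof=28, mask=mask)
        s2 = StatMap(t2, dof=28, mask=mask)
        union = build_connectivity_mask([s1, s2], 0.01, 1, 26, grid)
        assert union.sum() == 27 + 18
        same = build_connectivity_mask([s1, s1], 0.01, 1, 26, grid)
        assert same.sum() == 27
        empty = build_connectivity_mask(
            [StatMap(np.zeros(grid.dims), dof=28, mask=mask)], 0.01, 1, 26,
            grid)
        assert not empty.any()
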