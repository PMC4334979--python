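import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from rehoconn.io import load_series, read_motion_params
from rehoconn.synthetic import (CohortSpec, PlantedEffect, generate_cohort,
                                sphere_voxels, write_fixtures)


def _null_spec(**kwargs):
    defaults = dict(n_group_a=3, n_group_b=3, grid_dims=(12, 12, 10),
                    n_volumes=60, mask_radius_mm=15.0, rng_seed=7)
    defaults.update(kwargs)
    return CohortSpec(**defaults)


class TestReproducibility:
    def test_identical_spec_and_seed_bit_identical(self):
        a = generate_cohort(_null_spec())
        b = generate_cohort(_null_spec())
        for sid in a.series:
            assert np.array_equal(a.series[sid].data, b.series[sid].data)
            assert np.array_equal(a.motion[sid], b.motion[sid])
        assert pd.DataFrame(a.subject_table()).equals(b.subject_table())

    def test_different_seed_differs(self):
        a = generate_cohort(_null_spec())
        b = generate_cohort(_null_spec(rng_seed=8))
        assert not np.array_equal(a.series["sub001"].data,
                                  b.series["sub001"].data)


def _isolated_spec(**kwargs):
    """Spec with drift and shared nuisance signals off, so within-sphere
    correlations reflect the planted coupling alone."""
    defaults = dict(drift_amplitude=0.0, global_signal_weight=0.0,
                    tissue_signal_weights=(0.0, 0.0))
    defaults.update(kwargs)
    return _null_spec(**defaults)


class TestPlantedCouplings:
    def _sphere_pair_corr(self, cohort, sid):
        eff = cohort.truth["effects"][0]
        vox = np.asarray(eff["sphere_voxels"])
        data = cohort.series[sid].data[vox[:, 0], vox[:, 1], vox[:, 2], :]
        c = np.corrcoef(data)
        iu = np.triu_indices(len(vox), 1)
        return c[iu]

    def test_null_couplings_give_near_zero_pair_correlation(self):
        effect = PlantedEffect(center_mm=(0, 0, 0), radius_mm=6.0,
                               local_coupling_a=0.0, local_coupling_b=0.0)
        spec = _isolated_spec(planted_effects=(effect,), n_volumes=120)
        cohort = generate_cohort(spec)
        rs = np.concatenate([self._sphere_pair_corr(cohort, s.subject_id)
                             for s in cohort.subjects])
        # individual |r| can reach ~3/sqrt(n); the mean must be tighter
        assert abs(rs.mean()) < 3 / np.sqrt(120)

    def test_coupling_half_matches_simulation_oracle(self):
        """Planted c = 0.5 -> mean pairwise correlation ~= 0.5, within the
        Monte-Carlo error of an independent two-series oracle."""
        rng = np.random.default_rng(11)
        # oracle: simulate 100 independent pairs sharing half their variance
        oracle_rs = []
        for _ in range(100):
            latent = rng.standard_normal(120)
            x = np.sqrt(0.5) * rng.standard_normal(120) + np.sqrt(0.5) * latent
            y = np.sqrt(0.5) * rng.standard_normal(120) + np.sqrt(0.5) * latent
            oracle_rs.append(np.corrcoef(x, y)[0, 1])
        oracle_mean = np.mean(oracle_rs)
        oracle_sem = np.std(oracle_rs) / np.sqrt(len(oracle_rs))

        effect = PlantedEffect(center_mm=(0, 0, 0), radius_mm=6.0,
                               local_coupling_a=0.5, local_coupling_b=0.5)
        cohort = generate_cohort(_isolated_spec(planted_effects=(effect,),
                                                n_volumes=120))
        rs = np.concatenate([self._sphere_pair_corr(cohort, s.subject_id)
                             for s in cohort.subjects])
        assert rs.mean() == pytest.approx(oracle_mean, abs=6 * oracle_sem)
        assert rs.mean() == pytest.approx(0.5, abs=0.05)

    def test_sphere_outside_mask_rejected(self):
        effect = PlantedEffect(center_mm=(40, 0, 0), radius_mm=5.0)
        with pytest.raises(ValueError, match="outside the mask"):
            generate_cohort(_null_spec(planted_effects=(effect,)))

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError, match="dummy"):
            _null_spec(n_volumes=10)


class TestClinicalLink:
    def test_thq_correlates_with_true_coupling_at_analytic_level(self):
        """r(THQ, beta) should approach
        s*sd_beta / sqrt(s^2 sd_beta^2 + sigma^2)."""
        effect = PlantedEffect(center_mm=(-6, 6, 0), radius_mm=6.0,
                               local_coupling_a=0.4, local_coupling_b=0.1,
                               remote_center_mm=(9, -9, 0),
                               remote_radius_mm=5.0,
                               connectivity_slope=0.5, score_link=250.0)
        spec = _null_spec(n_group_a=60, n_group_b=2, grid_dims=(14, 14, 10),
                          mask_radius_mm=18.0, planted_effects=(effect,),
                          rng_seed=5)
        cohort = generate_cohort(spec)
        df = cohort.subject_table()
        patients = df[df["group"] == "patient"]
        r = np.corrcoef(patients["true_coupling"], patients["thq"])[0, 1]
        sd_beta = 0.5 * 0.35
        expected = 250.0 * sd_beta / np.hypot(250.0 * sd_beta, 50.0)
        # Fisher-z 95% interval at n = 60
        z_half = 1.96 / np.sqrt(60 - 3)
        assert abs(np.arctanh(r) - np.arctanh(expected)) < 1.5 * z_half
        assert r > 0

    def test_scores_only_for_patients(self):
        cohort = generate_cohort(_null_spec())
        df = cohort.subject_table()
        assert df.loc[df["group"] == "patient", ["thq", "sas", "sds"]].notna().all().all()
        assert df.loc[df["group"] == "control", "thq"].isna().all()


class TestStructure:
    def test_series_finite_and_mask_inside_grid(self):
        cohort = generate_cohort(_null_spec())
        for s in cohort.series.values():
            assert np.isfinite(s.data[s.mask]).all()
        border = np.zeros(cohort.mask.shape, bool)
        border[[0, -1], :, :] = True
        border[:, [0, -1], :] = True
        border[:, :, [0, -1]] = True
        assert not (cohort.mask & border).any()

    def test_motion_outlier_planted_on_request(self):
        cohort = generate_cohort(_null_spec(plant_motion_outlier=True))
        sid = cohort.truth["motion_outlier"]
        assert np.abs(cohort.motion[sid][:, :3]).max() > 2.0
        others = [np.abs(m[:, :3]).max() for s, m in cohort.motion.items()
                  if s != sid]
        assert max(others) <= 1.5


class TestFixtures:
    def test_round_trip_arrays_equal(self, tmp_path):
        cohort = generate_cohort(_null_spec())
        manifest = write_fixtures(cohort, tmp_path)
        assert len(manifest["subjects"]) == 6
        entry = manifest["subjects"][0]
        loaded = load_series(tmp_path / entry["bold"],
                             tmp_path / manifest["mask"],
                             tr_s=manifest["tr_s"])
        orig = cohort.series[entry["subject_id"]]
        assert np.allclose(loaded.data, orig.data, atol=1e-5)  # float32 file
        assert np.array_equal(loaded.mask, orig.mask)
        mot = read_motion_params(tmp_path / entry["motion"])
        assert np.allclose(mot, cohort.motion[entry["subject_id"]], atol=1e-6)

    def test_one_motion_file_per_subject(self, tmp_path):
        cohort = generate_cohort(_null_spec())
        manifest = write_fixtures(cohort, tmp_path)
        ids = [e["subject_id"] for e in manifest["subjects"]]
        assert sorted(ids) == sorted(s.subject_id for s in cohort.subjects)
        assert all((tmp_path / e["motion"]).exists()
                   for e in manifest["subjects"])

    def test_truth_sphere_counts_match_bruteforce_rasterization(self, tmp_path):
        effect = PlantedEffect(center_mm=(0, 0, 0), radius_mm=6.0,
                               local_coupling_a=0.3, local_coupling_b=0.1)
        cohort = generate_cohort(_null_spec(planted_effects=(effect,)))
        write_fixtures(cohort, tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        listed = {tuple(v) for v in truth["effects"][0]["sphere_voxels"]}
        # brute force: check the distance of every voxel centre
        grid = cohort.grid
        expected = set()
        for vox in np.ndindex(*grid.dims):
            mm = grid.voxel_to_mm(np.array(vox))
            if float(np.sum(mm ** 2)) <= 6.0 ** 2:
                expected.add(vox)
        assert listed == expected
        assert listed == {tuple(v)
                          for v in sphere_voxels(grid, (0, 0, 0), 6.0)}
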