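import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedgc import mapstats, synth
from seedgc.types import (
    AlphaSimParams,
    GroupDesign,
    SmoothnessEstimate,
    StatMap,
    TfceParams,
    default_affine,
)

MASK8 = np.ones((8, 8, 8), bool)


def _design(n1, n2, covariates=None):
    ids = [f"s{i}" for i in range(n1 + n2)]
    groups = np.array(["g1"] * n1 + ["g2"] * n2)
    return GroupDesign(ids, groups, covariates)


class TestGlmTmap:
    def test_identical_groups_give_zero_t(self):
        maps = np.tile(np.arange(64.0).reshape(4, 4, 4), (10, 1, 1, 1))
        stat, _ = mapstats.glm_tmap(maps, _design(5, 5))
        np.testing.assert_allclose(stat.t, 0.0)

    def test_two_sample_matches_pooled_formula(self):
        """No-covariate two-group t equals the textbook pooled formula."""
        g1 = np.array([1.1, 2.3, 0.7, 1.9, 2.8, 1.5])
        g2 = np.array([2.4, 3.1, 2.0, 3.6, 2.9, 2.2])
        maps = np.concatenate([g1, g2]).reshape(12, 1, 1, 1)
        stat, _ = mapstats.glm_tmap(maps, _design(6, 6))
        sp = np.sqrt((g1.var(ddof=1) * 5 + g2.var(ddof=1) * 5) / 10)
        oracle = (g1.mean() - g2.mean()) / (sp * np.sqrt(1 / 6 + 1 / 6))
        assert stat.t[0, 0, 0] == pytest.approx(oracle, abs=1e-12)
        assert stat.t[0, 0, 0] == pytest.approx(-2.4460490027013684, abs=1e-12)
        assert stat.df == 10

    def test_one_sample_equals_t_formula(self, rng):
        maps = rng.standard_normal((8, 3, 3, 3))
        stat, _ = mapstats.glm_tmap(maps, None)
        v = maps[:, 1, 1, 1]
        oracle = v.mean() / (v.std(ddof=1) / np.sqrt(8))
        assert stat.t[1, 1, 1] == pytest.approx(oracle, rel=1e-12)
        assert stat.df == 7

    def test_covariate_collinear_with_group_raises_named_error(self, rng):
        cov = pd.DataFrame({"age": [1.0] * 4 + [2.0] * 4})  # = group indicator
        maps = rng.standard_normal((8, 2, 2, 2))
        with pytest.raises(ValueError, match="age"):
            mapstats.glm_tmap(maps, _design(4, 4, cov))

    def test_residuals_returned_for_smoothness(self, rng):
        maps = rng.standard_normal((10, 4, 4, 4))
        _, resid = mapstats.glm_tmap(maps, _design(5, 5))
        assert resid.shape == (10, 4, 4, 4)
        # residuals orthogonal to the design columns
        assert abs(resid.sum(axis=0)).max() < 1e-8


class TestSmoothness:
    def test_white_noise_intrinsic_sqrt2_voxels(self):
        rng = np.random.default_rng(21)
        resid = rng.standard_normal((4, 32, 32, 32))
        est = mapstats.estimate_smoothness(resid, np.ones((32, 32, 32), bool), (3, 3, 3))
        np.testing.assert_allclose(est.fwhm_mm, np.sqrt(2) * 3.0, rtol=0.10)

    def test_smoothing_increases_estimate(self):
        rng = np.random.default_rng(22)
        from seedgc.preprocess import smooth_gaussian

        white = rng.standard_normal((4, 24, 24, 24))
        smooth = np.stack([smooth_gaussian(w, 6.0, (3, 3, 3)) for w in white])
        mask = np.ones((24, 24, 24), bool)
        e_white = mapstats.estimate_smoothness(white, mask, (3, 3, 3))
        e_smooth = mapstats.estimate_smoothness(smooth, mask, (3, 3, 3))
        assert np.all(e_smooth.fwhm_mm > e_white.fwhm_mm)

    def test_constant_maps_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mapstats.estimate_smoothness(
                np.ones((3, 8, 8, 8)), MASK8, (3, 3, 3)
            )

    def test_kernel_inversion_roundtrip(self):
        """The MC smoothing kernel reproduces the requested estimated FWHM."""
        rng = np.random.default_rng(23)
        from scipy import ndimage

        target = 8.0
        sigma = mapstats._kernel_sigma_vox(target, (3.0, 3.0, 3.0))
        # enough maps that the per-voxel variance standardization is stable
        fields = np.stack(
            [
                ndimage.gaussian_filter(rng.standard_normal((40, 40, 40)), sigma, mode="constant")
                for _ in range(30)
            ]
        )
        est = mapstats.estimate_smoothness(fields, np.ones((40, 40, 40), bool), (3, 3, 3))
        assert est.geometric_mean == pytest.approx(target, rel=0.12)


class TestAlphaSim:
    def test_deterministic_given_seed(self):
        p = AlphaSimParams(n_iterations=200, rng_seed=9)
        mask = np.ones((12, 12, 12), bool)
        k1 = mapstats.alphasim_threshold(mask, 6.0, p, (3, 3, 3))
        k2 = mapstats.alphasim_threshold(mask, 6.0, p, (3, 3, 3))
        assert k1 == k2

    def test_threshold_monotone_in_smoothness(self):
        mask = np.ones((16, 16, 16), bool)
        p = AlphaSimParams(n_iterations=300, rng_seed=4)
        k_small = mapstats.alphasim_threshold(mask, 4.5, p, (3, 3, 3))
        k_large = mapstats.alphasim_threshold(mask, 9.0, p, (3, 3, 3))
        assert k_large >= k_small

    def test_unattainable_cluster_p_reports_floor(self):
        p = AlphaSimParams(cluster_p=0.001, n_iterations=100, rng_seed=1)
        with pytest.raises(ValueError, match="floor"):
            mapstats.alphasim_threshold(np.ones((8, 8, 8), bool), 6.0, p, (3, 3, 3))


class TestClusterTable:
    def _blob_stat(self, sign=1):
        t = np.zeros((12, 12, 12))
        blob = np.zeros_like(t, bool)
        blob[2:5, 2:5, 2:5] = True  # 27 voxels
        blob[5, 2, 2] = blob[5, 3, 2] = blob[5, 2, 3] = True  # 30 total
        t[blob] = sign * 5.0
        t[3, 3, 3] = sign * 8.0
        return StatMap(t, 20, np.ones_like(t, bool), default_affine((3, 3, 3)))

    def test_constructed_blob_found_with_peak(self):
        table = mapstats.cluster_table(self._blob_stat(), 0.001, min_extent=22)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.size_voxels == 30
        assert (row.peak_i, row.peak_j, row.peak_k) == (3, 3, 3)
        assert row.peak_t == pytest.approx(8.0)
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == (9.0, 9.0, 9.0)

    def test_min_extent_50_drops_blob(self):
        table = mapstats.cluster_table(self._blob_stat(), 0.001, min_extent=50)
        assert len(table) == 0

    def test_negative_blob_reported_with_sign(self):
        table = mapstats.cluster_table(self._blob_stat(sign=-1), 0.001, min_extent=22)
        assert len(table) == 1
        assert table.iloc[0].sign == -1
        assert table.iloc[0].peak_t == pytest.approx(-8.0)

    def test_invariant_to_discovery_order(self):
        """Two separated blobs: cluster set identical however labeled."""
        t = np.zeros((14, 14, 14))
        t[1:4, 1:4, 1:4] = 6.0
        t[9:13, 9:13, 9:13] = -5.0
        stat = StatMap(t, 20, np.ones_like(t, bool), default_affine((3, 3, 3)))
        table = mapstats.cluster_table(stat, 0.001, min_extent=1)
        got = {(int(r.size_voxels), int(r.sign)) for _, r in table.iterrows()}
        assert got == {(27, 1), (64, -1)}


class TestTfceTransform:
    def test_zero_map_zero_output(self):
        out = mapstats.tfce_transform(np.zeros((8, 8, 8)), MASK8)
        np.testing.assert_array_equal(out, 0.0)

    def test_single_voxel_analytic_value(self):
        """Isolated voxel of height 3 with H=2, E=0.5: integral of h^2 over
        (0, 3] = 9; the midpoint rule at 100 steps is within its error bound."""
        m = np.zeros((9, 9, 9))
        m[4, 4, 4] = 3.0
        out = mapstats.tfce_transform(m, np.ones((9, 9, 9), bool), TfceParams())
        dh = 3.0 / 100
        bound = 100 * dh**3 / 24 * 2  # midpoint-rule bound for f'' = 2
        assert abs(out[4, 4, 4] - 9.0) <= bound + 1e-12

    def test_monotone_under_scaling(self, rng):
        m = rng.standard_normal((8, 8, 8))
        out1 = mapstats.tfce_transform(m, MASK8)
        out2 = mapstats.tfce_transform(2 * m, MASK8)
        assert np.all(np.abs(out2) >= np.abs(out1) - 1e-12)

    def test_negative_part_antisymmetric(self, rng):
        m = rng.standard_normal((8, 8, 8))
        out = mapstats.tfce_transform(m, MASK8)
        out_neg = mapstats.tfce_transform(-m, MASK8)
        np.testing.assert_allclose(out, -out_neg, atol=1e-12)


class TestTfcePermutation:
    def test_identical_maps_all_p_one(self):
        base = np.random.default_rng(1).standard_normal((6, 6, 6))
        maps = np.stack([base] * 12)
        res = mapstats.tfce_permutation_test(
            maps, _design(6, 6), TfceParams(n_steps=20, n_permutations=50, rng_seed=0)
        )
        np.testing.assert_allclose(res.p, 1.0)

    def test_exhaustive_enumeration_reported(self, rng):
        maps = rng.standard_normal((6, 5, 5, 5))
        res = mapstats.tfce_permutation_test(
            maps, _design(3, 3), TfceParams(n_steps=15, n_permutations=500, rng_seed=0)
        )
        assert res.exhaustive
        assert res.n_permutations == 20  # C(6, 3)

    def test_deterministic_given_seed(self, rng):
        maps = rng.standard_normal((10, 6, 6, 6))
        params = TfceParams(n_steps=15, n_permutations=60, rng_seed=5)
        r1 = mapstats.tfce_permutation_test(maps, _design(5, 5), params)
        r2 = mapstats.tfce_permutation_test(maps, _design(5, 5), params)
        np.testing.assert_array_equal(r1.p, r2.p)

    def test_power_on_planted_effect(self):
        """Cohen's d ~ 1.5 over a 27-voxel region, 12 vs 12: detected at
        FWE 0.05 in nearly all replicates."""
        rng = np.random.default_rng(77)
        region = np.zeros((16, 16, 16), bool)
        region[6:9, 6:9, 6:9] = True
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            maps = synth.simulate_null_maps(24, smooth_fwhm_mm=0.0, rng=rng)
            maps[:12][:, region] += 1.5  # unit-variance maps: shift = d
            res = mapstats.tfce_permutation_test(
                maps,
                _design(12, 12),
                TfceParams(n_steps=25, n_permutations=100, rng_seed=rep),
            )
            hits += int((res.p[region] <= 0.05).any())
        assert hits >= int(0.9 * n_rep)
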