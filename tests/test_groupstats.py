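"""Voxelwise group inference: GLM maps, Z conversion, clusters, ROIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from vmhcpipe.groupstats import (
    StatMap,
    ancova_f_map,
    estimate_smoothness,
    extract_sphere_mean,
    find_peak,
    grf_cluster_correct,
    label_clusters,
    one_sample_group_map,
    permutation_cluster_null,
    permutation_cluster_p,
    posthoc_bonferroni,
    sphere_voxels,
    stat_to_z,
    two_sample_t_map,
)

AFFINE3 = np.diag([3.0, 3.0, 3.0, 1.0])


class TestOneSampleMap:
    def test_null_maps_survive_nowhere(self, rng):
        maps = rng.normal(0, 0.01, size=(10, 8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        _, clusters = one_sample_group_map(maps, mask, AFFINE3)
        assert clusters.clusters == []

    def test_strong_region_survives(self, rng):
        """Effect size ~3.3 per voxel at n=20 survives FDR and extent."""
        maps = rng.normal(0, 0.3, size=(20, 10, 10, 10))
        maps[:, 2:7, 2:7, 2:6] += 1.0  # 100-voxel region, mean z = 1
        mask = np.ones((10, 10, 10), bool)
        _, clusters = one_sample_group_map(maps, mask, AFFINE3)
        assert sum(c.size_voxels for c in clusters.clusters) >= 100

    def test_extent_filter_removes_small_components(self, rng):
        maps = rng.normal(0, 0.05, size=(12, 12, 12, 12))
        maps[:, 2:5, 2:5, 2:4] += 2.0  # 18-voxel component < 20 extent
        mask = np.ones((12, 12, 12), bool)
        _, clusters = one_sample_group_map(maps, mask, AFFINE3,
                                           min_extent=20)
        assert clusters.clusters == []
        _, clusters19 = one_sample_group_map(maps, mask, AFFINE3,
                                             min_extent=18)
        assert clusters19.clusters != []

    def test_too_few_maps_error(self, rng):
        with pytest.raises(ValueError):
            one_sample_group_map(rng.normal(size=(2, 4, 4, 4)),
                                 np.ones((4, 4, 4), bool), AFFINE3)


class TestAncova:
    def test_matches_brute_force_oracle(self):
        from vmhcpipe.validation import ancova_oracle_max_diff

        assert ancova_oracle_max_diff(0, n_instances=30) < 1e-8

    def test_type_one_error_calibrated(self):
        from vmhcpipe.validation import ancova_type_one_rate

        rate = ancova_type_one_rate(0, n_voxels=2000)
        assert 0.03 <= rate <= 0.07

    def test_zero_covariate_reduces_to_plain_anova(self, rng):
        groups = np.array(["AVH"] * 5 + ["NonAVH"] * 5 + ["Control"] * 5)
        y = rng.normal(size=(15, 40, 1, 1))
        mask = np.ones((40, 1, 1), bool)
        fmap, _ = ancova_f_map(y, groups, np.zeros(15), mask)
        assert fmap.df == (2, 12)  # df2 = n - 3 when the covariate drops
        ref = stats.f_oneway(y[:5, :, 0, 0], y[5:10, :, 0, 0], y[10:, :, 0, 0])
        assert np.allclose(fmap.values[:, 0, 0], ref.statistic, atol=1e-10)

    def test_f_equals_squared_adjusted_t_for_two_groups(self, rng):
        groups = np.array(["AVH"] * 7 + ["Control"] * 8)
        y = rng.normal(size=(15, 30, 1, 1))
        cov = rng.normal(size=15)
        mask = np.ones((30, 1, 1), bool)
        fmap, _ = ancova_f_map(y, groups, cov, mask)
        tmap, _ = two_sample_t_map(y[:7], y[7:], cov, mask)
        assert np.allclose(fmap.values, tmap.values**2, atol=1e-9)
        assert fmap.df[1] == tmap.df[0]

    def test_small_group_rejected(self, rng):
        groups = np.array(["AVH"] * 1 + ["NonAVH"] * 4 + ["Control"] * 4)
        with pytest.raises(ValueError, match="AVH"):
            ancova_f_map(rng.normal(size=(9, 2, 2, 2)), groups,
                         np.zeros(9), np.ones((2, 2, 2), bool))


class TestTwoSampleMap:
    def test_identical_groups_give_zero_t(self, rng):
        a = rng.normal(size=(4, 5, 5, 5))
        maps = np.concatenate([a, a])
        mask = np.ones((5, 5, 5), bool)
        tmap, _ = two_sample_t_map(maps[:4], maps[4:], None, mask)
        assert np.allclose(tmap.values, 0.0, atol=1e-10)

    def test_swapping_groups_negates_t(self, rng):
        a = rng.normal(size=(5, 4, 4, 4))
        b = rng.normal(size=(6, 4, 4, 4))
        cov = rng.normal(size=11)
        mask = np.ones((4, 4, 4), bool)
        t_ab, _ = two_sample_t_map(a, b, cov, mask)
        cov_swapped = np.concatenate([cov[5:], cov[:5]])
        t_ba, _ = two_sample_t_map(b, a, cov_swapped, mask)
        assert np.allclose(t_ab.values, -t_ba.values, atol=1e-10)

    def test_planted_difference_detected_after_correction(self, rng):
        """Mean shift 0.5 at sd 0.3 with n = 18 + 20 is near-certain power."""
        shape = (12, 12, 10)
        a = rng.normal(0, 0.3, size=(18,) + shape)
        b = rng.normal(0, 0.3, size=(20,) + shape)
        a[:, 4:8, 4:8, 3:7] += 0.5
        mask = np.ones(shape, bool)
        tmap, resid = two_sample_t_map(a, b, None, mask)
        tz = stat_to_z(tmap)
        sm = estimate_smoothness(resid, mask, (3.0,) * 3)
        res = grf_cluster_correct(tz, mask, AFFINE3, sm)
        assert res.clusters and res.clusters[0].size_voxels >= 30


class TestStatToZ:
    def test_t_zero_maps_to_zero(self):
        out = stat_to_z(StatMap(values=np.zeros((2, 2, 2)), kind="t", df=(10,)))
        assert np.allclose(out.values, 0.0)

    def test_f_at_upper_tail_0107_gives_z_23(self):
        """The forming threshold Z = 2.3 corresponds to upper-tail p = 0.0107."""
        p = stats.norm.sf(2.3)
        for df in [(2, 50), (1, 30), (5, 12)]:
            f_val = stats.f.isf(p, *df)
            out = stat_to_z(StatMap(values=np.array([[[f_val]]]), kind="F",
                                    df=df))
            assert np.isclose(out.values[0, 0, 0], 2.3, atol=1e-6)
        assert np.isclose(stats.norm.isf(0.0107), 2.3, atol=5e-3)

    def test_monotone_in_f(self):
        vals = np.array([[[0.5, 1.0, 2.0, 4.0, 8.0]]])
        out = stat_to_z(StatMap(values=vals, kind="F", df=(2, 50)))
        assert np.all(np.diff(out.values.ravel()) > 0)

    def test_t_sign_preserved(self):
        vals = np.array([[[-3.0, -1.0, 0.0, 1.0, 3.0]]])
        out = stat_to_z(StatMap(values=vals, kind="t", df=(20,)))
        assert np.all(np.sign(out.values) == np.sign(vals))

    def test_extreme_values_stay_finite(self):
        out = stat_to_z(StatMap(values=np.array([[[1e5]]]), kind="F",
                                df=(2, 50)))
        assert np.isfinite(out.values).all()


class TestSmoothness:
    def test_known_kernel_recovered_within_15_percent(self):
        voxel = 3.0
        sigma = 6.0 / 2.3548 / voxel
        ests = []
        for s in range(50):
            r = np.random.default_rng(700 + s).standard_normal((8, 22, 22, 22))
            r = gaussian_filter(r, (0, sigma, sigma, sigma), mode="wrap")
            fw, _ = estimate_smoothness(r, np.ones((22, 22, 22), bool),
                                        (voxel,) * 3)
            ests.append(fw.mean())
        assert abs(np.mean(ests) - 6.0) / 6.0 < 0.15

    def test_unsmoothed_noise_below_voxel_scale(self, rng):
        r = rng.standard_normal((8, 16, 16, 16))
        fw, _ = estimate_smoothness(r, np.ones((16, 16, 16), bool), (3.0,) * 3)
        assert np.all(fw <= 1.5 * 3.0)

    def test_resels_double_with_mask_volume(self, rng):
        r = gaussian_filter(rng.standard_normal((6, 24, 12, 12)),
                            (0, 1.2, 1.2, 1.2), mode="wrap")
        full = np.ones((24, 12, 12), bool)
        half = full.copy()
        half[12:] = False
        # fix the smoothness: compare resels at identical per-axis FWHM
        fw_full, res_full = estimate_smoothness(r, full, (3.0,) * 3)
        fw_half, res_half = estimate_smoothness(r, half, (3.0,) * 3)
        implied_full = res_half * full.sum() / half.sum() * np.prod(fw_half / fw_full)
        assert np.isclose(res_full, implied_full, rtol=1e-6)

    def test_too_few_maps_error(self, rng):
        with pytest.raises(ValueError):
            estimate_smoothness(rng.normal(size=(1, 8, 8, 8)),
                                np.ones((8, 8, 8), bool), (3.0,) * 3)


class TestGrfAndPermutation:
    def test_empty_suprathreshold_is_empty_result(self):
        z = StatMap(values=np.zeros((6, 6, 6)), kind="Z")
        res = grf_cluster_correct(z, np.ones((6, 6, 6), bool), AFFINE3,
                                  (np.array([6.0] * 3), 50.0))
        assert res.clusters == []

    def test_permutation_deterministic_under_seed(self, rng):
        maps = rng.normal(size=(12, 8, 8, 6))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        mask = np.ones((8, 8, 6), bool)
        n1 = permutation_cluster_null(maps, groups, None, mask, 100, seed=9,
                                      stat="two_sample")
        n2 = permutation_cluster_null(maps, groups, None, mask, 100, seed=9,
                                      stat="two_sample")
        assert np.array_equal(n1, n2)

    def test_planted_effect_beats_permutation_null(self, rng):
        shape = (10, 10, 8)
        sigma = 8.0 / 2.3548 / 3.0
        maps = gaussian_filter(rng.standard_normal((20,) + shape),
                               (0, sigma, sigma, sigma), mode="reflect")
        maps[:10, 3:7, 3:7, 2:6] += 1.0
        groups = np.array(["a"] * 10 + ["b"] * 10)
        mask = np.ones(shape, bool)
        tmap, _ = two_sample_t_map(maps[:10], maps[10:], None, mask)
        tz = stat_to_z(tmap)
        supra = tz.values > 2.3
        observed = label_clusters(supra, tz.values, AFFINE3)
        obs_max = max(c.size_voxels for c in observed.clusters)
        null = permutation_cluster_null(maps, groups, None, mask, 200,
                                        seed=3, stat="two_sample")
        assert permutation_cluster_p(null, obs_max) < 0.05


class TestPeaksAndSpheres:
    def test_single_voxel_cluster_is_its_own_peak(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 3, 1] = True
        stat = np.zeros((5, 5, 5))
        stat[2, 3, 1] = 4.2
        vox, mm, val = find_peak(m, stat, AFFINE3)
        assert vox == (2, 3, 1) and val == 4.2
        assert mm == (6.0, 9.0, 3.0)

    def test_tied_maxima_take_smallest_linear_index(self):
        m = np.ones((2, 2, 2), bool)
        stat = np.full((2, 2, 2), 1.0)
        vox, _, _ = find_peak(m, stat, AFFINE3)
        assert vox == (0, 0, 0)

    def test_sphere_contains_19_voxels_on_3mm_grid(self):
        mask = sphere_voxels((0.0, 0.0, 0.0), 5.0, (9, 9, 9),
                             np.array([[3, 0, 0, -12], [0, 3, 0, -12],
                                       [0, 0, 3, -12], [0, 0, 0, 1]], float))
        assert mask.sum() == 19

    def test_constant_map_returns_constant(self):
        z = np.full((9, 9, 9), 0.37)
        aff = np.array([[3, 0, 0, -12], [0, 3, 0, -12], [0, 0, 3, -12],
                        [0, 0, 0, 1]], float)
        assert np.isclose(extract_sphere_mean(z, (0, 0, 0), aff, 5.0), 0.37)

    def test_linear_gradient_mean_equals_center_value(self):
        """The 19-voxel offset set is symmetric, so a linear field averages
        to its central value."""
        aff = np.array([[3, 0, 0, -12], [0, 3, 0, -12], [0, 0, 3, -12],
                        [0, 0, 0, 1]], float)
        ii = np.arange(9)
        z = (0.5 * (3 * ii[:, None, None] - 12)
             + 0.25 * (3 * ii[None, :, None] - 12)
             - 0.1 * (3 * ii[None, None, :] - 12))
        assert np.isclose(extract_sphere_mean(z, (0, 0, 0), aff, 5.0), 0.0)

    def test_empty_sphere_errors(self):
        with pytest.raises(ValueError):
            extract_sphere_mean(np.zeros((4, 4, 4)), (500, 0, 0), AFFINE3, 5.0)


class TestPosthoc:
    def test_identical_groups_capped_at_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["Control", "NonAVH", "AVH"], 4)
        out = posthoc_bonferroni(vals, groups)
        assert np.allclose(out["p_bonferroni"], 1.0)

    def test_matches_pooled_variance_textbook_computation(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=15)
        groups = np.repeat(["Control", "NonAVH", "AVH"], 5)
        out = posthoc_bonferroni(vals, groups).set_index(["group_a", "group_b"])
        means = {g: vals[groups == g].mean() for g in np.unique(groups)}
        ssw = sum(((vals[groups == g] - means[g]) ** 2).sum()
                  for g in np.unique(groups))
        msw = ssw / 12
        t = (means["Control"] - means["AVH"]) / np.sqrt(msw * (2 / 5))
        p = 2 * stats.t.sf(abs(t), 12)
        row = out.loc[("Control", "AVH")]
        assert np.isclose(row["t"], t, atol=1e-8)
        assert np.isclose(row["p_bonferroni"], min(3 * p, 1.0), atol=1e-8)

    def test_correction_never_below_uncorrected(self, rng):
        vals = rng.normal(size=18)
        groups = np.repeat(["Control", "NonAVH", "AVH"], 6)
        out = posthoc_bonferroni(vals, groups)
        assert (out["p_bonferroni"] >= out["p_uncorrected"] - 1e-15).all()
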