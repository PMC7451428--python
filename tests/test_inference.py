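"""Group inference: voxelwise GLM, smoothness, Monte-Carlo extent threshold,
cluster extraction, effect sizes, activation control."""

import numpy as np
import pytest
from scipy import ndimage, stats

from seedgc import (
    GroupDesign,
    activation_control,
    alphasim_extent_threshold,
    cluster_mean_cpc,
    cohens_d_from_t,
    estimate_smoothness,
    extract_clusters,
    one_sample_cluster_t,
    voxelwise_group_t,
)


def random_design(rng, n=60, n1=30):
    X = np.column_stack([
        np.ones(n),
        np.r_[np.ones(n1), -np.ones(n - n1)],
        rng.normal(33, 9, n),
        (rng.random(n) < 0.25).astype(float),
        rng.gamma(4, 0.025, n),
        rng.gamma(4, 0.025, n),
    ])
    return GroupDesign(X, ["intercept", "group", "age", "gender", "fd_r", "fd_t"],
                       [f"s{i}" for i in range(n)])


class TestVoxelwiseGroupT:
    def test_df_is_n_minus_design_columns(self, rng):
        design = random_design(rng)
        _, df, _ = voxelwise_group_t(rng.standard_normal((60, 100)), design)
        assert df == 54

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        design = random_design(rng, n=8, n1=4)
        Y = rng.standard_normal((8, 5))
        t, df, _ = voxelwise_group_t(Y, design)
        for v in range(5):
            fit = sm.OLS(Y[:, v], design.matrix).fit()
            assert t[v] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert df == int(fit.df_resid)

    def test_null_rejection_close_to_nominal(self, rng):
        design = random_design(rng)
        t, df, _ = voxelwise_group_t(rng.standard_normal((60, 5000)), design)
        crit = stats.t.isf(0.005, df)
        rate = (np.abs(t) > crit).mean()
        assert 0.005 <= rate <= 0.02

    def test_rank_deficiency_rejected(self, rng):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            GroupDesign(X, ["a", "b"], [str(i) for i in range(10)])


class TestOneSampleClusterT:
    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            one_sample_cluster_t(np.full(10, 2.0))

    def test_balanced_signs_give_t_zero(self):
        res = one_sample_cluster_t(np.array([1.0, -1.0] * 5))
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 9

    def test_df_is_n_minus_1_in_plain_mode(self, rng):
        res = one_sample_cluster_t(rng.standard_normal(31))
        assert res.df == 30

    def test_adjusted_mode_reduces_df_and_matches_ols(self, rng):
        import statsmodels.api as sm

        v = rng.standard_normal(20)
        C = rng.standard_normal((20, 3))
        res = one_sample_cluster_t(v, covariates=C)
        assert res.df == 16
        X = np.column_stack([np.ones(20), C - C.mean(axis=0)])
        fit = sm.OLS(v, X).fit()
        assert res.statistic == pytest.approx(fit.tvalues[0], abs=1e-8)


class TestSmoothnessEstimation:
    def test_white_noise_estimates_about_voxel_size(self, rng):
        maps = rng.standard_normal((10, 12, 12, 12))
        fwhm = estimate_smoothness(maps, np.ones((12, 12, 12), bool), np.full(3, 3.0))
        assert np.all(fwhm >= 3.0)
        assert np.all(fwhm <= 3.6)  # within 20 % of voxel size

    def test_smoothed_noise_recovers_applied_fwhm(self, rng):
        target_fwhm = 8.0
        sigma = target_fwhm / (2 * np.sqrt(2 * np.log(2))) / 3.0
        maps = np.stack([
            ndimage.gaussian_filter(rng.standard_normal((20, 20, 20)), sigma,
                                    mode="wrap")
            for _ in range(50)
        ])
        fwhm = estimate_smoothness(maps, np.ones((20, 20, 20), bool), np.full(3, 3.0))
        assert np.all((fwhm >= 6.5) & (fwhm <= 9.5))

    def test_fwhm_scales_with_voxel_size(self, rng):
        sigma = 1.5
        maps = np.stack([
            ndimage.gaussian_filter(rng.standard_normal((16, 16, 16)), sigma,
                                    mode="wrap")
            for _ in range(20)
        ])
        mask = np.ones((16, 16, 16), bool)
        f3 = estimate_smoothness(maps, mask, np.full(3, 3.0))
        f6 = estimate_smoothness(maps, mask, np.full(3, 6.0))
        assert f6 == pytest.approx(2 * f3)


class TestAlphaSim:
    def test_rare_isolated_voxels_need_extent_one(self):
        mask = np.ones((4, 4, 4), bool)
        k, maxima = alphasim_extent_threshold(
            mask, 0.0, np.full(3, 3.0), voxel_p=1e-6, alpha=0.05, n_iter=1000,
            rng=0,
        )
        assert k == 1
        assert maxima.max() <= 1

    def test_threshold_nondecreasing_in_fwhm(self):
        mask = np.ones((14, 14, 14), bool)
        ks = []
        for fwhm in (0.0, 6.0, 12.0):
            k, _ = alphasim_extent_threshold(mask, fwhm, np.full(3, 3.0),
                                             voxel_p=0.01, alpha=0.05,
                                             n_iter=400, rng=1)
            ks.append(k)
        assert ks[0] <= ks[1] <= ks[2]

    def test_stricter_voxel_p_lowers_extent(self):
        mask = np.ones((14, 14, 14), bool)
        k_loose, _ = alphasim_extent_threshold(mask, 8.0, np.full(3, 3.0),
                                               voxel_p=0.05, alpha=0.05,
                                               n_iter=400, rng=2)
        k_strict, _ = alphasim_extent_threshold(mask, 8.0, np.full(3, 3.0),
                                                voxel_p=0.001, alpha=0.05,
                                                n_iter=400, rng=2)
        assert k_strict <= k_loose

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            alphasim_extent_threshold(np.zeros((4, 4, 4), bool), 8.0,
                                      np.full(3, 3.0), n_iter=300)


class TestExtractClusters:
    def _affine(self):
        a = np.eye(4) * 3.0
        a[3, 3] = 1.0
        a[:3, 3] = -1.5 * np.array([9, 9, 9])
        return a

    def test_zero_map_gives_empty_table(self):
        tab = extract_clusters(np.zeros((10, 10, 10)), 54, np.ones((10, 10, 10), bool),
                               self._affine())
        assert len(tab) == 0

    def test_planted_blob_recovered_with_peak(self):
        t_map = np.zeros((10, 10, 10))
        blob = np.zeros((10, 10, 10), bool)
        blob[3:7, 3:7, 4:6] = True  # 4*4*2 = 32 voxels
        t_map[blob] = 6.0
        t_map[5, 5, 5] = 7.5
        blob[5, 5, 5] = True
        tab = extract_clusters(t_map, 54, np.ones((10, 10, 10), bool), self._affine(),
                               voxel_p=0.01, extent_threshold=20)
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row.extent == 32
        assert row.peak_t == pytest.approx(7.5)
        mm = self._affine()[:3, :3] @ np.array([5, 5, 5]) + self._affine()[:3, 3]
        assert (row.peak_x, row.peak_y, row.peak_z) == pytest.approx(tuple(mm))

    def test_opposite_sign_blobs_never_merge(self):
        t_map = np.zeros((10, 10, 10))
        t_map[2:5, 2:5, 2:5] = 6.0
        t_map[5:8, 5:8, 5:8] = -6.0  # corner-adjacent to the positive blob
        tab = extract_clusters(t_map, 54, np.ones((10, 10, 10), bool), self._affine(),
                               extent_threshold=1, connectivity=26)
        assert len(tab) == 2
        assert sorted(tab["sign"]) == [-1, 1]

    def test_small_components_filtered_by_extent(self):
        t_map = np.zeros((10, 10, 10))
        t_map[1, 1, 1] = 8.0
        tab = extract_clusters(t_map, 54, np.ones((10, 10, 10), bool), self._affine(),
                               extent_threshold=5)
        assert len(tab) == 0


class TestClusterMeanAndEffectSize:
    def test_single_voxel_cluster_returns_that_voxel(self, rng):
        mask = np.ones((4, 4, 4), bool)
        stack = rng.standard_normal((6, mask.sum()))
        cl = np.zeros((4, 4, 4), bool)
        cl[2, 1, 3] = True
        flat_index = np.flatnonzero(cl[mask])[0]
        got = cluster_mean_cpc(stack, mask, cl)
        assert got == pytest.approx(stack[:, flat_index])

    def test_uniform_map_returns_constant_and_hand_average(self, rng):
        mask = np.ones((4, 4, 4), bool)
        stack = np.full((3, 64), 0.7)
        cl = np.zeros((4, 4, 4), bool)
        cl[0, 0, 0] = cl[1, 1, 1] = cl[2, 2, 2] = True
        assert cluster_mean_cpc(stack, mask, cl) == pytest.approx([0.7] * 3)
        stack2 = rng.standard_normal((2, 64))
        sel = cl[mask]
        expected = stack2[:, sel].mean(axis=1)
        assert cluster_mean_cpc(stack2, mask, cl) == pytest.approx(expected)

    def test_cluster_outside_mask_is_an_error(self, rng):
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        cl = np.zeros((4, 4, 4), bool)
        cl[3, 3, 3] = True
        with pytest.raises(ValueError):
            cluster_mean_cpc(rng.standard_normal((3, int(mask.sum()))), mask, cl)

    @pytest.mark.parametrize("t,expected", [(4.72, 1.22), (-3.88, -1.00), (0.0, 0.0)])
    def test_cohens_d_conversion(self, t, expected):
        assert cohens_d_from_t(t, 29, 31) == pytest.approx(expected, abs=0.005)


class TestActivationControl:
    def test_orthogonal_activation_barely_changes_t(self, rng):
        design = random_design(rng, n=60, n1=30)
        group = design.matrix[:, 1]
        cpc = 0.3 * group + rng.standard_normal(60) * 0.5
        act = rng.standard_normal((60, 2))
        # orthogonalise activation against the full design
        act = act - design.matrix @ np.linalg.lstsq(design.matrix, act, rcond=None)[0]
        t_plain, _, _ = voxelwise_group_t(cpc[:, None], design)
        res = activation_control(cpc, design, act)
        assert abs(res.statistic - t_plain[0]) < 0.1

    def test_mediated_effect_collapses(self, rng):
        design = random_design(rng, n=40, n1=20)
        act = design.matrix[:, 1] + 0.01 * rng.standard_normal(40)
        cpc = act.copy()  # CPC fully explained by "activation"
        res = activation_control(cpc, design, act[:, None])
        assert abs(res.statistic) < 0.5

    def test_matches_ols_oracle(self, rng):
        import statsmodels.api as sm

        design = random_design(rng, n=12, n1=6)
        cpc = rng.standard_normal(12)
        act = rng.standard_normal((12, 1))
        res = activation_control(cpc, design, act)
        X = np.hstack([design.matrix, act - act.mean(axis=0)])
        fit = sm.OLS(cpc, X).fit()
        assert res.statistic == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert res.df == int(fit.df_resid)

    def test_collinear_activation_rejected(self, rng):
        design = random_design(rng, n=20, n1=10)
        with pytest.raises(ValueError):
            activation_control(rng.standard_normal(20), design,
                               design.matrix[:, 2:3].copy())
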