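"""Preprocessing chain: discard, FD, exclusion, scrubbing, smoothing,
band-pass, task regressors, nuisance regression, seed extraction."""

import numpy as np
import pytest

from seedgc import (
    ConfoundSet,
    SeedSpec,
    build_task_regressors,
    compute_fd,
    discard_initial_volumes,
    exclusion_screen,
    extract_seed_ts,
    generate_task_design,
    nuisance_regress,
    scrub_interpolate,
    spatial_smooth,
    temporal_bandpass,
)
from seedgc.preprocess import seed_voxel_indices

from conftest import make_volume


def make_confounds(T, rng=None):
    rng = rng or np.random.default_rng(0)
    return ConfoundSet(rng.standard_normal((T, 6)) * 0.01, rng.standard_normal((T, 3)))


class TestDiscard:
    def test_240_minus_5_leaves_235(self, rng):
        vol = make_volume(rng.standard_normal((4, 4, 4, 240)))
        conf = make_confounds(240)
        out, oc = discard_initial_volumes(vol, conf, 5)
        assert out.n_vols == 235
        assert len(oc) == 235

    def test_zero_is_identity_and_consistency_holds(self, noise_volume):
        conf = make_confounds(noise_volume.n_vols)
        out, oc = discard_initial_volumes(noise_volume, conf, 0)
        assert out is noise_volume
        for n in (1, 7):
            out, oc = discard_initial_volumes(noise_volume, conf, n)
            assert out.n_vols == len(oc)
            assert oc.fd[0] == 0.0

    def test_discarding_everything_is_an_error(self, noise_volume):
        with pytest.raises(ValueError):
            discard_initial_volumes(noise_volume, make_confounds(noise_volume.n_vols),
                                    noise_volume.n_vols)


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        fd, mean_fd = compute_fd(np.ones((20, 6)) * 0.3)
        assert np.all(fd == 0.0)
        assert mean_fd == 0.0

    def test_single_translation_step(self):
        m = np.zeros((10, 6))
        m[5:, 0] = 0.1
        fd, _ = compute_fd(m)
        assert fd[5] == pytest.approx(0.1)
        assert fd[4] == 0.0 and fd[6] == 0.0

    def test_rotation_scaled_by_50mm(self):
        m = np.zeros((10, 6))
        m[3:, 4] = 0.002
        fd, _ = compute_fd(m)
        assert fd[3] == pytest.approx(0.1)  # 50 mm * 0.002 rad

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            compute_fd(np.zeros((10, 5)))


class _Rec:
    def __init__(self, hit_rate):
        self.hit_rate = hit_rate


class TestExclusionScreen:
    def test_translation_over_3mm_excludes(self):
        m = np.zeros((10, 6))
        m[4, 1] = 3.1
        keep, reason = exclusion_screen(_Rec(90.0), m)
        assert not keep and "motion" in reason

    def test_low_hit_rate_excludes(self):
        keep, reason = exclusion_screen(_Rec(29.0), np.zeros((10, 6)))
        assert not keep and "performance" in reason

    def test_boundaries_are_strict(self):
        m = np.zeros((10, 6))
        m[4, 0] = 3.0  # exactly at the limit: kept ("exceeding" is strict)
        keep, reason = exclusion_screen(_Rec(80.0), m)
        assert keep and reason == ""

    def test_rotation_in_degrees(self):
        m = np.zeros((10, 6))
        m[4, 5] = np.radians(3.1)
        keep, reason = exclusion_screen(_Rec(80.0), m)
        assert not keep and "rotation" in reason

    def test_missing_hit_rate(self):
        with pytest.raises(ValueError):
            exclusion_screen(_Rec(np.nan), np.zeros((10, 6)), task=True)
        keep, _ = exclusion_screen(_Rec(np.nan), np.zeros((10, 6)), task=False)
        assert keep


class TestScrubbing:
    def test_no_flags_is_identity(self, noise_volume):
        fd = np.zeros(noise_volume.n_vols)
        assert scrub_interpolate(noise_volume, fd) is noise_volume

    def test_interior_point_on_linear_series_is_exact(self):
        T = 10
        data = np.tile(np.arange(T, dtype=float), (2, 2, 2, 1))
        vol = make_volume(data.copy())
        vol.data[..., 5] = 99.0
        fd = np.zeros(T)
        fd[5] = 1.0
        out = scrub_interpolate(vol, fd, threshold=0.5)
        assert out.data[0, 0, 0, 5] == pytest.approx(5.0)

    def test_run_of_three_flagged_points(self):
        # hand-computed linear interpolation between t=3 (value 30) and t=7 (70)
        series = np.array([0, 10, 20, 30, 1e3, 1e3, 1e3, 70, 80, 90], dtype=float)
        vol = make_volume(series.reshape(1, 1, 1, -1))
        fd = np.zeros(10)
        fd[4:7] = 2.0
        out = scrub_interpolate(vol, fd, threshold=0.5)
        assert out.data[0, 0, 0, 4:7] == pytest.approx([40.0, 50.0, 60.0])

    def test_endpoint_uses_nearest_neighbour(self):
        series = np.array([500.0, 1.0, 2.0, 3.0], dtype=float)
        vol = make_volume(series.reshape(1, 1, 1, -1))
        fd = np.array([0.0, 0.0, 0.0, 0.0])
        fd[0] = 9.0  # fd[0] is normally 0, but a flagged start must clamp
        out = scrub_interpolate(vol, fd, threshold=0.5)
        assert out.data[0, 0, 0, 0] == pytest.approx(1.0)

    def test_all_flagged_is_an_error(self, noise_volume):
        with pytest.raises(ValueError):
            scrub_interpolate(noise_volume, np.ones(noise_volume.n_vols), threshold=0.5)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, noise_volume):
        assert spatial_smooth(noise_volume, 0.0) is noise_volume

    def test_delta_profile_matches_gaussian(self):
        data = np.zeros((15, 15, 15, 1))
        data[7, 7, 7, 0] = 1.0
        vol = make_volume(data, voxel_size=3.0)
        out = spatial_smooth(vol, 8.0)
        sd = 8.0 / (2 * np.sqrt(2 * np.log(2)))
        expected = np.exp(-(3.0**2) / (2 * sd**2))
        ratio = out.data[8, 7, 7, 0] / out.data[7, 7, 7, 0]
        assert ratio == pytest.approx(expected, rel=0.01)

    def test_mass_conserved_for_interior_delta(self):
        data = np.zeros((15, 15, 15, 1))
        data[7, 7, 7, 0] = 1.0
        out = spatial_smooth(make_volume(data, voxel_size=3.0), 8.0)
        assert out.data.sum() == pytest.approx(1.0, rel=1e-3)


class TestBandpass:
    def _sine_volume(self, freq, T=235, tr=2.5):
        t = np.arange(T) * tr
        data = np.tile(np.sin(2 * np.pi * freq * t), (2, 2, 2, 1))
        return make_volume(data, tr=tr)

    def test_in_band_sinusoid_preserved(self):
        out = temporal_bandpass(self._sine_volume(0.04), 0.01, 0.08)
        ratio = out.data[0, 0, 0].std() / self._sine_volume(0.04).data[0, 0, 0].std()
        assert 0.95 <= ratio <= 1.05

    def test_out_of_band_sinusoid_suppressed(self):
        out = temporal_bandpass(self._sine_volume(0.15), 0.01, 0.08)
        ratio = out.data[0, 0, 0].std() / self._sine_volume(0.15).data[0, 0, 0].std()
        assert ratio < 0.05

    def test_constant_series_removed(self):
        vol = make_volume(np.ones((2, 2, 2, 100)))
        out = temporal_bandpass(vol, 0.01, 0.08)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_cutoff_above_nyquist_rejected(self, noise_volume):
        with pytest.raises(ValueError):
            temporal_bandpass(noise_volume, 0.01, 0.25)


class TestTaskRegressors:
    def test_single_window_peaks_4_to_8s_after_onset(self):
        from seedgc.design import Block, TaskDesign

        design = TaskDesign(blocks=[Block("2-back", 50.0, 30.0, 0)], n_sessions=1,
                            session_duration=300.0)
        cols, labels = build_task_regressors(design, tr=2.5, n_vols=120)
        reg = cols[:, labels.index("2-back")]
        # zero before the response can start; undershoot after the window is
        # bounded by the kernel's peak:undershoot ratio
        assert np.allclose(reg[: int(50 / 2.5)], 0.0, atol=1e-9)
        assert reg.min() >= -reg.max() / 3.0
        t_peak = (np.argmax(reg) + 0.5) * 2.5
        assert 50.0 + 4.0 <= t_peak <= 50.0 + 30.0 + 8.0

    def test_two_identical_sessions_tile_the_regressor(self):
        from seedgc.design import Block, TaskDesign

        blocks = [Block("2-back", 10.0, 30.0, s) for s in (0, 1)]
        design = TaskDesign(blocks=blocks, n_sessions=2, session_duration=100.0)
        cols, _ = build_task_regressors(design, tr=2.5, n_vols=80)
        per_session = 40
        assert cols[:per_session, 0] == pytest.approx(cols[per_session:, 0], abs=1e-6)

    def test_empty_design_gives_zero_columns(self):
        from seedgc.design import TaskDesign

        design = TaskDesign(blocks=[], n_sessions=1, session_duration=0.0)
        cols, labels = build_task_regressors(design, tr=2.5, n_vols=50, labels=["2-back"])
        assert cols.shape == (50, 1)
        assert np.allclose(cols, 0.0)

    def test_design_longer_than_scan_rejected(self, default_design):
        with pytest.raises(ValueError):
            build_task_regressors(default_design, tr=2.5, n_vols=100)


class TestNuisanceRegression:
    def test_regressing_series_on_itself_zeroes_it(self, rng):
        series = rng.standard_normal(40)
        vol = make_volume(np.tile(series, (3, 3, 3, 1)))
        out = nuisance_regress(vol, series[:, None])
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, noise_volume, rng):
        R = rng.standard_normal((noise_volume.n_vols, 4))
        out = nuisance_regress(noise_volume, R)
        res = out.masked_series()
        dots = res @ R
        scale = np.linalg.norm(res, axis=1)[:, None] * np.linalg.norm(R, axis=0)[None]
        assert np.all(np.abs(dots) / np.maximum(scale, 1e-30) < 1e-8)

    def test_orthogonal_regressor_leaves_demeaned_series(self, rng):
        T = 40
        series = rng.standard_normal(T)
        r = rng.standard_normal(T)
        # orthogonalise the regressor against the (demeaned) series
        sc = series - series.mean()
        r = r - r.mean()
        r -= (r @ sc) / (sc @ sc) * sc
        vol = make_volume(np.tile(series, (2, 2, 2, 1)))
        out = nuisance_regress(vol, r[:, None])
        assert out.data[0, 0, 0] == pytest.approx(sc, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        # 10-point worked example solved directly via the normal equations
        T = 10
        y = rng.standard_normal(T)
        R = rng.standard_normal((T, 2))
        X = np.column_stack([np.ones(T), R])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        expected = y - X @ beta
        vol = make_volume(y.reshape(1, 1, 1, T))
        out = nuisance_regress(vol, R)
        assert out.data[0, 0, 0] == pytest.approx(expected, abs=1e-10)

    def test_collinear_columns_reported(self, noise_volume, rng):
        r = rng.standard_normal(noise_volume.n_vols)
        with pytest.raises(ValueError, match="collinear"):
            nuisance_regress(noise_volume, np.column_stack([r, 2 * r]))


class TestSeedExtraction:
    def test_default_seed_count_matches_brute_force(self, rng):
        vol = make_volume(rng.standard_normal((24, 28, 24, 5)))
        seed = SeedSpec()  # (33, 21, -3), r = 6 mm
        idx = seed_voxel_indices(vol, seed)
        # exhaustive distance check over the whole grid
        count = 0
        for i in range(24):
            for j in range(28):
                for k in range(24):
                    mm = vol.ijk_to_mm([i, j, k])[0]
                    if np.linalg.norm(mm - np.array(seed.center)) <= seed.radius:
                        count += 1
        assert len(idx) == count > 0

    def test_sub_voxel_radius_selects_containing_voxel(self, rng):
        vol = make_volume(rng.standard_normal((8, 8, 8, 5)))
        centre_mm = vol.ijk_to_mm([4, 4, 4])[0]
        ts = extract_seed_ts(vol, SeedSpec(center=tuple(centre_mm), radius=0.5))
        assert ts == pytest.approx(vol.data[4, 4, 4])

    def test_uniform_image_returns_the_constant(self):
        vol = make_volume(np.full((8, 8, 8, 5), 3.5))
        ts = extract_seed_ts(vol, SeedSpec(center=(0.0, 0.0, 0.0), radius=6.0))
        assert ts == pytest.approx(np.full(5, 3.5))

    def test_sphere_outside_mask_is_an_error(self, rng):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0, 0, 0] = True
        vol = make_volume(rng.standard_normal((8, 8, 8, 5)), mask=mask)
        with pytest.raises(ValueError):
            extract_seed_ts(vol, SeedSpec(center=(10.0, 10.0, 10.0), radius=2.0))
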