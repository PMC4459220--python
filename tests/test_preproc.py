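"""Preprocessing chain: FD, exclusion, regression, detrend, filter, smooth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmhcpipe.preproc import (
    BoldSeries,
    MotionTrace,
    bandpass,
    build_symmetric_template,
    compute_fd,
    detrend_linear,
    discard_initial_volumes,
    exclusion_flags,
    regress_nuisance,
    smooth_gaussian,
)


def _bold(data, tr=2.0):
    return BoldSeries(data=np.asarray(data, float), tr_seconds=tr,
                      voxel_mm=(3.0, 3.0, 3.0))


def _series(values, tr=2.0):
    return _bold(np.asarray(values, float).reshape(1, 1, 1, -1), tr)


class TestDiscard:
    def test_study_discard_240_to_230(self, rng):
        bold = _bold(rng.normal(size=(2, 2, 2, 240)))
        out = discard_initial_volumes(bold, 10)
        assert out.n_volumes == 230
        assert np.array_equal(out.data, bold.data[..., 10:])

    def test_discard_zero_is_identity(self, rng):
        bold = _bold(rng.normal(size=(2, 2, 2, 5)))
        assert np.array_equal(discard_initial_volumes(bold, 0).data, bold.data)

    def test_boundary_then_temporal_ops_error(self, rng):
        bold = _bold(rng.normal(size=(1, 1, 1, 240)))
        out = discard_initial_volumes(bold, 239)
        assert out.n_volumes == 1
        with pytest.raises(ValueError):
            discard_initial_volumes(bold, 240)
        with pytest.raises(ValueError):
            detrend_linear(out)


class TestFramewiseDisplacement:
    def test_zero_trace_gives_zero_fd(self):
        t = MotionTrace(np.zeros((10, 3)), np.zeros((10, 3)))
        fd = compute_fd(t)
        assert np.all(fd.values == 0) and fd.mean_fd == 0

    def test_single_translation_step(self):
        tr = np.zeros((6, 3))
        tr[2:, 0] = 0.5  # +0.5 mm step in x entering frame 3
        fd = compute_fd(MotionTrace(tr, np.zeros((6, 3))))
        expected = np.array([0, 0, 0.5, 0, 0, 0])
        assert np.allclose(fd.values, expected)

    def test_rotation_arc_length_on_50mm_sphere(self):
        rot = np.zeros((4, 3))
        rot[2:, 1] = np.rad2deg(0.02)  # 1.1459 degrees = 0.02 rad
        fd = compute_fd(MotionTrace(np.zeros((4, 3)), rot))
        assert np.allclose(fd.values, [0, 0, 1.0, 0])

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            compute_fd(MotionTrace(np.zeros((1, 3)), np.zeros((1, 3))))

    @given(offset=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance(self, offset):
        """Adding a constant offset to every frame leaves FD unchanged."""
        rng = np.random.default_rng(0)
        tr = rng.normal(size=(20, 3))
        rot = rng.normal(size=(20, 3))
        fd0 = compute_fd(MotionTrace(tr, rot))
        fd1 = compute_fd(MotionTrace(tr + offset, rot + offset))
        assert np.allclose(fd0.values, fd1.values)


class TestExclusion:
    def _trace(self, t_max=0.0, r_max=0.0):
        tr = np.zeros((10, 3))
        tr[5, 0] = t_max
        rot = np.zeros((10, 3))
        rot[5, 1] = r_max
        return MotionTrace(tr, rot)

    def test_translation_above_threshold_excluded(self):
        flags = exclusion_flags({"s": self._trace(t_max=2.5)})
        assert flags.loc["s", "excluded"]

    def test_exactly_two_mm_retained(self):
        """Thresholds are strict inequalities: 2.0 mm exactly is retained."""
        flags = exclusion_flags({"s": self._trace(t_max=2.0, r_max=1.9)})
        assert not flags.loc["s", "excluded"]

    def test_rotation_axis_rule(self):
        flags = exclusion_flags({"s": self._trace(r_max=2.1)})
        assert flags.loc["s", "excluded"]


class TestNuisanceRegression:
    def test_span_of_regressors_annihilated(self, rng):
        reg = rng.normal(size=(30, 2))
        series = (reg @ np.array([1.5, -2.0]) + 3.0).reshape(1, 1, 1, -1)
        out = regress_nuisance(_bold(series), reg)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        """Residuals equal an independent normal-equations solve."""
        for _ in range(100):
            T, k = 20, 2
            reg = rng.normal(size=(T, k))
            data = rng.normal(size=(2, 2, 1, T))
            out = regress_nuisance(_bold(data), reg)
            X = np.column_stack([np.ones(T), reg])
            beta = np.linalg.solve(X.T @ X, X.T @ data.reshape(-1, T).T)
            oracle = data.reshape(-1, T).T - X @ beta
            assert np.allclose(out.data.reshape(-1, T).T, oracle, atol=1e-8)

    def test_residuals_orthogonal_to_regressors(self, rng):
        reg = rng.normal(size=(40, 3))
        out = regress_nuisance(_bold(rng.normal(size=(3, 2, 2, 40))), reg)
        flat = out.data.reshape(-1, 40)
        inner = np.abs(flat @ reg) / (np.abs(flat).sum(1, keepdims=True) + 1e-12)
        assert inner.max() < 1e-8

    def test_rank_deficient_design_warns_and_drops(self, rng):
        reg = rng.normal(size=(25, 2))
        reg = np.column_stack([reg, reg[:, 0] * 2.0])  # dependent column
        with pytest.warns(UserWarning, match="rank-deficient"):
            out = regress_nuisance(_bold(rng.normal(size=(1, 1, 1, 25))), reg)
        assert np.isfinite(out.data).all()


class TestDetrend:
    def test_pure_ramp_and_constant_to_zero(self):
        t = np.arange(20.0)
        for series in (3.0 + 0.5 * t, np.full(20, 7.0)):
            out = detrend_linear(_series(series))
            assert np.max(np.abs(out.data)) < 1e-9

    def test_whole_period_sinusoid_unchanged(self):
        """A sinusoid over whole periods, phased even about the grid center,
        is exactly orthogonal to both intercept and linear trend."""
        t = np.arange(200.0)
        s = np.cos(2 * np.pi * 5 * (t - 99.5) / 200)
        out = detrend_linear(_series(s))
        assert np.max(np.abs(out.data.ravel() - s)) < 1e-6

    def test_idempotence(self, rng):
        b1 = detrend_linear(_bold(rng.normal(size=(2, 2, 2, 50))))
        b2 = detrend_linear(b1)
        rel = np.max(np.abs(b2.data - b1.data)) / np.max(np.abs(b1.data))
        assert rel < 1e-6


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        t = np.arange(230) * 2.0
        s = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(_series(s, tr=2.0)).data.ravel()
        assert np.abs(out).max() >= 0.95 * np.abs(s).max()

    def test_stopband_sinusoid_removed(self):
        t = np.arange(230) * 2.0
        s = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass(_series(s, tr=2.0)).data.ravel()
        assert np.abs(out).max() <= 0.05 * np.abs(s).max()

    def test_constant_series_zeroed(self):
        out = bandpass(_series(np.full(64, 11.0)))
        assert np.max(np.abs(out.data)) < 1e-9

    def test_matches_fft_oracle(self, rng):
        """Filter equals explicit FFT masking on the exact frequency grid."""
        x = rng.normal(size=230)
        out = bandpass(_series(x, tr=2.0)).data.ravel()
        freqs = np.fft.rfftfreq(230, d=2.0)
        spec = np.fft.rfft(x)
        spec[(freqs < 0.01) | (freqs > 0.08)] = 0
        assert np.allclose(out, np.fft.irfft(spec, 230), atol=1e-10)

    def test_band_errors(self):
        s = _series(np.zeros(32), tr=2.0)
        with pytest.raises(ValueError):
            bandpass(s, 0.08, 0.01)
        with pytest.raises(ValueError):
            bandpass(s, 0.01, 0.3)  # above the 0.25 Hz Nyquist

    def test_idempotence(self, rng):
        b1 = bandpass(_bold(rng.normal(size=(2, 2, 1, 100))))
        b2 = bandpass(b1)
        rel = np.max(np.abs(b2.data - b1.data)) / np.max(np.abs(b1.data))
        assert rel < 1e-6


class TestSmoothing:
    def test_zero_fwhm_identity(self, rng):
        v = rng.normal(size=(6, 6, 6))
        assert np.array_equal(smooth_gaussian(v, 0.0, (3, 3, 3)), v)

    def test_impulse_matches_gaussian_kernel(self):
        """Central profile equals the closed-form kernel at 3 mm spacing."""
        v = np.zeros((21, 21, 21))
        v[10, 10, 10] = 1.0
        out = smooth_gaussian(v, 4.0, (3.0, 3.0, 3.0))
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        x = 3.0 * (np.arange(21) - 10)
        kern = np.exp(-(x**2) / (2 * sigma**2))
        kern /= kern.sum()
        # separable kernel: profile along x at center = kx * ky(0) * kz(0)
        # (discrete implementation truncates the kernel support, hence atol)
        assert np.allclose(out[:, 10, 10], kern * kern[10] * kern[10],
                           atol=1e-4)

    def test_mass_conserved(self, rng):
        v = rng.normal(size=(10, 12, 8)) + 5.0
        out = smooth_gaussian(v, 6.0, (3.0, 3.0, 3.0))
        assert np.isclose(out.sum(), v.sum(), rtol=1e-6)


class TestSymmetricTemplate:
    def test_symmetric_input_is_fixed_point(self, rng):
        v = rng.normal(size=(4, 3, 3))
        v = (v + v[::-1]) / 2
        out = build_symmetric_template([v])
        assert np.allclose(out.data, v)

    def test_pairwise_average_on_toy_grid(self):
        v = np.zeros((4, 2, 2))
        v[0, 0, 0] = 2.0  # value a; mirror voxel (3,0,0) holds b = 0
        out = build_symmetric_template([v])
        assert out.data[0, 0, 0] == out.data[3, 0, 0] == 1.0

    def test_identical_copies_match_single(self, rng):
        v = rng.normal(size=(4, 4, 4))
        one = build_symmetric_template([v]).data
        many = build_symmetric_template([v, v, v]).data
        assert np.allclose(one, many)
        assert np.array_equal(many, many[::-1])

    def test_grid_mismatch_names_volume(self, rng):
        with pytest.raises(ValueError, match="volume 1"):
            build_symmetric_template([np.zeros((4, 4, 4)), np.zeros((4, 4, 5))])
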