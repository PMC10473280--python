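"""Preprocessing physics: FD, confound regression, scrubbing, filter, kernel."""

import numpy as np
import pandas as pd
import pytest

from wdhub import (ConfigurationError, DataQualityError, ModelError,
                   SchemaError, bandpass, compute_fd_jenkinson,
                   regress_confounds, scrub_interpolate, smooth_gaussian)
from wdhub.preprocess import ConfoundModel, preprocess_series, rigid_matrix
from wdhub.synthgen import NUISANCE_COLUMNS
from wdhub.io import MOTION_COLUMNS

from conftest import make_series


def fd_ball_oracle(params_prev, params_cur, radius_mm, rng, n_points=200000):
    """RMS displacement of random points in a solid sphere (Monte Carlo)."""
    m_rel = rigid_matrix(params_cur) @ np.linalg.inv(rigid_matrix(params_prev))
    pts = rng.standard_normal((n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= radius_mm * rng.random(n_points)[:, None] ** (1 / 3)
    moved = pts @ m_rel[:3, :3].T + m_rel[:3, 3]
    return float(np.sqrt(np.mean(np.sum((moved - pts) ** 2, axis=1))))


class TestFramewiseDisplacement:
    def test_zero_motion_zero_fd(self):
        summary = compute_fd_jenkinson(np.zeros((10, 6)))
        assert np.all(summary.fd_jenkinson_mm == 0)
        assert summary.flagged_frames.size == 0

    def test_pure_translation_equals_step(self):
        motion = np.zeros((5, 6))
        motion[3:, 0] = 0.3  # 0.3 mm jump in x between frames 2 and 3
        summary = compute_fd_jenkinson(motion)
        assert summary.fd_jenkinson_mm[3] == pytest.approx(0.3, abs=1e-12)
        assert list(summary.flagged_frames) == [3]

    def test_rotation_fd_positive_and_grows_with_radius(self, rng):
        motion = np.zeros((2, 6))
        motion[1, 4] = 0.002  # 2 mrad rotation about y
        fd_small = compute_fd_jenkinson(motion, radius_mm=50.0)
        fd_large = compute_fd_jenkinson(motion, radius_mm=80.0)
        assert fd_small.fd_jenkinson_mm[1] > 0
        assert fd_large.fd_jenkinson_mm[1] > fd_small.fd_jenkinson_mm[1]
        oracle = fd_ball_oracle(motion[0], motion[1], 80.0, rng)
        assert fd_large.fd_jenkinson_mm[1] == pytest.approx(oracle, rel=0.02)

    def test_general_motion_matches_ball_oracle(self, rng):
        motion = rng.normal(0, [0.2] * 3 + [0.004] * 3, size=(3, 6))
        summary = compute_fd_jenkinson(motion, radius_mm=80.0)
        for t in (1, 2):
            oracle = fd_ball_oracle(motion[t - 1], motion[t], 80.0, rng)
            assert summary.fd_jenkinson_mm[t] == pytest.approx(oracle, rel=0.02)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(SchemaError):
            compute_fd_jenkinson(np.zeros((10, 5)))


def make_confounds(rng, T):
    motion = pd.DataFrame(
        rng.normal(0, [[0.02] * 3 + [2e-4] * 3], (T, 6)),
        columns=MOTION_COLUMNS)
    nuisance = pd.DataFrame(rng.standard_normal((T, 10)),
                            columns=NUISANCE_COLUMNS)
    return ConfoundModel.from_tables(motion, nuisance), motion, nuisance


class TestConfoundRegression:
    def test_series_equal_to_regressor_goes_to_zero(self, rng):
        T = 60
        conf, motion, _ = make_confounds(rng, T)
        series = make_series(np.tile(motion.iloc[:, 0].to_numpy(), (4, 1)))
        resid = regress_confounds(series, conf)
        assert np.allclose(resid.data, 0.0, atol=1e-10)

    def test_intercept_only_demeans(self, rng):
        T = 40
        zero_motion = pd.DataFrame(np.zeros((T, 6)), columns=MOTION_COLUMNS)
        nuis = pd.DataFrame(np.zeros((T, 10)), columns=NUISANCE_COLUMNS)
        with pytest.raises(ModelError):
            # all-zero regressors are collinear; the model must say so
            ConfoundModel.from_tables(zero_motion, nuis).design_matrix()

    def test_residuals_match_lstsq_oracle_and_are_orthogonal(self, rng):
        T = 80
        conf, *_ = make_confounds(rng, T)
        Y = rng.standard_normal((6, T))
        series = make_series(Y)
        resid = regress_confounds(series, conf).data
        X, _ = conf.design_matrix()
        beta = np.linalg.solve(X.T @ X, X.T @ Y.T)     # normal equations
        assert np.allclose(resid, (Y.T - X @ beta).T, atol=1e-10)
        dots = np.abs(resid @ X)
        norms = np.linalg.norm(resid, axis=1, keepdims=True) * \
            np.linalg.norm(X, axis=0)
        assert np.all(dots <= 1e-8 * np.maximum(norms, 1e-30))

    def test_regression_is_idempotent(self, rng):
        conf, *_ = make_confounds(rng, 70)
        series = make_series(rng.standard_normal((5, 70)))
        once = regress_confounds(series, conf)
        twice = regress_confounds(once, conf)
        rel = np.linalg.norm(twice.data - once.data) / np.linalg.norm(once.data)
        assert rel < 1e-6


class TestScrubbing:
    def test_no_flags_identity(self, rng):
        series = make_series(rng.standard_normal((3, 20)))
        out = scrub_interpolate(series, np.array([], dtype=int))
        assert np.array_equal(out.data, series.data)

    def test_middle_frame_linear_interpolation(self):
        data = np.array([[1.0, 5.0, 3.0]])
        out = scrub_interpolate(make_series(data), np.array([1]))
        assert out.data[0, 1] == pytest.approx(2.0)

    def test_flagged_run_interpolates_across_gap(self):
        data = np.array([[0.0, 9.0, 9.0, 9.0, 4.0]])
        out = scrub_interpolate(make_series(data), np.array([1, 2, 3]))
        assert np.allclose(out.data[0], [0.0, 1.0, 2.0, 3.0, 4.0])

    def test_edge_frames_copy_nearest(self):
        data = np.array([[7.0, 2.0, 3.0, 9.0]])
        out = scrub_interpolate(make_series(data), np.array([0, 3]))
        assert out.data[0, 0] == 2.0
        assert out.data[0, 3] == 3.0

    def test_all_flagged_rejected(self):
        series = make_series(np.ones((2, 4)))
        with pytest.raises(DataQualityError):
            scrub_interpolate(series, np.arange(4))


class TestBandpass:
    @staticmethod
    def amplitude_ratio(freq_hz, tr=1.5, T=400):
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * freq_hz * t)
        series = make_series(np.tile(x, (2, 1)), tr=tr)
        y = bandpass(series, 0.01, 0.08).data[0]
        spec_in = np.abs(np.fft.rfft(x))
        spec_out = np.abs(np.fft.rfft(y))
        k = np.argmax(spec_in)
        return spec_out[k] / spec_in[k]

    def test_passband_retained(self):
        assert self.amplitude_ratio(0.04) >= 0.9

    def test_stopband_suppressed(self):
        assert self.amplitude_ratio(0.2) <= 0.1

    def test_constant_removed(self):
        series = make_series(np.full((2, 200), 5.0))
        out = bandpass(series, 0.01, 0.08)
        assert np.max(np.abs(out.data)) < 1e-6

    def test_zero_phase_no_shift(self):
        tr, T = 1.5, 600
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * 0.04 * t)
        y = bandpass(make_series(x[None, :], tr=tr), 0.01, 0.08).data[0]
        mid = slice(100, 500)  # away from edge transients
        lag = np.argmax(np.correlate(y[mid], x[mid], mode="full")) \
            - (x[mid].size - 1)
        assert lag == 0

    def test_linearity(self, rng):
        x = rng.standard_normal((1, 150))
        y = rng.standard_normal((1, 150))
        fx = bandpass(make_series(x), 0.01, 0.08).data
        fy = bandpass(make_series(y), 0.01, 0.08).data
        fxy = bandpass(make_series(2.0 * x + 3.0 * y), 0.01, 0.08).data
        assert np.allclose(fxy, 2.0 * fx + 3.0 * fy, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        series = make_series(np.zeros((1, 50)), tr=1.5)
        with pytest.raises(ConfigurationError):
            bandpass(series, 0.01, 0.4)


class TestSmoothing:
    def test_impulse_matches_analytic_gaussian(self):
        shape = (21, 21, 21)
        vox = 2.0
        n = int(np.prod(shape))
        data = np.zeros((n, 1))
        center = np.ravel_multi_index((10, 10, 10), shape)
        data[center, 0] = 1.0
        series = make_series(data, voxel_mm=vox, shape=shape)
        fwhm = 6.0
        out = smooth_gaussian(series, fwhm_mm=fwhm).data[:, 0].reshape(shape)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        xs = (np.arange(21) - 10) * vox
        d2 = xs[:, None, None]**2 + xs[None, :, None]**2 + xs[None, None, :]**2
        analytic = np.exp(-d2 / (2 * sigma ** 2))
        analytic /= analytic.sum()
        out = out / out.sum()
        within = d2 <= (2 * sigma) ** 2
        assert np.allclose(out[within], analytic[within], rtol=0.01)

    def test_constant_image_preserved_under_mask(self):
        shape = (8, 8, 8)
        mask = np.zeros(shape, dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        from conftest import make_geometry
        from wdhub import BoldSeries
        geom = make_geometry(shape, voxel_mm=3.0, mask=mask)
        series = BoldSeries(data=np.full((geom.n_voxels, 2), 4.2),
                            geometry=geom, tr_seconds=1.5)
        out = smooth_gaussian(series, fwhm_mm=6.0)
        assert np.allclose(out.data, 4.2, atol=1e-12)

    def test_tiny_fwhm_is_identity(self, rng):
        series = make_series(rng.standard_normal((27, 3)))
        out = smooth_gaussian(series, fwhm_mm=1e-9)
        assert np.allclose(out.data, series.data, atol=1e-9)

    def test_nonpositive_fwhm_rejected(self, rng):
        series = make_series(rng.standard_normal((8, 2)))
        with pytest.raises(ConfigurationError):
            smooth_gaussian(series, fwhm_mm=0.0)


class TestOrchestration:
    def test_stage_order_override_and_default(self, rng):
        T = 60
        _, motion, nuisance = make_confounds(rng, T)
        series = make_series(rng.standard_normal((27, T)))
        out_default, summary = preprocess_series(series, motion, nuisance)
        out_no_smooth, _ = preprocess_series(
            series, motion, nuisance,
            stage_order=("regress", "scrub", "bandpass"))
        assert out_default.data.shape == series.data.shape
        assert not np.allclose(out_default.data, out_no_smooth.data)

    def test_unknown_stage_rejected(self, rng):
        _, motion, nuisance = make_confounds(rng, 30)
        series = make_series(rng.standard_normal((8, 30)))
        with pytest.raises(ConfigurationError):
            preprocess_series(series, motion, nuisance,
                              stage_order=("regress", "fly"))
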