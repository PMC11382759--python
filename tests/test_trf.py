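"""TRF estimation: design construction, ridge fit, magnitude and envelope."""

import numpy as np
import pytest
from scipy import signal

from speechffr import synthdata as sd
from speechffr import trf
from speechffr.features import StimulusFeatures
from speechffr.neuralprep import NeuralRecording

FS = 1000.0


def _features(n=2000, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    sos = signal.butter(2, [70, 120], btype="bandpass", fs=fs, output="sos")
    f = signal.sosfiltfilt(sos, rng.standard_normal(n))
    e = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return StimulusFeatures(f, e, fs)


class TestLagAxis:
    def test_default_axis_has_141_lags(self):
        axis = trf.LagAxis()
        assert axis.n_lags == 141
        lags = axis.lags_ms()
        assert lags[0] == -20.0 and lags[-1] == 120.0

    def test_default_design_has_282_columns_at_1khz(self):
        design = trf.build_design(_features(500), trf.LagAxis())
        assert design.shape == (500, 282)

    def test_non_integer_lag_step_rejected(self):
        with pytest.raises(ValueError):
            trf.LagAxis(0.0, 10.0, 1.0).lag_samples(512.0)

    def test_invalid_axis_rejected(self):
        with pytest.raises(ValueError):
            trf.LagAxis(120.0, -20.0)
        with pytest.raises(ValueError):
            trf.LagAxis(0.0, 10.0, 0.0)


class TestBuildDesign:
    def test_single_zero_lag_design_is_unshifted_features(self):
        feats = _features(300)
        design = trf.build_design(feats, trf.LagAxis(0.0, 1.0, 1.0))
        assert np.array_equal(design[:, 0], feats.fundamental)
        assert np.array_equal(design[:, 2], feats.envelope_mod)

    def test_impulse_lands_at_lag_index(self):
        f = np.zeros(100)
        f[0] = 1.0
        feats = StimulusFeatures(f, np.zeros(100), FS)
        axis = trf.LagAxis(10.0, 11.0, 1.0)
        design = trf.build_design(feats, axis)
        assert design[10, 0] == 1.0  # column for tau = 10 ms
        assert design[11, 1] == 1.0  # column for tau = 11 ms
        assert design.sum() == 2.0

    def test_negative_lags_reach_into_the_future(self):
        f = np.zeros(50)
        f[20] = 1.0
        feats = StimulusFeatures(f, np.zeros(50), FS)
        design = trf.build_design(feats, trf.LagAxis(-5.0, -4.0, 1.0))
        # tau = -5 ms pairs the response at t with the feature at t + 5
        assert design[15, 0] == 1.0


def closed_form_ridge(x, y, lam):
    """Independent oracle: explicit inverse of the regularized normal matrix."""
    p = x.shape[1]
    return np.linalg.inv(x.T @ x + lam * np.eye(p)) @ x.T @ y


class TestFitRidge:
    def test_matches_closed_form_on_random_problems(self):
        axis = trf.LagAxis(0.0, 2.0, 1.0)  # 3 lags -> 6 columns
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((50, 6))
            y = rng.standard_normal(50)
            model = trf.fit_ridge(x, y[None, :], 1.0, lag_axis=axis)
            w = np.concatenate([model.alpha[:, 0], model.beta[:, 0]])
            w_ref = closed_form_ridge(x, y, 1.0)
            assert np.linalg.norm(w - w_ref) / np.linalg.norm(w_ref) < 1e-8

    def test_exact_least_squares_on_noiseless_single_lag(self):
        feats = _features(1000)
        axis = trf.LagAxis(0.0, 1.0, 1.0)
        design = trf.build_design(feats, axis)
        y = 2.0 * feats.fundamental
        model = trf.fit_ridge(design, y[None, :], 0.0, lag_axis=axis)
        assert model.alpha[0, 0] == pytest.approx(2.0, abs=1e-8)
        assert abs(model.beta[0, 0]) < 1e-6

    def test_infinite_shrinkage_limit(self):
        feats = _features(500)
        axis = trf.LagAxis(0.0, 4.0, 1.0)
        design = trf.build_design(feats, axis)
        y = feats.fundamental[None, :]
        model = trf.fit_ridge(design, y, 1e12, lag_axis=axis)
        assert np.max(np.abs(model.alpha)) < 1e-6

    def test_coefficient_norm_nonincreasing_in_lambda(self):
        feats = _features(800, seed=3)
        axis = trf.LagAxis(-5.0, 20.0, 1.0)
        design = trf.build_design(feats, axis)
        rng = np.random.default_rng(3)
        y = rng.standard_normal(800)[None, :]
        norms = []
        for lam in (0.0, 0.1, 1.0, 10.0, 100.0):
            m = trf.fit_ridge(design, y, lam, lag_axis=axis)
            norms.append(np.sqrt(np.sum(m.alpha ** 2) + np.sum(m.beta ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_negative_lambda_and_zero_design_rejected(self):
        design = np.ones((10, 2))
        with pytest.raises(ValueError):
            trf.fit_ridge(design, np.zeros((1, 10)), -1.0,
                          lag_axis=trf.LagAxis(0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            trf.fit_ridge(np.zeros((10, 2)), np.zeros((1, 10)), 1.0,
                          lag_axis=trf.LagAxis(0.0, 1.0, 1.0))

    def test_solver_refit_equals_direct_fit(self):
        feats = _features(2000, seed=4)
        axis = trf.LagAxis()
        rng = np.random.default_rng(4)
        y = rng.standard_normal((2, 2000))
        direct = trf.fit_ridge(trf.build_design(feats, axis), y, 1.0,
                               lag_axis=axis)
        solver = trf.RidgeSolver(feats, axis, 1.0)
        refit = solver.fit(y)
        assert np.allclose(refit.alpha, direct.alpha, atol=1e-10)
        assert np.allclose(refit.beta, direct.beta, atol=1e-10)


class TestMagnitudeAndEnvelope:
    def test_single_channel_magnitude_is_absolute_coefficients(self):
        axis = trf.LagAxis(0.0, 4.0, 1.0)
        coefs = np.array([[1.0], [-2.0], [3.0], [-4.0], [0.5]])
        model = trf.TRFModel(coefs, np.zeros_like(coefs), axis, 1.0, FS)
        mag = trf.trf_magnitude(model)
        assert np.array_equal(mag["fundamental"], np.abs(coefs[:, 0]))

    def test_sign_flipped_channels_average_to_common_magnitude(self):
        axis = trf.LagAxis(0.0, 2.0, 1.0)
        c = np.array([1.0, -2.0, 3.0])
        coefs = np.column_stack([c, -c])
        model = trf.TRFModel(coefs, np.zeros_like(coefs), axis, 1.0, FS)
        mag = trf.trf_magnitude(model)
        assert np.allclose(mag["fundamental"], np.abs(c))

    def test_dipole_triplet_uses_euclidean_norm(self):
        axis = trf.LagAxis(0.0, 0.5, 1.0)
        coefs = np.array([[3.0, 4.0, 0.0]])
        model = trf.TRFModel(coefs, np.zeros_like(coefs), axis, 1.0, FS)
        mag = trf.trf_magnitude(model, component_groups=[[0, 1, 2]])
        assert mag["fundamental"][0] == pytest.approx(5.0)

    def test_envelope_of_gabor_magnitude_peaks_at_modulator_centre(self):
        tau = trf.LagAxis().lags_ms()
        mag = np.abs(np.sin(2 * np.pi * 100 * tau * 1e-3)) * \
            np.exp(-0.5 * ((tau - 35) / 10) ** 2)
        env = trf.trf_envelope(mag, FS)
        assert abs(tau[np.argmax(env)] - 35.0) <= 2.0
        assert np.all(env >= 0)

    def test_constant_magnitude_envelope_flat_away_from_edges(self):
        env = trf.trf_envelope(np.full(141, 2.0), FS)
        assert np.allclose(env[30:-30], 2.0, rtol=0.05)

    def test_envelope_dominates_smoothed_magnitude(self):
        rng = np.random.default_rng(9)
        mag = np.abs(rng.standard_normal(141))
        env = trf.trf_envelope(mag, FS)
        sos = signal.butter(5, 70.0, btype="low", fs=FS, output="sos")
        smoothed = signal.sosfiltfilt(sos, mag)
        assert np.all(env >= smoothed - 0.15 * mag.max())

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            trf.trf_envelope(np.ones(10), FS)


class TestGenerativeConsistency:
    def test_noiseless_fit_recovers_generating_kernels_exactly(self):
        feats = _features(6000, seed=2)
        truth = sd.make_ground_truth(noise_sd=0.0, seed=2)
        rec = sd.gen_neural_response(feats, truth, attended=False)
        model = trf.estimate_trf(feats, rec, ridge_lambda=1e-10)
        est = model.alpha[:, 0]
        assert np.corrcoef(est, truth.kernel_alpha)[0, 1] > 0.999

    def test_serialization_round_trip(self, tmp_path):
        feats = _features(1500, seed=6)
        rng = np.random.default_rng(6)
        model = trf.fit_ridge(trf.build_design(feats, trf.LagAxis()),
                              rng.standard_normal((2, 1500)), 1.0)
        path = tmp_path / "model.tsv"
        trf.save_trf(model, path)
        loaded = trf.load_trf(path)
        assert np.allclose(loaded.alpha, model.alpha, atol=1e-10)
        assert np.allclose(loaded.beta, model.beta, atol=1e-10)
        assert loaded.ridge_lambda == model.ridge_lambda
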