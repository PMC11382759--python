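"""Temporal response functions by lagged ridge regression.

The forward model expresses the neural response at time ``t`` in channel
``v`` as a lagged linear combination of the two speech features,

    y_t(v) = sum_tau [ alpha_tau(v) * f_{t-tau} + beta_tau(v) * e_{t-tau} ],

with latencies ``tau`` running from -20 ms to 120 ms in 1 ms steps by
default.  The coefficient curves alpha and beta are the TRFs; they are
estimated per channel by ridge regression with a single fixed
regularisation parameter (lambda = 1 by default, applied to the raw,
unstandardised features).  Because the features live in the 70-120 Hz band
the TRFs oscillate near the fundamental rate; a smooth per-lag envelope —
analytic-signal magnitude followed by a zero-phase low-pass — summarises
their magnitude for peak analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .features import StimulusFeatures
from .neuralprep import NeuralRecording

__all__ = [
    "LagAxis",
    "TRFModel",
    "build_design",
    "fit_ridge",
    "estimate_trf",
    "trf_magnitude",
    "trf_envelope",
    "save_trf",
    "load_trf",
]

FEATURE_NAMES = ("fundamental", "envelope_mod")


@dataclass(frozen=True)
class LagAxis:
    """Latency axis of the forward model (ms)."""

    tau_min_ms: float = -20.0
    tau_max_ms: float = 120.0
    step_ms: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau_min_ms < self.tau_max_ms:
            raise ValueError("tau_min must be below tau_max")
        if self.step_ms <= 0:
            raise ValueError("lag step must be positive")

    @property
    def n_lags(self) -> int:
        return int(round((self.tau_max_ms - self.tau_min_ms) / self.step_ms)) + 1

    def lags_ms(self) -> np.ndarray:
        return self.tau_min_ms + self.step_ms * np.arange(self.n_lags)

    def lag_samples(self, sample_rate_hz: float) -> np.ndarray:
        """Lags in samples; the step must be a whole number of samples."""
        step = self.step_ms * 1e-3 * sample_rate_hz
        if abs(step - round(step)) > 1e-9:
            raise ValueError("lag step is not an integer number of samples "
                             f"at {sample_rate_hz} Hz")
        lags = self.lags_ms() * 1e-3 * sample_rate_hz
        return np.round(lags).astype(int)


@dataclass
class TRFModel:
    """Fitted TRF coefficients for the two features.

    ``alpha`` and ``beta`` are (n_lags, n_channels) arrays for the
    fundamental waveform and the envelope modulation respectively.
    """

    alpha: np.ndarray
    beta: np.ndarray
    lag_axis: LagAxis
    ridge_lambda: float
    sample_rate_hz: float
    intercept: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.alpha.ndim == 2 and self.alpha.shape[0] == 1 and \
                self.lag_axis.n_lags == self.alpha.shape[1]:
            self.alpha = self.alpha.T
            self.beta = self.beta.T
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must share shape")
        if self.alpha.shape[0] != self.lag_axis.n_lags:
            raise ValueError("coefficient rows must match the lag axis")

    @property
    def n_channels(self) -> int:
        return self.alpha.shape[1]

    def coefficients(self, feature: str) -> np.ndarray:
        if feature == "fundamental":
            return self.alpha
        if feature == "envelope_mod":
            return self.beta
        raise KeyError(feature)


def _lagged_matrix(x: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    t = x.size
    out = np.zeros((t, shifts.size))
    for j, s in enumerate(shifts):
        if s >= 0:
            out[s:, j] = x[:t - s] if s else x
        else:
            out[:t + s, j] = x[-s:]
    return out


def build_design(features: StimulusFeatures, lag_axis: LagAxis) -> np.ndarray:
    """Lagged design matrix, time x (2 * n_lags).

    Column ``k`` of the first block holds the fundamental waveform delayed
    by lag ``tau_k`` (samples falling outside the recording are
    zero-filled); the second block holds the envelope modulation likewise.
    Column order is stable: all fundamental lags from tau_min to tau_max,
    then all envelope-modulation lags.
    """
    shifts = lag_axis.lag_samples(features.sample_rate_hz)
    return np.hstack([_lagged_matrix(features.fundamental, shifts),
                      _lagged_matrix(features.envelope_mod, shifts)])


def fit_ridge(
    design: np.ndarray,
    response: NeuralRecording | np.ndarray,
    ridge_lambda: float = 1.0,
    *,
    lag_axis: LagAxis = LagAxis(),
    sample_rate_hz: float | None = None,
    fit_intercept: bool = False,
) -> TRFModel:
    """Per-channel ridge solution  w = (X'X + lambda I)^{-1} X'y.

    The penalty acts on the raw lagged features; the optional intercept is
    left unpenalised (implemented by centring).  The solve is a symmetric
    positive-definite factorisation of the Gram matrix, deterministic for
    fixed inputs.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be non-negative")
    x = np.asarray(design, dtype=float)
    if isinstance(response, NeuralRecording):
        y = response.samples.T
        fs = response.sample_rate_hz
    else:
        y = np.asarray(response, dtype=float)
        y = y.T if y.ndim == 2 else y[:, None]
        fs = sample_rate_hz or 1000.0
    if x.shape[0] != y.shape[0]:
        raise ValueError("design rows must equal response samples")
    if not np.any(x):
        raise ValueError("degenerate all-zero design")
    n_lags = lag_axis.n_lags
    if x.shape[1] != 2 * n_lags:
        raise ValueError("design width does not match the lag axis")

    intercept = None
    if fit_intercept:
        x_mean, y_mean = x.mean(axis=0), y.mean(axis=0)
        x = x - x_mean
        y = y - y_mean
    gram = x.T @ x
    gram[np.diag_indices_from(gram)] += ridge_lambda
    w = linalg.solve(gram, x.T @ y, assume_a="pos")
    if fit_intercept:
        intercept = y_mean - x_mean @ w
    return TRFModel(alpha=w[:n_lags], beta=w[n_lags:], lag_axis=lag_axis,
                    ridge_lambda=ridge_lambda, sample_rate_hz=fs,
                    intercept=intercept)


class RidgeSolver:
    """Pre-factorised ridge solver for refitting many responses to one design.

    In a fixed-stimulus experiment every subject shares the same lagged
    design, so the Gram matrix ``X'X + lambda I`` can be factorised once
    and each subject's fit reduces to the cross-product ``X'y`` plus two
    triangular solves.  Results are identical to :func:`fit_ridge`.
    """

    def __init__(self, features: StimulusFeatures, lag_axis: LagAxis = LagAxis(),
                 ridge_lambda: float = 1.0):
        if ridge_lambda < 0:
            raise ValueError("ridge_lambda must be non-negative")
        self.features = features
        self.lag_axis = lag_axis
        self.ridge_lambda = ridge_lambda
        self._shifts = lag_axis.lag_samples(features.sample_rate_hz)
        design = build_design(features, lag_axis)
        gram = design.T @ design
        gram[np.diag_indices_from(gram)] += ridge_lambda
        self._cho = linalg.cho_factor(gram, lower=True)

    def _xty(self, y: np.ndarray) -> np.ndarray:
        t = y.shape[0]
        out = np.empty((2 * self._shifts.size, y.shape[1]))
        for b, x in enumerate((self.features.fundamental, self.features.envelope_mod)):
            for j, s in enumerate(self._shifts):
                row = b * self._shifts.size + j
                if s >= 0:
                    out[row] = (x[:t - s] @ y[s:]) if s else (x @ y)
                else:
                    out[row] = x[-s:] @ y[:t + s]
        return out

    def fit(self, response: NeuralRecording | np.ndarray) -> TRFModel:
        if isinstance(response, NeuralRecording):
            y = response.samples.T
            fs = response.sample_rate_hz
        else:
            y = np.asarray(response, dtype=float)
            y = y.T if y.ndim == 2 else y[:, None]
            fs = self.features.sample_rate_hz
        if y.shape[0] != self.features.n_samples:
            raise ValueError("response length must match the design")
        n_lags = self.lag_axis.n_lags
        w = linalg.cho_solve(self._cho, self._xty(y))
        return TRFModel(alpha=w[:n_lags], beta=w[n_lags:], lag_axis=self.lag_axis,
                        ridge_lambda=self.ridge_lambda, sample_rate_hz=fs)


def estimate_trf(
    features: StimulusFeatures,
    recording: NeuralRecording,
    lag_axis: LagAxis = LagAxis(),
    ridge_lambda: float = 1.0,
) -> TRFModel:
    """Convenience wrapper: build the lagged design and fit the ridge model."""
    if features.sample_rate_hz != recording.sample_rate_hz:
        raise ValueError("features and recording must share a sample rate")
    if features.n_samples != recording.n_times:
        raise ValueError("features and recording must be aligned (equal length)")
    design = build_design(features, lag_axis)
    return fit_ridge(design, recording, ridge_lambda, lag_axis=lag_axis,
                     sample_rate_hz=recording.sample_rate_hz)


def trf_magnitude(
    model: TRFModel,
    component_groups: list[list[int]] | None = None,
) -> dict[str, np.ndarray]:
    """Channel-averaged per-lag coefficient magnitude for each feature.

    For source points represented by 3-component dipole triplets, pass the
    channel-index triplets in ``component_groups``: the Euclidean norm is
    taken across each triplet before the unweighted average over groups.
    By default every channel is its own group (plain |coefficient| mean).
    """
    out: dict[str, np.ndarray] = {}
    for name in FEATURE_NAMES:
        coef = model.coefficients(name)
        if component_groups is None:
            out[name] = np.abs(coef).mean(axis=1)
        else:
            norms = [np.linalg.norm(coef[:, g], axis=1) for g in component_groups]
            out[name] = np.mean(norms, axis=0)
    return out


def trf_envelope(
    magnitude: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = 70.0,
    order: int = 5,
) -> np.ndarray:
    """Smooth envelope of a per-lag magnitude curve.

    Magnitude of the analytic signal of the lag series (treated at the
    neural sample rate), then a zero-phase Butterworth low-pass below the
    fundamental band so the residual f0-rate oscillation is removed.  Tiny
    negative values created by the filter are clipped to zero.
    """
    m = np.asarray(magnitude, dtype=float)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sample_rate_hz,
                        output="sos")
    padlen = 3 * (2 * order + 1)
    if m.size <= padlen:
        raise ValueError("magnitude sequence too short for the envelope filter")
    env = signal.sosfiltfilt(sos, np.abs(signal.hilbert(m)))
    return np.clip(env, 0.0, None)


def model_envelopes(model: TRFModel,
                    component_groups: list[list[int]] | None = None
                    ) -> dict[str, np.ndarray]:
    """Magnitude envelopes for both features of a fitted model."""
    mags = trf_magnitude(model, component_groups)
    return {name: trf_envelope(m, model.sample_rate_hz) for name, m in mags.items()}


# ---------------------------------------------------------------------------
# serialization: delimited text + JSON sidecar


def save_trf(model: TRFModel, path: str) -> None:
    lags = model.lag_axis.lags_ms()
    cols = [lags[:, None], model.alpha, model.beta]
    header = ["lag_ms"]
    header += [f"alpha_ch{c}" for c in range(model.n_channels)]
    header += [f"beta_ch{c}" for c in range(model.n_channels)]
    np.savetxt(path, np.hstack(cols), delimiter="\t", header="\t".join(header))
    sidecar = {
        "ridge_lambda": model.ridge_lambda,
        "sample_rate_hz": model.sample_rate_hz,
        "lag_axis": {"tau_min_ms": model.lag_axis.tau_min_ms,
                     "tau_max_ms": model.lag_axis.tau_max_ms,
                     "step_ms": model.lag_axis.step_ms},
        "n_channels": model.n_channels,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_trf(path: str) -> TRFModel:
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    data = np.loadtxt(path, delimiter="\t")
    n_ch = meta["n_channels"]
    axis = LagAxis(**meta["lag_axis"])
    return TRFModel(alpha=data[:, 1:1 + n_ch], beta=data[:, 1 + n_ch:1 + 2 * n_ch],
                    lag_axis=axis, ridge_lambda=meta["ridge_lambda"],
                    sample_rate_hz=meta["sample_rate_hz"])
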