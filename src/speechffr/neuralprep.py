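"""Post-acquisition conditioning of continuous neural recordings.

The speech-FFR pipeline expects neural time series that have been power-line
notched, brought to a common 1000 Hz rate, band-passed to the
fundamental-frequency range (70–120 Hz) and aligned to the stimulus,
compensating the fixed acoustic-tube delay between sound generation and its
arrival at the ear.  All operations are per-channel and channel-order
preserving; every applied step is appended to the recording's provenance
chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .features import StimulusFeatures

__all__ = ["NeuralRecording", "notch", "resample", "ffr_bandpass", "align"]

#: window (ms) at each end flagged as potentially contaminated by
#: zero-phase filter edge effects
EDGE_GUARD_MS = 100.0


@dataclass
class NeuralRecording:
    """Multichannel uniform-rate neural time series with alignment metadata."""

    samples: np.ndarray  # channels x time
    sample_rate_hz: float
    alignment_offset_ms: float = 6.0  # stimulus lead (acoustic-tube delay)
    channel_roles: list[str] | None = None
    processing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if not np.isfinite(self.alignment_offset_ms):
            raise ValueError("alignment offset must be finite")
        if self.channel_roles is None:
            self.channel_roles = ["sensor"] * self.n_channels
        if len(self.channel_roles) != self.n_channels:
            raise ValueError("one role per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.sample_rate_hz

    def _derive(self, samples: np.ndarray, step: str, **changes) -> "NeuralRecording":
        return replace(self, samples=samples,
                       processing=self.processing + [step], **changes)


def notch(recording: NeuralRecording, freq_hz: float = 50.0,
          transition_bandwidth_hz: float = 0.5,
          notch_width_hz: float = 2.0) -> NeuralRecording:
    """Remove a power-line component with a linear-phase FIR band-stop.

    The filter is a windowed-sinc (firwin) band-stop of ``notch_width_hz``
    around ``freq_hz`` with the given transition bandwidth.  Being linear
    phase and applied with centred convolution, the group delay cancels and
    the step is effectively zero phase.
    """
    fs = recording.sample_rate_hz
    if freq_hz >= fs / 2:
        raise ValueError("notch frequency must lie below Nyquist")
    numtaps = int(np.ceil(3.3 * fs / transition_bandwidth_hz)) | 1
    half = notch_width_hz / 2
    taps = signal.firwin(numtaps, [freq_hz - half, freq_hz + half], fs=fs)
    out = np.empty_like(recording.samples)
    for c in range(recording.n_channels):
        out[c] = signal.fftconvolve(recording.samples[c], taps, mode="same")
    return recording._derive(out, f"notch({freq_hz} Hz, tbw {transition_bandwidth_hz} Hz)")


def resample(recording: NeuralRecording, target_rate_hz: float) -> NeuralRecording:
    """Anti-aliased polyphase down-sampling to ``target_rate_hz``.

    Upsampling is outside the contract of this step and rejected.
    """
    fs = recording.sample_rate_hz
    if target_rate_hz > fs:
        raise ValueError("resample only down-samples; target exceeds current rate")
    if target_rate_hz == fs:
        return recording._derive(recording.samples.copy(), "resample(identity)")
    frac = Fraction(target_rate_hz / fs).limit_denominator(10000)
    out = signal.resample_poly(recording.samples, frac.numerator,
                               frac.denominator, axis=1)
    return recording._derive(out, f"resample({fs} -> {target_rate_hz} Hz)",
                             sample_rate_hz=target_rate_hz)


def ffr_bandpass(recording: NeuralRecording, low_hz: float = 70.0,
                 high_hz: float = 120.0, order: int = 2) -> NeuralRecording:
    """Zero-phase Butterworth band-pass to the fundamental-frequency range."""
    fs = recording.sample_rate_hz
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError("invalid band for this sample rate")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, recording.samples, axis=1, padtype="even")
    return recording._derive(out, f"ffr_bandpass({low_hz}-{high_hz} Hz, order {order})")


def align(recording: NeuralRecording, features: StimulusFeatures,
          tube_delay_ms: float | None = None
          ) -> tuple[NeuralRecording, StimulusFeatures]:
    """Compensate the acoustic-tube delay and trim to common support.

    The sound reaches the ear ``tube_delay_ms`` after its nominal onset, so
    the feature stream is delayed by that amount relative to the recording
    (a negative delay advances it) and both are trimmed to the overlapping
    samples.  Applying the delay and then its negative restores the
    original pairing on the shared support.
    """
    if features.sample_rate_hz != recording.sample_rate_hz:
        raise ValueError("recording and features must share a sample rate")
    if tube_delay_ms is None:
        tube_delay_ms = recording.alignment_offset_ms
    fs = recording.sample_rate_hz
    d = int(round(tube_delay_ms * 1e-3 * fs))
    n = min(recording.n_times, features.n_samples)
    if abs(d) >= n:
        raise ValueError("delay exceeds signal length")
    if d >= 0:
        rec_sl, feat_sl = slice(d, n), slice(0, n - d)
    else:
        rec_sl, feat_sl = slice(0, n + d), slice(-d, n)
    trimmed = recording._derive(recording.samples[:, rec_sl],
                                f"align(delay {tube_delay_ms} ms)",
                                alignment_offset_ms=0.0)
    return trimmed, features.slice(feat_sl.start, feat_sl.stop)
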