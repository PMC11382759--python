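"""Synthetic stimuli, neural responses and cohorts with known ground truth.

Every downstream stage of the speech-FFR pipeline is validated by parameter
recovery against this generator:

* a slowly wandering fundamental-frequency trajectory confined to a
  low-pitched speaker's range (70–120 Hz by default),
* a harmonic voice following that trajectory, whose higher harmonics are
  amplitude-modulated at the fundamental rate (the glottal-pulse cue the
  envelope-modulation feature extracts),
* neural responses formed by convolving the stimulus features with known
  TRF kernels — scaled by an attention gain when the voice is attended —
  plus additive white or 1/f-shaped noise,
* cohorts of participant profiles satisfying the musician / non-musician
  questionnaire criteria by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cohort import ParticipantProfile, classify_participant
from .features import F0Track, StimulusFeatures
from .neuralprep import NeuralRecording
from .trf import LagAxis, build_design

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "gen_f0_trajectory",
    "gen_voice",
    "gen_neural_response",
    "gen_cohort",
    "noise_sd_for_snr",
    "write_wav",
]


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Generating kernels and nuisance parameters for one synthetic subject.

    ``kernel_alpha`` / ``kernel_beta`` span ``lag_axis`` (same axis later
    used for estimation); ``attention_gain`` multiplies the stimulus-driven
    response when the voice is attended and must be at least 1;
    ``noise_exponent`` shapes the additive noise spectrum as 1/f^exponent
    (0 = white).
    """

    kernel_alpha: np.ndarray
    kernel_beta: np.ndarray
    lag_axis: LagAxis
    sample_rate_hz: float
    peak_latency_ms: float
    attention_gain: float = 1.5
    noise_sd: float = 1.0
    noise_exponent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.kernel_alpha = np.asarray(self.kernel_alpha, dtype=float)
        self.kernel_beta = np.asarray(self.kernel_beta, dtype=float)
        n = self.lag_axis.n_lags
        if self.kernel_alpha.size != n or self.kernel_beta.size != n:
            raise ValueError("kernels must span the lag axis")
        if self.attention_gain < 1:
            raise ValueError("attention_gain must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_ground_truth(
    lag_axis: LagAxis = LagAxis(),
    sample_rate_hz: float = 1000.0,
    peak_latency_ms: float = 35.0,
    carrier_hz: float = 95.0,
    width_ms: float = 10.0,
    alpha_amplitude: float = 1.0,
    beta_amplitude: float = 0.6,
    attention_gain: float = 1.5,
    noise_sd: float = 1.0,
    noise_exponent: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Gabor-shaped TRF kernels: a Gaussian bump at ``peak_latency_ms``
    carrying an oscillation near the fundamental rate, mirroring the
    oscillatory cortical speech-FFR whose envelope peaks at ~30–40 ms."""
    tau = lag_axis.lags_ms()
    gauss = np.exp(-0.5 * ((tau - peak_latency_ms) / width_ms) ** 2)
    osc = np.cos(2 * np.pi * carrier_hz * (tau - peak_latency_ms) * 1e-3)
    kernel = gauss * osc
    return GroundTruth(kernel_alpha=alpha_amplitude * kernel,
                       kernel_beta=beta_amplitude * kernel,
                       lag_axis=lag_axis, sample_rate_hz=sample_rate_hz,
                       peak_latency_ms=peak_latency_ms,
                       attention_gain=attention_gain, noise_sd=noise_sd,
                       noise_exponent=noise_exponent, seed=seed)


# ---------------------------------------------------------------------------
# stimulus


def gen_f0_trajectory(
    duration_s: float,
    f0_range_hz: tuple[float, float] = (70.0, 120.0),
    wander_rate_hz: float = 0.5,
    seed: int = 0,
    sample_rate_hz: float = 8000.0,
) -> F0Track:
    """Smooth random fundamental-frequency trajectory confined to a range.

    Low-pass-filtered Gaussian noise is squashed by tanh into the interval,
    so the track never leaves ``f0_range_hz`` and its spectral content is
    controlled by ``wander_rate_hz`` (0 gives a constant track at the
    interval midpoint).
    """
    lo, hi = f0_range_hz
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not (0 < lo < hi < sample_rate_hz / 2):
        raise ValueError("f0 range must be within (0, Nyquist) and ordered")
    n = int(round(duration_s * sample_rate_hz))
    mid, half = (hi + lo) / 2, (hi - lo) / 2
    if wander_rate_hz == 0:
        f0 = np.full(n, mid)
    else:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        sos = signal.butter(2, wander_rate_hz, btype="low", fs=sample_rate_hz,
                            output="sos")
        z = signal.sosfiltfilt(sos, z)
        sd = z.std()
        z = z / sd if sd > 0 else z
        f0 = mid + half * np.tanh(z)
    return F0Track(f0, np.ones(n, dtype=bool), sample_rate_hz)


def gen_voice(
    f0_track: F0Track,
    n_harmonics: int = 5,
    sample_rate_hz: float | None = None,
    seed: int = 0,
    modulation_depth: float = 1.0,
    modulation_detune_hz: float = 0.7,
) -> np.ndarray:
    """Harmonic complex following an f0 track, AM-modulated at the f0 rate.

    Harmonic ``k`` has amplitude 1/k; harmonics above the fundamental are
    amplitude-modulated at the instantaneous fundamental rate so that the
    envelope-modulation feature has something to detect (a caricature of
    the glottal pulse train).  The modulation phase precesses slowly
    relative to the fundamental (``modulation_detune_hz``), emulating the
    varying glottal pulse shape of natural speech; this keeps the
    fundamental waveform and the envelope modulation essentially
    uncorrelated on long signals while the modulation rate stays inside
    the f0 band.  Harmonics that would exceed 95% of Nyquist are truncated
    with a warning.  Each harmonic additionally carries a slow random phase
    drift (seeded), standing in for the changing harmonic phase relations
    of a real vocal tract; without it the beating of adjacent harmonics
    would stay rigidly phase-locked to the fundamental and the two
    extracted features would be artificially correlated.
    """
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    fs = sample_rate_hz or f0_track.sample_rate_hz
    if fs != f0_track.sample_rate_hz:
        raise ValueError("sample rate must match the f0 track")
    f0 = f0_track.f0_hz
    rng = np.random.default_rng(seed)
    phase = 2 * np.pi * np.cumsum(f0) / fs
    drift = 2 * np.pi * modulation_detune_hz * np.arange(f0.size) / fs

    def _phase_drift() -> np.ndarray:
        # low-passed noise spanning a few radians on a sub-second timescale
        if f0.size < 64:
            return np.full(f0.size, rng.uniform(0, 2 * np.pi))
        z = rng.standard_normal(f0.size)
        sos = signal.butter(2, 2.0, btype="low", fs=fs, output="sos")
        z = signal.sosfiltfilt(sos, z)
        sd = z.std()
        return rng.uniform(0, 2 * np.pi) + np.pi * (z / sd if sd > 0 else z)

    mod = (1 - modulation_depth) + modulation_depth * 0.5 * (
        1 + np.cos(phase + drift + _phase_drift()))

    out = np.zeros_like(phase)
    kept = 0
    for k in range(1, n_harmonics + 1):
        if k * f0.max() > 0.95 * fs / 2:
            warnings.warn(f"harmonic {k} exceeds 95% of Nyquist; truncating")
            break
        kept = k
        if k == 1:
            # the fundamental stays phase-coherent so its instantaneous
            # frequency follows the f0 track exactly
            out += np.sin(phase + rng.uniform(0, 2 * np.pi))
        else:
            out += np.sin(k * phase + _phase_drift()) / k * mod
    if kept == 0:
        raise ValueError("fundamental itself exceeds Nyquist")
    peak = np.abs(out).max()
    return 0.9 * out / peak if peak > 0 else out


# ---------------------------------------------------------------------------
# neural response


def _shaped_noise(rng: np.random.Generator, shape: tuple[int, ...],
                  exponent: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    if exponent == 0:
        return white
    freqs = np.fft.rfftfreq(shape[-1])
    gain = np.ones_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2)
    gain[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=shape[-1], axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.where(sd > 0, sd, 1.0)


def noise_sd_for_snr(clean: np.ndarray, snr_db: float) -> float:
    """Noise SD making the broadband SNR of ``clean`` equal ``snr_db``."""
    return float(np.std(clean) * 10 ** (-snr_db / 20))


def gen_neural_response(
    features: StimulusFeatures,
    truth: GroundTruth,
    attended: bool = True,
    n_channels: int = 1,
    seed: int | None = None,
    acoustic_delay_ms: float = 0.0,
) -> NeuralRecording:
    """Neural recording generated from the forward model.

    Each channel is ``g * (alpha (*) f + beta (*) e) + noise`` where ``g``
    is the attention gain when the voice is attended and 1 otherwise, and
    ``(*)`` is the lagged sum of the forward model (realised through the
    same design matrix used for estimation, so generation and fitting are
    exactly consistent).  Channels differ only in independent noise draws.
    ``acoustic_delay_ms`` delays the features before convolution, emulating
    the sound's travel time through the delivery tubes; the recording's
    ``alignment_offset_ms`` records it for later compensation.
    """
    if features.sample_rate_hz != truth.sample_rate_hz:
        raise ValueError("features and ground truth must share a sample rate")
    shifts = truth.lag_axis.lag_samples(truth.sample_rate_hz)
    if shifts.max() >= features.n_samples:
        raise ValueError("kernel support longer than the signal")
    feats = features
    if acoustic_delay_ms:
        d = int(round(acoustic_delay_ms * 1e-3 * features.sample_rate_hz))
        f = np.concatenate([np.zeros(d), features.fundamental[:-d]])
        e = np.concatenate([np.zeros(d), features.envelope_mod[:-d]])
        feats = StimulusFeatures(f, e, features.sample_rate_hz)
    design = build_design(feats, truth.lag_axis)
    clean = design @ np.concatenate([truth.kernel_alpha, truth.kernel_beta])
    gain = truth.attention_gain if attended else 1.0
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    noise = truth.noise_sd * _shaped_noise(rng, (n_channels, clean.size),
                                           truth.noise_exponent)
    samples = gain * clean[None, :] + noise
    return NeuralRecording(samples, truth.sample_rate_hz,
                           alignment_offset_ms=acoustic_delay_ms,
                           processing=["synthetic"])


# ---------------------------------------------------------------------------
# cohort


def _musician(rng: np.random.Generator, i: int) -> ParticipantProfile:
    age = float(rng.integers(4, 8))
    return ParticipantProfile(
        subject_id=f"M{i:02d}", starting_age_years=age,
        total_training_years=float(rng.integers(10, 21)),
        currently_training=True,
        hours_per_week=float(np.round(rng.uniform(2, 14), 1)),
        n_instruments_lifetime=int(rng.integers(1, 5)),
        percent_correct=np.nan)


def _nonmusician(rng: np.random.Generator, i: int) -> ParticipantProfile:
    if rng.random() < 0.6:  # never played an instrument
        return ParticipantProfile(
            subject_id=f"N{i:02d}", starting_age_years=None,
            total_training_years=0.0, currently_training=False,
            hours_per_week=0.0, n_instruments_lifetime=0,
            percent_correct=np.nan)
    return ParticipantProfile(
        subject_id=f"N{i:02d}", starting_age_years=float(rng.integers(7, 16)),
        total_training_years=float(np.round(rng.uniform(0.5, 3.0), 1)),
        currently_training=False, hours_per_week=0.0,
        n_instruments_lifetime=int(rng.integers(1, 3)),
        percent_correct=np.nan)


def _neutral(rng: np.random.Generator, i: int) -> ParticipantProfile:
    # violates at least one criterion of each column: trained more than
    # three years (not a non-musician) but fewer than ten (not a musician)
    training = bool(rng.random() < 0.5)
    return ParticipantProfile(
        subject_id=f"X{i:02d}", starting_age_years=float(rng.integers(5, 13)),
        total_training_years=float(rng.integers(4, 10)),
        currently_training=training,
        hours_per_week=float(np.round(rng.uniform(0.5, 5), 1)) if training else 0.0,
        n_instruments_lifetime=int(rng.integers(1, 4)),
        percent_correct=np.nan)


def gen_cohort(
    n_musicians: int = 18,
    n_nonmusicians: int = 25,
    n_neutral: int = 9,
    seed: int = 0,
    behavior_mean: float = 72.0,
    behavior_sd: float = 12.0,
) -> list[ParticipantProfile]:
    """Synthetic cohort whose profiles classify into the requested groups.

    The default sizes mirror a mid-sized MEG study (18 musicians, 25
    non-musicians, 9 neutral).  Behavioural comprehension scores are drawn
    from one common normal distribution for all groups, clipped to
    [25, 100] (25% is the four-alternative chance level), since no group
    difference in comprehension is part of the generating model.
    """
    if min(n_musicians, n_nonmusicians, n_neutral) < 0:
        raise ValueError("group counts must be non-negative")
    rng = np.random.default_rng(seed)
    cohort: list[ParticipantProfile] = []
    for i in range(n_musicians):
        cohort.append(_musician(rng, i))
    for i in range(n_nonmusicians):
        cohort.append(_nonmusician(rng, i))
    for i in range(n_neutral):
        cohort.append(_neutral(rng, i))
    for p in cohort:
        p.percent_correct = float(np.clip(rng.normal(behavior_mean, behavior_sd),
                                          25.0, 100.0))
        p.group = classify_participant(p)
    expected = (["musician"] * n_musicians + ["non-musician"] * n_nonmusicians
                + ["neutral"] * n_neutral)
    assert [p.group for p in cohort] == expected
    return cohort


# ---------------------------------------------------------------------------
# audio output


def write_wav(path: str, waveform: np.ndarray, sample_rate_hz: float) -> None:
    """Write a mono waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    x = np.asarray(waveform, dtype=float)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * 0.98
    wavfile.write(path, int(sample_rate_hz), (x * 32767).astype(np.int16))
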