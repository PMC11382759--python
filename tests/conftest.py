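"""Shared fixtures: synthetic voices and features generated at test time."""

import numpy as np
import pytest

from speechffr import features as ft
from speechffr import synthdata as sd

AUDIO_RATE = 8000.0
NEURAL_RATE = 1000.0


@pytest.fixture(scope="session")
def voice20():
    """20 s synthetic harmonic voice with a wandering f0 in 70-120 Hz."""
    track = sd.gen_f0_trajectory(20.0, (70.0, 120.0), 0.5, seed=1,
                                 sample_rate_hz=AUDIO_RATE)
    voice = sd.gen_voice(track, n_harmonics=5, sample_rate_hz=AUDIO_RATE, seed=1)
    return track, voice


@pytest.fixture(scope="session")
def features20(voice20):
    """Extracted features of the 20 s voice, at audio rate."""
    _, voice = voice20
    return ft.extract_features(voice, AUDIO_RATE)


@pytest.fixture(scope="session")
def features20_neural(features20):
    """The 20 s features resampled to the neural rate (1000 Hz)."""
    return features20.resample(NEURAL_RATE)


@pytest.fixture(scope="session")
def voice60():
    """60 s voice and features for the slower recovery checks."""
    track = sd.gen_f0_trajectory(60.0, (70.0, 120.0), 0.5, seed=1,
                                 sample_rate_hz=AUDIO_RATE)
    voice = sd.gen_voice(track, n_harmonics=5, sample_rate_hz=AUDIO_RATE, seed=1)
    feats = ft.extract_features(voice, AUDIO_RATE)
    return track, voice, feats
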