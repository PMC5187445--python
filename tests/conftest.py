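"""Shared fixtures: small synthetic sounds and experiments.

Everything is generated programmatically at fixed seeds; session scope
keeps the expensive stimulus synthesis out of individual tests.
"""

import warnings

import numpy as np
import pytest

from strfshift import modulation, synthetic

AUDIO_RATE = 16000.0


@pytest.fixture(scope="session")
def speech_sound():
    """A 2 s speech-like synthetic sound at 16 kHz."""
    return synthetic.generate_speech_like_sound(2.0, AUDIO_RATE, seed=1)


@pytest.fixture(scope="session")
def speech_spectrogram(speech_sound):
    return modulation.compute_spectrogram(speech_sound, AUDIO_RATE)


@pytest.fixture(scope="session")
def small_experiment():
    """A tiny but complete synthetic experiment (5 trials, 8 electrodes)."""
    cfg = synthetic.SyntheticConfig(
        n_trials=5, n_electrodes=8, trial_duration=1.5, shift_lambda=0.8,
        snr=4.0, seed=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trialset, truth = synthetic.generate_experiment(cfg)
    return cfg, trialset, truth


@pytest.fixture(scope="session")
def random_auditory_stims():
    """Cheap stand-in auditory spectrograms (no audio synthesis): smooth
    non-negative random band amplitudes at 50 Hz, 8 bands."""
    rng = np.random.default_rng(7)
    from scipy.ndimage import uniform_filter1d

    stims = []
    for _ in range(6):
        v = rng.random((120, 8))
        stims.append(uniform_filter1d(v, 5, axis=0))
    return stims


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
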