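import numpy as np
import pytest

from wheezecount import AudioRecording, SimConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_440(rng):
    """1-second 440 Hz tone at 16 kHz with a little headroom."""
    t = np.arange(16_000) / 16_000
    return AudioRecording(0.5 * np.sin(2 * np.pi * 440.0 * t), 16_000)


@pytest.fixture
def small_sim_config():
    return SimConfig(n_breaths=4, wheeze_prob=0.5, pause_s=1.3, seed=7)


@pytest.fixture
def small_recording(small_sim_config):
    return generate_recording(small_sim_config)


def dominant_frequency(samples: np.ndarray, sample_rate: int) -> float:
    """FFT-peak oracle: frequency of the largest spectral magnitude."""
    spectrum = np.abs(np.fft.rfft(samples))
    freqs = np.fft.rfftfreq(len(samples), 1.0 / sample_rate)
    return float(freqs[np.argmax(spectrum)])
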