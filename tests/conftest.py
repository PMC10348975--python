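import numpy as np
import pytest

from eegcl import EEGRecording, StateSchedule, SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sine_recording():
    """Two-channel recording: 10 Hz and 6 Hz unit sines, 20 s at 500 Hz."""
    fs = 500.0
    t = np.arange(int(20 * fs)) / fs
    data = np.stack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 6 * t)])
    return EEGRecording(data=data, fs=fs, channel_labels=["a", "b"])


@pytest.fixture(scope="session")
def small_synth():
    """Short two-state synthetic recording shared across tests.

    60 s conscious + 60 s unconscious, 4 channels: enough windows for
    statistical contrasts while staying fast.
    """
    schedule = StateSchedule([(60.0, "conscious"), (60.0, "unconscious")])
    config = SynthConfig(n_channels=4, fs=500.0, seed=7)
    rec, labels = generate_recording(schedule, config)
    return schedule, config, rec, labels
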