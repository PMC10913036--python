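import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oscillotrack as ot
from oscillotrack.stimgen import TrainSpec, build_train, synthesize_click

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FS_EEG = 500.0
FS_AUDIO = 8000.0  # tests use a reduced audio rate for speed


@pytest.fixture(scope="session")
def fs_eeg():
    return FS_EEG


@pytest.fixture(scope="session")
def click_train_45():
    """30 s periodic (0% jitter) click train at 4.5 Hz."""
    spec = TrainSpec(rate=4.5, jitter=0.0, n_tokens=150, fs=FS_AUDIO, seed=11)
    return build_train(synthesize_click(FS_AUDIO), spec)


@pytest.fixture(scope="session")
def montage64():
    return ot.make_fixture_montage(64, seed=3)


@pytest.fixture(scope="session")
def envelope_45(click_train_45):
    return ot.stimulus_envelope(click_train_45.audio, click_train_45.fs, FS_EEG)[:15000]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)
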