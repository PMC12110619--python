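import numpy as np
import pytest

from bandopt import (
    ArtifactSpec,
    EEGRecording,
    generate_recording,
    inject_artifacts,
    study_spec,
)

FS = 500.0


@pytest.fixture(scope="session")
def clean_recording() -> EEGRecording:
    """60 s, 64-channel study-like recording: beta+alpha rhythms on 1/f noise."""
    return generate_recording(study_spec(seed=3, duration_s=60.0))


@pytest.fixture(scope="session")
def planted_recording(clean_recording):
    """The clean recording with exactly 3 bad channels planted.

    Channel 5 flatlines for 12 s, channel 20 carries strong 45–100 Hz muscle
    noise, channel 40 is replaced by independent noise (lost scalp contact).
    """
    art = ArtifactSpec(
        flat_channels=[(5, 10.0, 12.0)],
        muscle_rms=20e-6,
        muscle_channels=[20],
        decorrelated_channels=[40],
        seed=7,
    )
    rec, events = inject_artifacts(clean_recording, art)
    return rec, events


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
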