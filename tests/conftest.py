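import numpy as np
import pytest

from radarposture.scene_simulator import (
    SceneConfig,
    make_pulse,
    sample_participant,
    simulate_recording,
)


@pytest.fixture(scope="session")
def pulse():
    return make_pulse()


@pytest.fixture(scope="session")
def quiet_scene():
    """Noise-free scene with fixed clutter for deterministic signal tests."""
    return SceneConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def seated_recording(pulse):
    """10 s seated-working recording with the default noise level."""
    profile = sample_participant(11)
    return simulate_recording(
        SceneConfig(), profile, "seated_working", 10.08, seed=42,
        pulse=pulse, participant_id="P01",
    )


@pytest.fixture(scope="session")
def empty_recording_noisefree(pulse, quiet_scene):
    profile = sample_participant(12)
    return simulate_recording(
        quiet_scene, profile, "empty", 6.0, seed=43,
        pulse=pulse, participant_id="P01",
    )
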