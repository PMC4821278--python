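import numpy as np
import pytest

from batcensus import desk_config, simulate_emergence
from batcensus.workflow import observations_from_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_recording():
    """One desk-scale synthetic emergence shared across tests (seed fixed)."""
    return simulate_emergence(desk_config(42))


@pytest.fixture(scope="session")
def desk_observations(desk_recording):
    """Video-count observations of the shared emergence, low counts filtered."""
    return observations_from_recording(desk_recording)


@pytest.fixture
def unit_sine_clip():
    """Unit-amplitude sine over an integer number of cycles (sd = 1/sqrt(2))."""
    from batcensus import AudioClip

    t = np.arange(1000) / 1000.0
    return AudioClip(np.sin(2 * np.pi * 5 * t), sample_rate=1000.0)
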