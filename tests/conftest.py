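import numpy as np
import pytest
from hypothesis import settings

from iinfb.controller import EngineConfig
from iinfb.synth import SubjectProfile, simulate_closed_loop_session

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture()
def quiet_profile():
    """Noise- and artifact-free subject: every quantity is exact."""
    return SubjectProfile(
        contra_ratio_task=0.5,
        ipsi_ratio_task=1.0,
        responsiveness=0.0,
        noise_amp=0.0,
        blink_rate=0.0,
        emg_burst_rate=0.0,
        seed=17,
    )


@pytest.fixture(scope="session")
def default_session():
    """One full closed-loop session of the default subject (shared)."""
    recording, log = simulate_closed_loop_session(SubjectProfile(seed=11))
    return recording, log


@pytest.fixture(scope="session")
def engine_config():
    return EngineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
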