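import pytest

from stnmer import SimConfig, load_default_model, simulate_session

#: Reduced descent used by unit tests: same geometry and signal structure as
#: the default study conditions, but a shorter descent (5 to -5 mm) and 10 s
#: records so each synthetic session stays cheap.
SMALL = SimConfig(depth_start_mm=5.0, depth_stop_mm=-5.0,
                  record_duration_s=10.0, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_session():
    return simulate_session(SMALL)


@pytest.fixture(scope="session")
def default_model():
    return load_default_model()
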