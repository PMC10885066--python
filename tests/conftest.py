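import pytest
from hypothesis import HealthCheck, settings

import somnostat as sm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> sm.ModelParams:
    """Fitted all-night parameter set (the package defaults)."""
    return sm.ModelParams()


@pytest.fixture(scope="session")
def night_schedule() -> sm.Schedule:
    return sm.build_allnight_schedule()


@pytest.fixture(scope="session")
def night_traj(night_schedule, params) -> sm.Trajectory:
    return sm.simulate_protocol(night_schedule, params)


@pytest.fixture(scope="session")
def s_onset_16h(params) -> float:
    """Process S at habitual sleep onset after the 16-h wake phase."""
    return float(sm.buildup(16.0, params.S.U, params.S.B, params.S.T_build))
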