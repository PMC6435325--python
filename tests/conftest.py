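import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def track_session():
    """A 600 s pure-RUN session for place-field tests."""
    from hippostate.states import compute_speed
    from hippostate.synthetic_data import SimConfig, simulate_behavior

    cfg = SimConfig(seed=3, state_schedule=[("RUN", 600.0)])
    t, pos, states = simulate_behavior(cfg)
    speed = compute_speed(pos, t)
    velocity = np.gradient(pos, t)
    return {"t": t, "pos": pos, "speed": speed, "velocity": velocity,
            "config": cfg, "states": states}


@pytest.fixture(scope="session")
def sleep_lfp_session():
    """A QW+SWS session with ripples at the default SNR."""
    from hippostate.synthetic_data import (SimConfig, simulate_behavior,
                                           simulate_lfp)

    cfg = SimConfig(n_cells=5, seed=1, ripple_rate=0.25,
                    state_schedule=[("QW", 200.0), ("SWS", 400.0)])
    _, _, states = simulate_behavior(cfg)
    lfp, ripples = simulate_lfp(states, cfg)
    return {"lfp": lfp, "ripples": ripples, "states": states, "config": cfg}
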