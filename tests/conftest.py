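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


@pytest.fixture(scope="session")
def sw_layout():
    """S-W layout with exactly linear calibrations (zero jitter)."""
    from dogscreen.simulate import build_layout

    return build_layout("S-W", seed=11, jitter_scale=0.0)


@pytest.fixture(scope="session")
def ts_layout():
    from dogscreen.simulate import build_layout

    return build_layout("T-S", seed=11, jitter_scale=0.0)


@pytest.fixture(scope="session")
def all_layouts():
    from dogscreen.simulate import build_layout
    from dogscreen.gradients import LAYOUT_NAMES

    return {name: build_layout(name, seed=11, jitter_scale=0.0)
            for name in LAYOUT_NAMES}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
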