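import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from antsim.config import SimConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def tiny_config(**overrides) -> SimConfig:
    """A desk-scale configuration for unit tests: 6x4 vision, [72, 5, 3] net."""
    params = dict(
        arena_width=20.0, arena_height=20.0, dt=0.1, duration=10.0,
        hunger_period=1.0, food_count=8, eat_radius=1.0,
        initial_population=5, vision_width=6, vision_height=4,
        layer_sizes=(72, 5, 3), view_range=15.0, sample_interval=10,
        seed=7,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture
def config():
    return tiny_config()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
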