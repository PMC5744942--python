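import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from torusrange import PlotGeometry, RunConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_geometry():
    """A 60 x 50 m plot at 5 m cells (12 x 10 grid)."""
    return PlotGeometry(length_x=60.0, length_y=50.0, cell_size=5.0)


@pytest.fixture
def config():
    return RunConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
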