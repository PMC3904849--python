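import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from carbonscape import LandscapeConfig, make_landscape

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_landscape():
    """60x60 landscape with few habitat classes, shared across read-only tests."""
    cfg = LandscapeConfig(n_rows=60, n_cols=60, seed=11, n_habitat=8)
    return make_landscape(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
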