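import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220317)


@pytest.fixture
def random_networks():
    """A reproducible batch of networks covering the edge-case priors."""
    from beqbn import generate_random_networks

    return generate_random_networks(200, seed=11)
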