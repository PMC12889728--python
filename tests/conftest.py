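import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcgraph.parcellation import default_parcellation
from fcgraph.synthetic import CohortConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def parc60():
    return default_parcellation(60, 12)


@pytest.fixture(scope="session")
def parc24():
    return default_parcellation(24, 12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale config small enough for per-test pipeline runs."""
    return CohortConfig(
        n_participants=24,
        n_sites=2,
        n_parcels=24,
        n_networks=12,
        frames_per_run=60,
    )


def random_weight_matrix(rng, n, low=0.05, high=1.0):
    w = rng.uniform(low, high, (n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w
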