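import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20231127)


@pytest.fixture
def random_distance_matrix():
    """Factory for seeded random symmetric distance matrices."""
    from halobarcode import DistanceMatrix

    def make(n, seed, scale=1.0):
        r = np.random.default_rng(seed)
        a = r.random((n, n)) * scale
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 0.0)
        return DistanceMatrix([f"s{i:02d}" for i in range(n)], a)

    return make
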