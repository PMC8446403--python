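import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cogchange import simulate


@pytest.fixture(scope="session")
def default_cohort():
    cfg = simulate.default_config(seed=7)
    subjects, truth = simulate.generate_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def measure_specs():
    return simulate.default_measure_specs()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by repeated boolean matrix products
    (reach sets), independent of any graph library."""
    a = a.astype(bool)
    n = a.shape[0]
    step = a | np.eye(n, dtype=bool)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = np.eye(n, dtype=bool)
    for d in range(1, n + 1):
        new_reach = reach @ step
        newly = new_reach & ~reach
        if not newly.any():
            break
        dist[newly] = d
        reach = new_reach
    return dist
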