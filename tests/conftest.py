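import numpy as np
import pandas as pd
import pytest

from telesna import SimulationConfig, Thresholds, make_dataset, simulate_population
from telesna.simulate import random_weighted_network


def ts(*items):
    """Build a fix table from (animal, iso-timestamp, x, y) tuples."""
    return pd.DataFrame(items, columns=["animal_id", "timestamp", "x", "y"])


@pytest.fixture
def simple_dataset():
    """Two animals, co-located at 10:00/10:03 and apart at 12:00/12:02."""
    return make_dataset(ts(
        ("A", "2024-01-01T10:00:00Z", 0.0, 0.0),
        ("A", "2024-01-01T12:00:00Z", 0.0, 0.0),
        ("B", "2024-01-01T10:03:00Z", 3.0, 4.0),
        ("B", "2024-01-01T12:02:00Z", 500.0, 0.0),
    ))


@pytest.fixture(scope="session")
def planted_sim():
    """Planted-group simulation shared across tests (seed-fixed)."""
    return simulate_population(SimulationConfig(seed=11, duration_days=20))


@pytest.fixture(scope="session")
def planted_net(planted_sim):
    from telesna import build_network

    ds, _ = planted_sim
    return build_network(ds, Thresholds())


@pytest.fixture(scope="session")
def herd_net_60():
    """Larger connected modular herd for node-metric stability checks."""
    from telesna import build_network

    ds, _ = simulate_population(
        SimulationConfig(n_individuals=60, n_groups=6, duration_days=20, seed=11))
    return build_network(ds, Thresholds())


@pytest.fixture
def gnp40():
    return random_weighted_network(40, 0.3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
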