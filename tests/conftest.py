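import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# the virtual-search round-cap warning is expected on tiny test networks
logging.getLogger("netconcord.nulls").setLevel(logging.ERROR)


@pytest.fixture
def path_network():
    """A-B-C path with v_g = v_s = (1.0, 2.0, 0.1): the worked search example."""
    from netconcord.network import WeightedNetwork

    w = np.array([1.0, 2.0, 0.1])
    return WeightedNetwork(["A", "B", "C"], [("A", "B"), ("B", "C")], w, w.copy())


@pytest.fixture
def random_weighted_network():
    """Factory for small random connected-ish weighted networks."""
    from netconcord.network import WeightedNetwork

    def make(n_nodes=10, p_edge=0.3, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:02d}" for i in range(n_nodes)]
        edges = [
            (genes[i], genes[j])
            for i in range(n_nodes)
            for j in range(i + 1, n_nodes)
            if rng.uniform() < p_edge
        ]
        return WeightedNetwork(
            genes, edges, rng.normal(size=n_nodes), rng.normal(size=n_nodes)
        )

    return make
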