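import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import netprop as npg

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


@pytest.fixture
def path2():
    """Two nodes, one edge: the textbook Laplacian/kernel case."""
    return npg.build_network([("A", "B")])


@pytest.fixture
def triangle():
    return npg.build_network([("A", "B"), ("B", "C"), ("A", "C")])


def random_networks(n_er: int = 3, n_ba: int = 3, n: int = 50, seed0: int = 0):
    """Mixed Erdos-Renyi / preferential-attachment fixtures."""
    nets = []
    for i in range(n_er):
        nets.append(
            npg.generate_network(
                npg.FixtureSpec("erdos_renyi", n=n, params={"p": 0.1}, seed=seed0 + i)
            ).network
        )
    for i in range(n_ba):
        nets.append(
            npg.generate_network(
                npg.FixtureSpec("preferential_attachment", n=n, params={"m": 2}, seed=seed0 + 100 + i)
            ).network
        )
    return nets


@pytest.fixture(scope="session")
def random_nets():
    return random_networks()


@pytest.fixture
def identity_kernel():
    def make(net):
        return npg.KernelMatrix(np.eye(net.n_nodes), "identity", {}, net.node_order)

    return make
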