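import networkx as nx
import numpy as np
import pytest

from ckds.simulate import SimulationConfig, generate_dataset


def path3():
    g = nx.Graph()
    g.add_edge("a", "b", weight=0.8)
    g.add_edge("b", "c", weight=0.9)
    return g


@pytest.fixture
def toy_weighted_net():
    return path3()


@pytest.fixture(scope="session")
def small_dataset():
    """Ten simulated pairs at the default study conditions, shared by
    the slower integration checks."""
    return generate_dataset(SimulationConfig(), 10, 2024)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """Fifty simulated pairs at the default study conditions for the
    comparative benchmark checks."""
    return generate_dataset(SimulationConfig(), 50, 77)


def random_graphs(n_graphs, max_nodes=30, seed=0):
    """A mix of Erdős–Rényi and Barabási–Albert graphs (≤ max_nodes)."""
    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n_graphs):
        n = int(rng.integers(5, max_nodes + 1)) if i % 10 == 0 else int(rng.integers(5, 17))
        gseed = int(rng.integers(2**31 - 1))
        if i % 2 == 0:
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.6)), seed=gseed)
        else:
            m = int(rng.integers(1, max(2, n // 2)))
            g = nx.barabasi_albert_graph(n, m, seed=gseed)
        graphs.append(g)
    return graphs
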