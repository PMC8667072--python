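import numpy as np
import pytest

from rwrscreen.network import WeightedNetwork
from rwrscreen.synthetic import SyntheticSpec, generate_annotations, generate_network


@pytest.fixture
def path3():
    """Path a - b - c with equal weights."""
    return WeightedNetwork([("a", "b", 500), ("b", "c", 500)])


@pytest.fixture
def star4():
    """Star with center h and leaves x, y, z, all at confidence 999."""
    return WeightedNetwork([("h", "x", 999), ("h", "y", 999), ("h", "z", 999)])


@pytest.fixture(scope="session")
def planted_small():
    """Small planted-module study used across screening/pipeline tests."""
    spec = SyntheticSpec(n_background=100, module_size=10, seed_fraction=0.5,
                         n_terms=30, rng_seed=7)
    network, truth = generate_network(spec)
    corpus = generate_annotations(network, truth, spec)
    return spec, network, truth, corpus


def dense_column_normalized(network) -> np.ndarray:
    """Independent dense transition matrix: confidence(i,j)/weighted-degree(j).

    Built straight from the confidence map (not from the package's sparse
    operator) so it can serve as an oracle; isolated nodes get a unit
    self-transition.
    """
    n = network.n_nodes
    M = np.zeros((n, n))
    for i, u in enumerate(network.nodes):
        for j, v in enumerate(network.nodes):
            M[i, j] = network.confidence(u, v) if u != v else 0
    colsum = M.sum(axis=0)
    for j in range(n):
        if colsum[j] == 0:
            M[j, j] = 1.0
        else:
            M[:, j] /= colsum[j]
    return M


def rwr_linear_solve(M: np.ndarray, p0: np.ndarray, r: float) -> np.ndarray:
    """Closed-form RWR fixed point r (I - (1-r) M)^-1 p0 by dense solve."""
    n = M.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1.0 - r) * M, p0)


def random_weighted_network(rng: np.random.Generator, max_nodes: int = 50) -> WeightedNetwork:
    """Random Erdos-Renyi-style weighted network with >= 1 edge."""
    while True:
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.05, 0.5))
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    edges.append((f"n{i:03d}", f"n{j:03d}", int(rng.integers(1, 1000))))
        if edges:
            return WeightedNetwork(edges, extra_nodes=[f"n{i:03d}" for i in range(n)])
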