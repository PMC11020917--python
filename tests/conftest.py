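import networkx as nx
import numpy as np
import pytest

from netrf import GeneNetwork, row_normalize_adjacency


@pytest.fixture
def triangle():
    return GeneNetwork(["A", "B", "C"], [("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return GeneNetwork(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def star5():
    return GeneNetwork(
        ["H", "L1", "L2", "L3", "L4"],
        [("H", "L1"), ("H", "L2"), ("H", "L3"), ("H", "L4")],
    )


@pytest.fixture
def toy5():
    """Five genes, irregular connected topology."""
    return GeneNetwork(
        ["A", "B", "C", "D", "E"],
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("B", "D"), ("A", "E")],
    )


def drw_direct(network: GeneNetwork, pi0: np.ndarray, r: float) -> np.ndarray:
    """Independent closed-form oracle: pi* = r (I - (1-r) A^T)^(-1) pi0."""
    W = row_normalize_adjacency(network)
    n = network.n_genes
    return r * np.linalg.solve(np.eye(n) - (1.0 - r) * W.T, pi0)


def random_connected_network(rng: np.random.Generator, max_nodes: int = 20) -> GeneNetwork:
    """A random connected graph: spanning tree plus extra random edges."""
    n = int(rng.integers(3, max_nodes + 1))
    g = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = rng.integers(0, n, 2)
        if u != v:
            g.add_edge(int(u), int(v))
    return GeneNetwork([str(i) for i in range(n)], [(str(u), str(v)) for u, v in g.edges])


def random_prior(rng: np.random.Generator, n: int) -> np.ndarray:
    w = rng.random(n) + 1e-3
    return w / w.sum()
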