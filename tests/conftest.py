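import numpy as np
import pytest

from eegsmallworld.connectivity import ConnectivityMatrix
from eegsmallworld.filtering import BinaryGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_matrix(n: int, rng: np.random.Generator) -> ConnectivityMatrix:
    """Random connectivity matrix with off-diagonal weights in (0, 1)."""
    w = rng.uniform(0.05, 0.95, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(values=w, band="synthetic")


def random_graph(n: int, p: float, rng: np.random.Generator) -> BinaryGraph:
    """Erdos-Renyi G(n, p) as a BinaryGraph."""
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return BinaryGraph(n, tuple(edges))


def ring_lattice(n: int, k: int) -> BinaryGraph:
    """Ring lattice: each node connected to its k nearest neighbors
    (k even)."""
    edges = set()
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            edges.add((min(i, j), max(i, j)))
    return BinaryGraph(n, tuple(sorted(edges)))


def watts_strogatz(n: int, k: int, p_rewire: float,
                   rng: np.random.Generator) -> BinaryGraph:
    """Ring lattice with a fraction of edges rewired to random targets."""
    base = ring_lattice(n, k)
    edges = set(base.edges)
    for (i, j) in list(edges):
        if rng.random() < p_rewire:
            edges.discard((i, j))
            while True:
                t = int(rng.integers(0, n))
                if t != i and (min(i, t), max(i, t)) not in edges:
                    edges.add((min(i, t), max(i, t)))
                    break
    return BinaryGraph(n, tuple(sorted(edges)))
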