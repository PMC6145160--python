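"""Binary-graph topology metrics: clustering coefficient C and
characteristic path length L.

C is the Watts-Strogatz mean local clustering: for each node the
fraction of its neighbor pairs that are themselves connected, with
degree-0/1 nodes contributing 0.

L is the mean shortest-path hop count over *connected* unordered node
pairs only; disconnected pairs are excluded from both numerator and
denominator. This convention keeps L finite on fragmented graphs and
makes L fall once a thresholded graph splits into small components —
the behavior expected when sweeping an absolute threshold upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .filtering import BinaryGraph


class MetricsError(ValueError):
    pass


@dataclass
class GraphMetricsRecord:
    C: float
    L: float
    n_connected_pairs: int
    provenance: dict = field(default_factory=dict)


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean over all nodes of 2*triangles_i / (deg_i * (deg_i - 1))."""
    a = g.adjacency().astype(np.float64)
    n = g.n_nodes
    if n == 0:
        raise MetricsError("empty graph")
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0  # triangles through each node
    denom = deg * (deg - 1) / 2.0
    local = np.zeros(n)
    mask = denom > 0
    local[mask] = tri[mask] / denom[mask]
    return float(local.mean())


def characteristic_path_length(g: BinaryGraph) -> tuple[float, int]:
    """(L, n_connected_pairs): mean hop-count distance over connected
    unordered pairs. Raises if no pair of nodes is connected."""
    if g.n_edges == 0:
        raise MetricsError("graph has no edges: L undefined")
    a = csr_matrix(g.adjacency().astype(np.int8))
    d = shortest_path(a, method="D", directed=False, unweighted=True)
    iu = np.triu_indices(g.n_nodes, k=1)
    dists = d[iu]
    finite = np.isfinite(dists)
    n_pairs = int(finite.sum())
    if n_pairs == 0:
        raise MetricsError("no connected node pairs: L undefined")
    return float(dists[finite].mean()), n_pairs


def graph_metrics(g: BinaryGraph) -> GraphMetricsRecord:
    """C and L for one binary graph, with provenance carried over."""
    length, n_pairs = characteristic_path_length(g)
    return GraphMetricsRecord(
        C=clustering_coefficient(g),
        L=length,
        n_connected_pairs=n_pairs,
        provenance=dict(g.provenance),
    )
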