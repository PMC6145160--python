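"""Convert a connectivity matrix into an undirected binary graph.

Three schemes:

* absolute threshold ``T`` — keep edges with weight strictly above T;
  graph density then varies across subjects;
* mean degree ``K`` — keep the ``round(K*n/2)`` strongest edges so every
  subject's graph has the same density;
* OMST — orthogonal (edge-disjoint) minimal spanning trees: extract
  successive MSTs on the distance ``d = 1 - w``, and return the union of
  the first m trees that maximizes the objective
  ``J(m) = GlobalEfficiency_weighted(union) - Cost(union)`` where Cost is
  the fraction of total connection weight spent. The result is connected
  by construction, data-driven, and free of an arbitrary threshold.

Tie-breaks are deterministic (ascending lexicographic edge order) so
repeated runs produce identical graphs on any platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)


class FilteringError(ValueError):
    pass


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph on nodes 0..n-1 (no self-loops), with
    provenance describing how it was produced."""

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    provenance: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        seen = set()
        for i, j in self.edges:
            if i == j:
                raise FilteringError(f"self-loop at node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise FilteringError(f"edge ({i},{j}) outside node range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise FilteringError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1).astype(int)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


def _canonical_edges(pairs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    return tuple(sorted((min(i, j), max(i, j)) for i, j in pairs))


@dataclass
class FilterConfig:
    """Scheme selection and parameter grids for the sweep driver.

    Default grids cover T in (0.15, 0.45) step 0.005 and K in (2, 8)
    step 0.1, endpoints excluded (59 points each).
    """

    scheme: str = "absolute_T"  # absolute_T | mean_degree_K | OMST
    t_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.155, 0.4455, 0.005), 3))
    k_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(2.1, 7.95, 0.1), 1))
    omst_max_msts: int | None = None

    def validate(self, n_nodes: int) -> None:
        if self.scheme not in ("absolute_T", "mean_degree_K", "OMST"):
            raise FilteringError(f"unknown scheme {self.scheme!r}")
        for name, grid, lo, hi in (
            ("t_grid", np.asarray(self.t_grid), 0.0, 1.0),
            ("k_grid", np.asarray(self.k_grid), 0.0, n_nodes - 1),
        ):
            if grid.size and (np.any(np.diff(grid) <= 0) or grid[0] <= lo or grid[-1] >= hi):
                raise FilteringError(f"{name} must be strictly increasing within ({lo}, {hi})")


def threshold_absolute(m: ConnectivityMatrix, t: float) -> BinaryGraph:
    """Edge (i, j) iff weight strictly greater than ``t``."""
    if not (0.0 < t < 1.0):
        raise FilteringError(f"threshold T={t} outside (0, 1)")
    v = m.values
    n = v.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = v[iu, ju] > t
    edges = _canonical_edges(zip(iu[keep].tolist(), ju[keep].tolist()))
    return BinaryGraph(n, edges, {"scheme": "absolute_T", "parameter": t,
                                  "band": m.band, "subject": m.subject_id})


def threshold_mean_degree(m: ConnectivityMatrix, k: float) -> BinaryGraph:
    """Keep the E = round(K*n/2) largest off-diagonal weights; ties at
    the cutoff resolved by ascending (i, j) order."""
    v = m.values
    n = v.shape[0]
    if not (0.0 < k < n - 1):
        raise FilteringError(f"mean degree K={k} outside (0, {n - 1})")
    n_edges = int(np.rint(k * n / 2.0))
    if n_edges == 0:
        raise FilteringError(f"K={k} yields zero edges for n={n}")
    iu, ju = np.triu_indices(n, k=1)
    w = v[iu, ju]
    # sort by descending weight, then ascending (i, j) for determinism
    order = np.lexsort((ju, iu, -w))
    sel = order[:n_edges]
    edges = _canonical_edges(zip(iu[sel].tolist(), ju[sel].tolist()))
    return BinaryGraph(n, edges, {"scheme": "mean_degree_K", "parameter": k,
                                  "band": m.band, "subject": m.subject_id})


def _weighted_global_efficiency(g: nx.Graph, n: int) -> float:
    """Mean over ordered node pairs of 1/d_ij, with d_ij the shortest
    path under the edge length attribute ``dist``; unreachable pairs
    contribute 0."""
    total = 0.0
    for _, lengths in nx.all_pairs_dijkstra_path_length(g, weight="dist"):
        for v, d in lengths.items():
            if d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def orthogonal_msts(m: ConnectivityMatrix, max_msts: int | None = None) -> list[list[tuple[int, int]]]:
    """Successive edge-disjoint MSTs on the distance 1 - w.

    Extraction stops when the residual graph is no longer connected or
    ``max_msts`` trees have been collected.
    """
    v = m.values
    n = v.shape[0]
    if max_msts is None:
        max_msts = n - 1
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu.tolist(), ju.tolist()):
        if v[i, j] > 0:
            g.add_edge(i, j, dist=1.0 - v[i, j], w=v[i, j])
    if g.number_of_edges() == 0:
        raise FilteringError("no positive weights: cannot build MST")
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise FilteringError(f"weighted graph disconnected; components: {comps}")
    msts: list[list[tuple[int, int]]] = []
    while len(msts) < max_msts and g.number_of_nodes() == n and nx.is_connected(g):
        tree = nx.minimum_spanning_tree(g, weight="dist")
        tree_edges = sorted((min(i, j), max(i, j)) for i, j in tree.edges())
        msts.append(tree_edges)
        g.remove_edges_from(tree_edges)
    return msts


def omst_filter(
    m: ConnectivityMatrix,
    max_msts: int | None = None,
    return_objective: bool = False,
):
    """OMST topological filtering: return the union of the first m
    orthogonal MSTs maximizing J(m) = efficiency - cost.

    Cost is the selected fraction of the total connection weight;
    efficiency is the weighted global efficiency of the union under the
    same distance 1 - w. The returned graph is binary, connected, and
    has at least n-1 edges.
    """
    v = m.values
    n = v.shape[0]
    msts = orthogonal_msts(m, max_msts)
    total_weight = float(np.triu(v, k=1).sum())
    union: list[tuple[int, int]] = []
    g_union = nx.Graph()
    g_union.add_nodes_from(range(n))
    objective: list[float] = []
    best_j, best_m = -np.inf, 0
    cum_weight = 0.0
    for tree_edges in msts:
        for i, j in tree_edges:
            g_union.add_edge(i, j, dist=1.0 - v[i, j])
            cum_weight += v[i, j]
        union.extend(tree_edges)
        eff = _weighted_global_efficiency(g_union, n)
        cost = cum_weight / total_weight
        j_val = eff - cost
        objective.append(j_val)
        if j_val > best_j:
            best_j, best_m = j_val, len(objective)
    edges = _canonical_edges(e for tree in msts[:best_m] for e in tree)
    graph = BinaryGraph(n, edges, {"scheme": "OMST", "parameter": best_m,
                                   "band": m.band, "subject": m.subject_id})
    if return_objective:
        return graph, objective
    return graph


def sweep(m: ConnectivityMatrix, config: FilterConfig) -> list[BinaryGraph]:
    """Apply the configured scheme over its grid: one graph per grid
    point (a single graph for OMST). Mean-degree grid points that would
    produce an empty edge set are skipped with a warning."""
    config.validate(m.n_channels)
    if config.scheme == "absolute_T":
        return [threshold_absolute(m, float(t)) for t in np.asarray(config.t_grid)]
    if config.scheme == "mean_degree_K":
        graphs = []
        for k in np.asarray(config.k_grid):
            try:
                graphs.append(threshold_mean_degree(m, float(k)))
            except FilteringError as exc:
                logger.warning("skipping K=%s: %s", k, exc)
        return graphs
    return [omst_filter(m, config.omst_max_msts)]
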