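"""The fixed-radius distance adjustment: neighbor graph, connectivity
repair, and geodesic recomputation.

Samples become nodes of an undirected graph. Pairwise values strictly
below the neighborhood radius are trusted and become weighted edges; all
other pairwise values are discarded and replaced by the length of the
shortest path through trusted edges. If discarding edges fragments the
graph, the minimum possible set of edges is borrowed from a minimum
spanning tree computed on the original matrix, so every pair remains
reachable.

Zero-valued entries between distinct samples (exact duplicates) are kept
as weight-0 edges: duplicates must remain mutually at distance zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .io import check_distance_matrix, _as_labeled_frame

__all__ = [
    "NeighborGraph",
    "build_neighbor_graph",
    "connect_graph",
    "geodesic_distances",
    "lmdist_fixed_radius",
]


class DisconnectedGraphError(RuntimeError):
    """Raised when geodesics are requested on a fragmented graph."""


@dataclass(frozen=True)
class NeighborGraph:
    """Weighted undirected graph over sample nodes.

    Attributes
    ----------
    labels : tuple of str
        Sample identifiers, one per node.
    edges : dict
        Mapping ``(i, j) -> weight`` with ``i < j``; weights are the
        original dissimilarities.
    mst_borrowed : frozenset
        The subset of ``edges`` keys that were borrowed from the minimum
        spanning tree to repair connectivity (empty before repair).
    radius : float
        The neighborhood radius the graph was built with.
    """

    labels: tuple
    edges: dict
    mst_borrowed: frozenset = field(default_factory=frozenset)
    radius: float = float("inf")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def degrees(self, *, include_borrowed: bool = False) -> np.ndarray:
        """Per-node edge counts, by default over trusted edges only."""
        deg = np.zeros(self.n_nodes, dtype=int)
        for (i, j) in self.edges:
            if not include_borrowed and (i, j) in self.mst_borrowed:
                continue
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_sparse(self) -> coo_matrix:
        """Adjacency as a sparse matrix with explicit zero-weight edges.

        scipy.sparse.csgraph treats *stored* zeros as real zero-weight
        edges, which is exactly what duplicate samples require.
        """
        n = self.n_nodes
        if not self.edges:
            return coo_matrix((n, n))
        ij = np.array(list(self.edges.keys()), dtype=int)
        w = np.array(list(self.edges.values()), dtype=float)
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        return coo_matrix((np.concatenate([w, w]), (rows, cols)), shape=(n, n))

    def is_connected(self) -> bool:
        uf = nx.utils.UnionFind(range(self.n_nodes))
        for (i, j) in self.edges:
            uf.union(i, j)
        return len(list(uf.to_sets())) <= 1


def _edge_key(i: int, j: int):
    return (i, j) if i < j else (j, i)


def build_neighbor_graph(D, radius: float, labels=None) -> NeighborGraph:
    """Connect every pair of samples whose dissimilarity is strictly below
    ``radius``.

    The resulting graph may be disconnected; run :func:`connect_graph`
    before asking for geodesics.
    """
    if isinstance(D, pd.DataFrame) and labels is None:
        labels = list(D.index)
    M = check_distance_matrix(D)
    if not radius > 0:
        raise ValueError("radius must be positive")
    n = M.shape[0]
    if labels is None:
        labels = [f"s{i}" for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    below = M[iu, ju] < radius
    edges = {
        (int(i), int(j)): float(M[i, j])
        for i, j in zip(iu[below], ju[below])
    }
    return NeighborGraph(tuple(labels), edges, frozenset(), float(radius))


def _mst_edges(M: np.ndarray):
    """Kruskal MST of the complete graph on ``M``, edges in the
    deterministic (weight, i, j) processing order.

    Ties between equal-weight edges are broken lexicographically by node
    pair, so the same matrix always yields the same tree.
    """
    n = M.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, M[iu, ju]))
    uf = nx.utils.UnionFind(range(n))
    tree = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf[i] != uf[j]:
            uf.union(i, j)
            tree.append((i, j, float(M[i, j])))
            if len(tree) == n - 1:
                break
    return tree


def connect_graph(G: NeighborGraph, D) -> NeighborGraph:
    """Repair a fragmented neighbor graph by borrowing MST edges.

    The MST is computed once on the full original matrix. Its edges are
    walked in increasing weight order; any edge whose endpoints lie in
    different connected components of the current graph is added and
    flagged as borrowed, until the graph is connected. A connected input
    is returned unchanged.
    """
    if G.is_connected():
        return G
    M = check_distance_matrix(D)
    if M.shape[0] != G.n_nodes:
        raise ValueError("matrix size does not match graph")
    uf = nx.utils.UnionFind(range(G.n_nodes))
    for (i, j) in G.edges:
        uf.union(i, j)
    edges = dict(G.edges)
    borrowed = set(G.mst_borrowed)
    for i, j, w in _mst_edges(M):
        if uf[i] != uf[j]:
            uf.union(i, j)
            edges[_edge_key(i, j)] = w
            borrowed.add(_edge_key(i, j))
    return NeighborGraph(G.labels, edges, frozenset(borrowed), G.radius)


def geodesic_distances(G: NeighborGraph, return_frame: bool = True):
    """All-pairs shortest-path lengths through the neighbor graph.

    Runs Dijkstra from every node (all weights are nonnegative). The
    output is a valid distance matrix and, being built from path lengths,
    always satisfies the triangle inequality.
    """
    if not G.is_connected():
        raise DisconnectedGraphError(
            "graph is disconnected; run connect_graph before geodesic_distances"
        )
    geo = dijkstra(G.to_sparse().tocsr(), directed=False)
    # identical path sets from either endpoint; average away any last-ulp
    # asymmetry from summing edge weights in opposite orders
    geo = (geo + geo.T) / 2.0
    np.fill_diagonal(geo, 0.0)
    if return_frame:
        return _as_labeled_frame(geo, labels=list(G.labels))
    return geo


def lmdist_fixed_radius(D, radius: float) -> pd.DataFrame:
    """Adjust a distance matrix at a fixed neighborhood radius.

    Composition of :func:`build_neighbor_graph`, :func:`connect_graph`
    and :func:`geodesic_distances`; deterministic given ``D`` and
    ``radius``. With a radius above the largest distance of a metric
    input this is the identity transform.
    """
    G = build_neighbor_graph(D, radius)
    G = connect_graph(G, D)
    return geodesic_distances(G)
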