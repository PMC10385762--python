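"""Mutual (symmetric) k-nearest-neighbour network graph over observations.

Vertices are window indices of a feature matrix; an undirected edge {i, j}
exists iff j is among the k nearest neighbours of i AND i is among the k
nearest neighbours of j, nearness measured by cosine distance
(1 - cosine similarity).  The mutuality requirement prunes asymmetric
neighbour relations and keeps the graph sparse, which is what makes the
downstream community structure informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkGraph",
    "cosine_affinity",
    "cosine_affinity_matrix",
    "build_network_graph",
    "default_k",
]


@dataclass
class NetworkGraph:
    """Undirected mutual k-NN graph; vertices are observation indices."""

    n_vertices: int
    edges: set[tuple[int, int]]  # stored as (i, j) with i < j
    k: int

    def __post_init__(self) -> None:
        for (i, j) in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < j < self.n_vertices):
                raise ValueError(f"edge ({i},{j}) out of range / unordered")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency_matrix(self) -> np.ndarray:
        A = np.zeros((self.n_vertices, self.n_vertices), dtype=int)
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1
        return A

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_vertices))
        G.add_edges_from(self.edges)
        return G

    def to_edge_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame(rows, columns=["u", "v"])

    def write_edge_csv(self, path) -> None:
        self.to_edge_frame().to_csv(path, index=False)


def cosine_affinity(xi: np.ndarray, xj: np.ndarray) -> float:
    """Cosine similarity of two feature vectors, in [-1, 1]."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    ni, nj = np.linalg.norm(xi), np.linalg.norm(xj)
    if ni == 0 or nj == 0:
        raise ValueError("cosine affinity undefined for zero-norm vector")
    return float(np.clip(xi @ xj / (ni * nj), -1.0, 1.0))


def cosine_affinity_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities; raises naming the first zero-norm row."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-norm feature vector at row {bad[0]}")
    U = X / norms[:, None]
    return np.clip(U @ U.T, -1.0, 1.0)


def default_k(n: int, fraction: float = 0.02, k_min: int = 3) -> int:
    """Neighbourhood size as a fraction of the graph size (2% by default,
    5% being the other commonly useful setting), floored at ``k_min`` and
    capped at n - 1."""
    return max(1, min(n - 1, max(k_min, int(round(fraction * n)))))


def build_network_graph(X, k: int) -> NetworkGraph:
    """Mutual k-NN graph of the rows of ``X`` under cosine distance.

    Neighbour ranking uses distance ``1 - cos``, ties broken by smaller
    vertex index; a duplicate point (distance 0) counts as a neighbour.
    Vertices with no mutual neighbour remain in the graph as isolated
    vertices.
    """
    from .features import FeatureMatrix  # local import to avoid cycle at type level

    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    D = 1.0 - cosine_affinity_matrix(X)
    np.fill_diagonal(D, np.inf)  # exclude self
    idx = np.arange(n)
    # stable ranking by (distance, index): lexsort's last key is primary
    order = np.lexsort((np.broadcast_to(idx, (n, n)), D), axis=1)
    nbrs = order[:, :k]
    neighbour_sets = [set(row.tolist()) for row in nbrs]
    edges = {
        (min(i, j), max(i, j))
        for i in range(n)
        for j in neighbour_sets[i]
        if i in neighbour_sets[j]
    }
    return NetworkGraph(n_vertices=n, edges=edges, k=k)
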