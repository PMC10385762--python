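"""Structural dependency graph over core clusters or label classes.

The dependency graph is a complete directed weighted graph whose vertices
are core clusters (target domain) or activity classes (source domain).
Vertex i carries weight ``w_u[i] = Delta(C_i) / sigma(C_i)`` (density per
vertex) and the ordered edge (i, j) carries
``w_e[i, j] = Cut(C_i, C_j) / sigma(C_j)`` (inter-cluster affinity
normalised by the destination size, hence asymmetric).  These ratios are
the structural fingerprint matched across domains: they abstract away the
raw feature space, which is exactly what enables transfer between sensors
of different modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import Partition, partition_statistics
from .network import NetworkGraph, build_network_graph, default_k

__all__ = ["DependencyGraph", "build_dependency_graph", "source_dependency_graph"]


@dataclass
class DependencyGraph:
    """Complete directed weighted graph over m clusters/classes."""

    vertex_weights: np.ndarray            # m
    edge_weights: np.ndarray              # m x m, zero diagonal
    members: list[tuple[int, ...]]        # vertex -> observation indices
    class_labels: list | None = None      # source only

    def __post_init__(self) -> None:
        self.vertex_weights = np.asarray(self.vertex_weights, dtype=float)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        m = self.m
        if self.edge_weights.shape != (m, m):
            raise ValueError("edge_weights must be m x m")
        if np.any(self.vertex_weights < 0) or np.any(self.edge_weights < 0):
            raise ValueError("dependency weights must be non-negative")
        if self.class_labels is not None and len(self.class_labels) != m:
            raise ValueError("class_labels length must equal vertex count")

    @property
    def m(self) -> int:
        return len(self.vertex_weights)

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray([len(ms) for ms in self.members])

    def vertex_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "vertex": np.arange(self.m),
                "w_u": self.vertex_weights,
                "size": self.sizes,
            }
        )
        if self.class_labels is not None:
            df.insert(1, "label", self.class_labels)
        return df

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (i, j, self.edge_weights[i, j])
            for i in range(self.m)
            for j in range(self.m)
            if i != j
        ]
        return pd.DataFrame(rows, columns=["src", "dst", "w_e"])


def build_dependency_graph(G: NetworkGraph, P: Partition) -> DependencyGraph:
    """Dependency graph of partition P over network graph G.

    Weights come straight from the partition statistics:
    ``w_u = Delta / sigma`` per vertex and ``w_e[i, j] = Cut(i, j) /
    sigma(j)`` per ordered pair.  A partition of edgeless singletons yields
    the valid degenerate all-zero graph.
    """
    stats = partition_statistics(G, P)
    sigma = stats.sigma
    if np.any(sigma < 1):
        raise ValueError("every cluster must contain at least one vertex")
    w_u = stats.delta / sigma
    w_e = stats.cut / sigma[None, :]
    np.fill_diagonal(w_e, 0.0)
    return DependencyGraph(
        vertex_weights=w_u, edge_weights=w_e, members=list(P.clusters)
    )


def source_dependency_graph(
    X_s, k: int | None = None, k_fraction: float = 0.02
) -> DependencyGraph:
    """Dependency graph of a labelled source domain.

    The network graph is built on the source features; the partition is not
    clustered but taken directly from the class labels (one vertex per
    class, classes in sorted label order).  ``k`` defaults to the same
    fraction-of-n rule used for the target graph.
    """
    if X_s.labels is None:
        raise ValueError("source feature matrix must carry labels")
    labels = np.asarray(X_s.labels)
    classes = sorted(pd.unique(labels).tolist())
    counts = {c: int(np.sum(labels == c)) for c in classes}
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"classes with no observations: {empty}")
    if k is None:
        k = default_k(X_s.n, fraction=k_fraction)
    G = build_network_graph(X_s, k)
    P = Partition.from_labels(labels)
    dg = build_dependency_graph(G, P)
    dg.class_labels = classes
    return dg
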