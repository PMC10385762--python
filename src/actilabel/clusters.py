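"""Core activity cluster identification (CCI) on the network graph.

The network graph is first partitioned into communities with
Clauset-Newman-Moore greedy modularity maximisation; communities are then
iteratively merged, always joining the pair with the highest similarity
score

    alpha(i, j) = Cut(C_i, C_j) / ((Delta_i + Delta_j) / 2),

i.e. the number of edges between two communities relative to the average
number of edges inside them, until a target cluster count is reached.  The
target count is normally the number of activity classes known from the
labelled source domain.  The ratio form makes the score robust to community
size imbalance; when both communities are edgeless the denominator is
floored at 1 so that any connecting edge still permits a merge.

Statistics notation follows the community-detection convention:
``Cut(i, j)`` = edges with one end in each cluster, ``Delta(i)`` = edges
with both ends in cluster i (density), ``sigma(i)`` = vertex count (size).
They satisfy the conservation law ``sum(Delta) + sum_{i<j} Cut = |E|``
whenever the partition covers every edge's endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities

from .network import NetworkGraph

__all__ = [
    "Partition",
    "PartitionStatistics",
    "partition_statistics",
    "similarity_alpha",
    "alpha_matrix",
    "initial_communities",
    "merge_to_core_clusters",
    "identify_core_clusters",
]


@dataclass
class Partition:
    """Disjoint vertex sets with contiguous cluster ids from 0."""

    clusters: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        norm = []
        for members in self.clusters:
            members = tuple(sorted(int(v) for v in members))
            if not members:
                raise ValueError("empty cluster")
            if seen & set(members):
                raise ValueError("clusters are not disjoint")
            seen.update(members)
            norm.append(members)
        self.clusters = norm

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def vertices(self) -> set[int]:
        return {v for c in self.clusters for v in c}

    def assignment(self) -> dict[int, int]:
        return {v: cid for cid, members in enumerate(self.clusters) for v in members}

    def labels_for(self, n_vertices: int, missing: int = -1) -> np.ndarray:
        out = np.full(n_vertices, missing, dtype=int)
        for cid, members in enumerate(self.clusters):
            out[list(members)] = cid
        return out

    @classmethod
    def from_labels(cls, labels: Sequence) -> "Partition":
        labels = np.asarray(labels)
        classes = sorted(pd.unique(labels).tolist())
        return cls([tuple(np.flatnonzero(labels == c).tolist()) for c in classes])

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((v, cid) for cid, ms in enumerate(self.clusters) for v in ms)
        return pd.DataFrame(rows, columns=["window_index", "cluster_id"])


@dataclass
class PartitionStatistics:
    """Cut matrix plus per-cluster density and size."""

    cut: np.ndarray     # K x K symmetric, zero diagonal
    delta: np.ndarray   # K
    sigma: np.ndarray   # K

    @property
    def n_clusters(self) -> int:
        return len(self.delta)

    @property
    def n_edges_covered(self) -> int:
        return int(self.delta.sum() + np.triu(self.cut, 1).sum())


def partition_statistics(G: NetworkGraph, P: Partition) -> PartitionStatistics:
    """Edge-count statistics of a partition of the network graph.

    The partition may cover a subset of G's vertices (noise shards and
    isolated vertices set aside by CCI): edges with an endpoint outside the
    cover are ignored.  The conservation law (sum of densities plus sum of
    cuts equals the edge count) therefore holds exactly when the partition
    covers every vertex.
    """
    K = P.n_clusters
    assign = P.assignment()
    cut = np.zeros((K, K), dtype=float)
    delta = np.zeros(K, dtype=float)
    for u, v in G.edges:
        cu, cv = assign.get(u), assign.get(v)
        if cu is None or cv is None:
            continue
        if cu == cv:
            delta[cu] += 1
        else:
            cut[cu, cv] += 1
            cut[cv, cu] += 1
    sigma = np.asarray([len(m) for m in P.clusters], dtype=float)
    return PartitionStatistics(cut=cut, delta=delta, sigma=sigma)


def _alpha_from_stats(stats: PartitionStatistics, i: int, j: int) -> float:
    denom = (stats.delta[i] + stats.delta[j]) / 2.0
    if denom == 0:
        denom = 1.0  # both clusters edgeless: any connecting edge may merge
    return float(stats.cut[i, j] / denom)


def alpha_matrix(stats: PartitionStatistics) -> np.ndarray:
    """Pairwise similarity scores; diagonal is 0 by convention."""
    K = stats.n_clusters
    A = np.zeros((K, K), dtype=float)
    for i in range(K):
        for j in range(i + 1, K):
            A[i, j] = A[j, i] = _alpha_from_stats(stats, i, j)
    return A


def similarity_alpha(G: NetworkGraph, P: Partition, i: int, j: int) -> float:
    """Similarity score between clusters i and j of partition P on G."""
    if i == j:
        raise ValueError("alpha is defined for distinct clusters")
    return _alpha_from_stats(partition_statistics(G, P), i, j)


def initial_communities(G: NetworkGraph) -> Partition:
    """Greedy-modularity (CNM) communities of the network graph.

    Deterministic for a fixed graph; an edgeless graph degenerates to one
    community per vertex.  Communities are ordered by their smallest vertex.
    """
    if G.n_edges == 0:
        return Partition([(v,) for v in range(G.n_vertices)])
    comms = greedy_modularity_communities(G.to_networkx())
    clusters = sorted((tuple(sorted(c)) for c in comms), key=lambda c: c[0])
    return Partition(list(clusters))


def merge_to_core_clusters(
    G: NetworkGraph, P0: Partition, target_count: int
) -> Partition:
    """Greedily merge the most-similar cluster pair until ``target_count``.

    At each step the pair with maximal alpha is merged (ties broken by the
    lexicographically smallest (i, j) index pair); statistics are updated
    incrementally.  After merging cluster j into cluster i, clusters above
    j shift down by one, keeping ids contiguous.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if target_count > P0.n_clusters:
        raise ValueError(
            f"target_count={target_count} exceeds the {P0.n_clusters} initial "
            "communities; lower target_count or use a larger k so the graph "
            "is better connected"
        )
    stats = partition_statistics(G, P0)
    clusters = [list(m) for m in P0.clusters]
    cut, delta, sigma = stats.cut, stats.delta, stats.sigma
    while len(clusters) > target_count:
        K = len(clusters)
        best, best_alpha = None, -1.0
        for i in range(K):
            for j in range(i + 1, K):
                denom = (delta[i] + delta[j]) / 2.0 or 1.0
                a = cut[i, j] / denom
                if a > best_alpha:
                    best, best_alpha = (i, j), a
        i, j = best
        delta[i] += delta[j] + cut[i, j]
        sigma[i] += sigma[j]
        cut[i, :] += cut[j, :]
        cut[:, i] += cut[:, j]
        cut[i, i] = 0.0
        keep = [c for c in range(K) if c != j]
        cut = cut[np.ix_(keep, keep)]
        delta = delta[keep]
        sigma = sigma[keep]
        clusters[i].extend(clusters[j])
        del clusters[j]
    return Partition([tuple(sorted(c)) for c in clusters])


def identify_core_clusters(
    G: NetworkGraph,
    target_count: int,
    partitioner: Callable[[NetworkGraph], Partition] = initial_communities,
    min_component_frac: float = 0.01,
) -> tuple[Partition, list[int]]:
    """Full CCI: partition, set noise vertices aside, merge to target.

    Vertices that cannot be clustered with any confidence are excluded
    before merging and returned separately: isolated vertices (degree 0)
    and members of tiny connected components (fewer than
    ``max(3, min_component_frac * n)`` vertices).  Such shards have zero
    cut to every community, so alpha-merging could never absorb them and
    they would otherwise squat on a core-cluster slot, forcing two genuine
    activity clusters to merge.  They receive labels later through the
    nearest-centroid fallback so that every observation is still labelled.
    The ``partitioner`` is pluggable (e.g. Louvain or label propagation for
    benchmarking); CNM is the default.
    """
    import networkx as nx

    P0 = partitioner(G)
    min_size = max(3, int(round(min_component_frac * G.n_vertices)))
    noise: set[int] = set()
    for comp in nx.connected_components(G.to_networkx()):
        if len(comp) < min_size:
            noise.update(comp)
    core_clusters = []
    for members in P0.clusters:
        kept = tuple(v for v in members if v not in noise)
        if kept:
            core_clusters.append(kept)
    if not core_clusters:
        raise ValueError("network graph has no sizeable components; increase k")
    P = Partition(core_clusters)

    # merge until `target_count` clusters of activity-class scale remain;
    # sub-scale shards (tiny communities inside big components, which have
    # near-zero alpha to everything and would otherwise squat on a cluster
    # slot) are set aside for the fallback afterwards
    def n_sizeable(P: Partition) -> int:
        return sum(len(c) >= min_size for c in P.clusters)

    if n_sizeable(P) < target_count:
        raise ValueError(
            f"target_count={target_count} exceeds the {n_sizeable(P)} "
            "activity-scale communities; lower target_count or rebuild the "
            "network graph with a different k"
        )
    while n_sizeable(P) > target_count:
        P = merge_to_core_clusters(G, P, P.n_clusters - 1)
    for members in P.clusters:
        if len(members) < min_size:
            noise.update(members)
    core = Partition([c for c in P.clusters if len(c) >= min_size])
    return core, sorted(noise)
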