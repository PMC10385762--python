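"""Two-tier min-cost dependency-graph mapping and label propagation.

Target core clusters are matched to source activity classes in three
bipartite assignment solves:

1. *vertex tier* — match dependency-graph vertices by the absolute
   difference of their vertex weights;
2. *edge tier* — match ordered dependency-graph edges by the absolute
   difference of their edge weights;
3. *consensus tier* — each component-level match casts votes mu(i, j) for
   vertex pairs (a vertex match votes once; an edge match (a,b)->(c,d)
   votes for (a,c) and (b,d), respecting edge direction); the final
   assignment minimises 1 - mu/M where M is the total number of votes.

All three solves use the Hungarian algorithm (scipy's
``linear_sum_assignment``) on zero-padded square matrices, with a
deterministic lexicographic tie-break among equal-cost optima.  Dummy
(padding) matches are excluded from votes and from reported costs.

``direct_map`` is the flat baseline: a single Hungarian solve on cosine
distances between cluster centroids in the shared feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clusters import Partition
from .dependency import DependencyGraph

__all__ = [
    "Mapping",
    "component_cost",
    "hungarian",
    "vertex_mapping",
    "edge_mapping",
    "consensus_mapping",
    "map_dependency_graphs",
    "propagate_labels",
    "direct_map",
]

_TIE_TOL = 1e-9


@dataclass
class Mapping:
    """Result of one bipartite matching.

    ``pairs`` maps non-dummy row ids to non-dummy column ids (a bijection
    on the smaller side); ``total_cost`` sums the cost of non-dummy pairs.
    For edge-tier mappings, ``row_items``/``col_items`` name what the
    row/column indices stand for (ordered edge tuples); for the consensus
    tier, ``votes`` is the mu(i, j) table and ``n_votes`` its total M.
    """

    pairs: dict[int, int]
    total_cost: float
    row_items: list | None = None
    col_items: list | None = None
    row_weights: np.ndarray | None = None
    col_weights: np.ndarray | None = None
    votes: np.ndarray | None = None
    n_votes: int | None = None

    def assignment_vector(self, n_rows: int) -> list[int]:
        return [self.pairs.get(i, -1) for i in range(n_rows)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in sorted(self.pairs):
            j = self.pairs[i]
            rows.append(
                {
                    "target": self.row_items[i] if self.row_items else i,
                    "source": self.col_items[j] if self.col_items else j,
                    "votes": None if self.votes is None else int(self.votes[i, j]),
                }
            )
        return pd.DataFrame(rows)


def component_cost(w_t: float, w_s: float) -> float:
    """Cost of matching two components: absolute weight difference."""
    if not (np.isfinite(w_t) and np.isfinite(w_s)):
        raise ValueError("component weights must be finite")
    return abs(float(w_t) - float(w_s))


def _lexmin_assignment(C: np.ndarray) -> np.ndarray:
    """Column assignment per row of square C: minimum total cost, and the
    lexicographically smallest assignment vector among all optima.

    Fixes rows in order; for each row it takes the smallest column that can
    still complete an optimal assignment (checked by re-solving the reduced
    problem).  O(s^2) Hungarian solves of shrinking size -- fine for the
    cluster-scale matrices this package deals with.
    """
    s = C.shape[0]
    rows = list(range(s))
    cols = list(range(s))
    ri, ci = linear_sum_assignment(C)
    budget = float(C[ri, ci].sum())
    out = np.empty(s, dtype=int)
    for i in rows:
        for j in sorted(cols):
            sub_rows = [r for r in range(i + 1, s)]
            sub_cols = [c for c in cols if c != j]
            rest = 0.0
            if sub_rows:
                sub = C[np.ix_(sub_rows, sub_cols)]
                rr, cc = linear_sum_assignment(sub)
                rest = float(sub[rr, cc].sum())
            if C[i, j] + rest <= budget + _TIE_TOL:
                out[i] = j
                cols.remove(j)
                budget -= C[i, j]
                break
        else:  # pragma: no cover - would indicate numerical breakage
            raise RuntimeError("failed to extend optimal assignment")
    return out


def hungarian(cost: np.ndarray, lexicographic: bool = True) -> Mapping:
    """Min-cost perfect matching of a (possibly rectangular) cost matrix.

    Rectangular matrices are padded square with zero-cost dummy rows or
    columns; dummy pairs are dropped from ``pairs`` and ``total_cost``.
    With ``lexicographic=True`` (default) the lexicographically smallest
    assignment vector among equal-cost optima is returned.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost matrix must be 2-D and non-empty")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    r, c = cost.shape
    s = max(r, c)
    padded = np.zeros((s, s), dtype=float)
    padded[:r, :c] = cost
    if lexicographic:
        cols = _lexmin_assignment(padded)
        rows = np.arange(s)
    else:
        rows, cols = linear_sum_assignment(padded)
    pairs = {int(i): int(j) for i, j in zip(rows, cols) if i < r and j < c}
    total = float(sum(cost[i, j] for i, j in pairs.items()))
    return Mapping(pairs=pairs, total_cost=total)


def vertex_mapping(DG_t: DependencyGraph, DG_s: DependencyGraph) -> Mapping:
    """Vertex-tier matching on |w_u(target) - w_u(source)|."""
    C = np.abs(DG_t.vertex_weights[:, None] - DG_s.vertex_weights[None, :])
    M = hungarian(C)
    M.row_weights = DG_t.vertex_weights
    M.col_weights = DG_s.vertex_weights
    return M


def _ordered_edges(m: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(m) for b in range(m) if a != b]


def edge_mapping(DG_t: DependencyGraph, DG_s: DependencyGraph) -> Mapping:
    """Edge-tier matching between the ordered edges of the two graphs."""
    if DG_t.m < 2 or DG_s.m < 2:
        raise ValueError("edge mapping needs at least 2 vertices per graph")
    et = _ordered_edges(DG_t.m)
    es = _ordered_edges(DG_s.m)
    wt = np.asarray([DG_t.edge_weights[a, b] for a, b in et])
    ws = np.asarray([DG_s.edge_weights[c, d] for c, d in es])
    C = np.abs(wt[:, None] - ws[None, :])
    M = hungarian(C)
    M.row_items = et
    M.col_items = es
    M.row_weights = wt
    M.col_weights = ws
    return M


def consensus_mapping(M_v: Mapping, M_e: Mapping, m_t: int, m_s: int) -> Mapping:
    """Consensus tier: accumulate component votes and re-match.

    Each vertex match (i -> j) contributes one vote to mu(i, j); each edge
    match (a, b) -> (c, d) contributes one vote to mu(a, c) and one to
    mu(b, d).  M is the vote total; the consensus assignment minimises
    ``1 - mu/M`` over bijections, so pairs the component tiers agree on are
    cheap.

    When the component mappings carry their weight vectors
    (``row_weights``/``col_weights``, as produced by :func:`vertex_mapping`
    and :func:`edge_mapping`), a match in which either matched weight is
    zero abstains from voting: matching an absent relationship (weight 0)
    against anything is a forced or arbitrary pairing — typically resolved
    by the deterministic tie-break, not by structure — and would otherwise
    flood the vote table with an index-order artifact.  Mappings built
    without weight annotations vote unconditionally.
    """

    def informative(M: Mapping, i: int, j: int) -> bool:
        if M.row_weights is None or M.col_weights is None:
            return True
        return M.row_weights[i] != 0 and M.col_weights[j] != 0

    votes = np.zeros((m_t, m_s), dtype=int)
    for i, j in M_v.pairs.items():
        if informative(M_v, i, j):
            votes[i, j] += 1
    if M_e.row_items is None or M_e.col_items is None:
        raise ValueError("edge mapping lacks its edge lists")
    for ei, ej in M_e.pairs.items():
        if not informative(M_e, ei, ej):
            continue
        a, b = M_e.row_items[ei]
        c, d = M_e.col_items[ej]
        votes[a, c] += 1
        votes[b, d] += 1
    M = int(votes.sum())
    if M == 0:
        raise ValueError("no component-level mappings to build a consensus from")
    C = 1.0 - votes / M
    out = hungarian(C)
    out.votes = votes
    out.n_votes = M
    return out


def map_dependency_graphs(
    DG_t: DependencyGraph, DG_s: DependencyGraph
) -> tuple[Mapping, Mapping, Mapping]:
    """Run the full two-tier mapping; returns (vertex, edge, consensus)."""
    M_v = vertex_mapping(DG_t, DG_s)
    M_e = edge_mapping(DG_t, DG_s)
    M_c = consensus_mapping(M_v, M_e, DG_t.m, DG_s.m)
    return M_v, M_e, M_c


def _centroids(X: np.ndarray, members: list[tuple[int, ...]]) -> np.ndarray:
    return np.vstack([X[list(ms)].mean(axis=0) for ms in members])


def propagate_labels(
    P_t: Partition,
    M: Mapping,
    DG_s: DependencyGraph,
    X_t,
    extra_vertices: list[int] | None = None,
) -> pd.DataFrame:
    """Broadcast mapped source labels to every target observation.

    Observations in a cluster matched to source class j receive
    ``DG_s.class_labels[j]``.  Clusters matched to a dummy (absent from
    ``M.pairs``) and vertices outside the partition (isolated network
    vertices) fall back to the label of the nearest mapped cluster centroid
    under cosine distance and are flagged in the ``fallback`` column.
    """
    from .features import FeatureMatrix
    from .network import cosine_affinity_matrix

    if DG_s.class_labels is None:
        raise ValueError("source dependency graph carries no class labels")
    if isinstance(X_t, FeatureMatrix):
        X_t = X_t.X
    X_t = np.asarray(X_t, dtype=float)
    n = X_t.shape[0]
    labels = np.empty(n, dtype=object)
    fallback = np.zeros(n, dtype=bool)
    unassigned: list[int] = list(extra_vertices or [])

    mapped_cids = sorted(M.pairs)
    if not mapped_cids:
        raise ValueError("mapping assigns no target cluster to a source class")
    for cid, members in enumerate(P_t.clusters):
        if cid in M.pairs:
            labels[list(members)] = DG_s.class_labels[M.pairs[cid]]
        else:
            unassigned.extend(members)

    if unassigned:
        cents = _centroids(X_t, [P_t.clusters[c] for c in mapped_cids])
        stacked = np.vstack([X_t[unassigned], cents])
        sims = cosine_affinity_matrix(stacked)[: len(unassigned), len(unassigned):]
        nearest = sims.argmax(axis=1)
        for row, v in enumerate(unassigned):
            cid = mapped_cids[nearest[row]]
            labels[v] = DG_s.class_labels[M.pairs[cid]]
            fallback[v] = True
    return pd.DataFrame({"predicted_label": labels, "fallback_flag": fallback})


def direct_map(
    DG_t: DependencyGraph, DG_s: DependencyGraph, X_t, X_s
) -> Mapping:
    """Baseline comparator: one Hungarian solve on cosine distances between
    target cluster centroids and source class centroids."""
    from .features import FeatureMatrix
    from .network import cosine_affinity_matrix

    if isinstance(X_t, FeatureMatrix):
        X_t = X_t.X
    if isinstance(X_s, FeatureMatrix):
        X_s = X_s.X
    X_t = np.asarray(X_t, dtype=float)
    X_s = np.asarray(X_s, dtype=float)
    if X_t.shape[1] != X_s.shape[1]:
        raise ValueError(
            f"feature dimensionality mismatch: target d={X_t.shape[1]}, "
            f"source d={X_s.shape[1]}"
        )
    ct = _centroids(X_t, DG_t.members)
    cs = _centroids(X_s, DG_s.members)
    sims = cosine_affinity_matrix(np.vstack([ct, cs]))[: len(ct), len(ct):]
    return hungarian(1.0 - sims)
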