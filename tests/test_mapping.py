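from itertools import permutations

import numpy as np
import pytest

from actilabel.clusters import Partition
from actilabel.dependency import DependencyGraph
from actilabel.mapping import (
    Mapping,
    component_cost,
    consensus_mapping,
    direct_map,
    edge_mapping,
    hungarian,
    map_dependency_graphs,
    propagate_labels,
    vertex_mapping,
)


def brute_force_min(C):
    C = np.asarray(C, dtype=float)
    m = C.shape[0]
    return min(sum(C[i, p[i]] for i in range(m)) for p in permutations(range(m)))


def make_dg(rng, m, labels=None):
    w_u = rng.uniform(0.2, 2.0, size=m)
    w_e = rng.uniform(0.05, 1.0, size=(m, m))
    np.fill_diagonal(w_e, 0.0)
    members = [tuple(range(i * 3, i * 3 + 3)) for i in range(m)]
    return DependencyGraph(w_u, w_e, members, class_labels=labels)


class TestComponentCost:
    @pytest.mark.parametrize(
        "a,b,want", [(0.5, 0.5, 0.0), (0.2, 0.7, 0.5), (1.0, 0.0, 1.0)]
    )
    def test_absolute_difference(self, a, b, want):
        assert component_cost(a, b) == pytest.approx(want)
        assert component_cost(b, a) == pytest.approx(want)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            component_cost(np.inf, 0.0)


class TestHungarian:
    def test_diagonal_optimum(self):
        M = hungarian([[0, 1], [1, 0]])
        assert M.pairs == {0: 0, 1: 1}
        assert M.total_cost == 0

    def test_three_by_three_matches_enumeration(self):
        # exhaustive search over the 6 permutations: anti-diagonal, cost 10
        C = [[1, 2, 3], [2, 4, 6], [3, 6, 9]]
        M = hungarian(C)
        assert M.total_cost == pytest.approx(brute_force_min(C))
        assert M.pairs == {0: 2, 1: 1, 2: 0}

    def test_one_by_one(self):
        assert hungarian([[4.5]]).total_cost == 4.5

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(30):
            m = int(rng.integers(2, 6))
            C = rng.uniform(0, 1, size=(m, m))
            assert hungarian(C).total_cost == pytest.approx(brute_force_min(C))

    def test_constant_matrix_takes_lexicographically_smallest(self):
        M = hungarian(np.ones((4, 4)))
        assert M.pairs == {0: 0, 1: 1, 2: 2, 3: 3}

    def test_lexicographic_among_ties(self):
        # both diagonals are optimal; identity is lexicographically smaller
        C = [[1.0, 1.0], [1.0, 1.0]]
        assert hungarian(C).pairs == {0: 0, 1: 1}

    def test_rectangular_padding_drops_dummy_pairs(self, rng):
        C = rng.uniform(1, 2, size=(2, 4))
        M = hungarian(C)
        assert set(M.pairs) == {0, 1}
        assert len(set(M.pairs.values())) == 2

    def test_non_finite_cost_rejected(self):
        with pytest.raises(ValueError):
            hungarian([[np.nan, 1], [1, 0]])


class TestVertexMapping:
    def test_identical_graphs_identity(self, rng):
        dg = make_dg(rng, 4)
        M = vertex_mapping(dg, dg)
        assert M.pairs == {i: i for i in range(4)}
        assert M.total_cost == 0

    def test_crossed_weights(self):
        dg_t = make_dg(np.random.default_rng(0), 2)
        dg_s = make_dg(np.random.default_rng(1), 2)
        dg_t.vertex_weights = np.array([0.1, 0.9])
        dg_s.vertex_weights = np.array([0.88, 0.12])
        assert vertex_mapping(dg_t, dg_s).pairs == {0: 1, 1: 0}

    def test_unbalanced_leaves_a_source_unmatched(self, rng):
        M = vertex_mapping(make_dg(rng, 2), make_dg(rng, 3))
        assert set(M.pairs) == {0, 1}
        assert len(set(M.pairs.values())) == 2


class TestEdgeMapping:
    def test_identical_graphs_map_twin_edges(self, rng):
        dg = make_dg(rng, 3)
        M = edge_mapping(dg, dg)
        assert M.total_cost == pytest.approx(0)
        for ei, ej in M.pairs.items():
            assert M.row_items[ei] == M.col_items[ej]

    def test_m2_matches_enumeration(self, rng):
        dg_t, dg_s = make_dg(rng, 2), make_dg(rng, 2)
        wt = [dg_t.edge_weights[0, 1], dg_t.edge_weights[1, 0]]
        ws = [dg_s.edge_weights[0, 1], dg_s.edge_weights[1, 0]]
        best = min(
            abs(wt[0] - ws[0]) + abs(wt[1] - ws[1]),
            abs(wt[0] - ws[1]) + abs(wt[1] - ws[0]),
        )
        assert edge_mapping(dg_t, dg_s).total_cost == pytest.approx(best)

    def test_all_zero_weights_use_tie_rule(self, rng):
        dg_t, dg_s = make_dg(rng, 2), make_dg(rng, 2)
        dg_t.edge_weights = np.zeros((2, 2))
        dg_s.edge_weights = np.zeros((2, 2))
        M = edge_mapping(dg_t, dg_s)
        assert M.total_cost == 0
        assert M.pairs == {0: 0, 1: 1}  # lexicographically smallest


class TestConsensusMapping:
    def hand_mappings(self):
        """The worked two-cluster vote table: identity at both tiers."""
        M_v = Mapping(pairs={0: 0, 1: 1}, total_cost=0.0)
        M_e = Mapping(
            pairs={0: 0, 1: 1},
            total_cost=0.0,
            row_items=[(0, 1), (1, 0)],
            col_items=[(0, 1), (1, 0)],
        )
        return M_v, M_e

    def test_hand_vote_accumulation(self):
        M_v, M_e = self.hand_mappings()
        M = consensus_mapping(M_v, M_e, 2, 2)
        np.testing.assert_array_equal(M.votes, [[3, 0], [0, 3]])
        assert M.n_votes == 6
        assert M.pairs == {0: 0, 1: 1}
        assert M.total_cost == pytest.approx(0.5 + 0.5)

    def test_unanimous_disagreement_with_identity(self):
        M_v = Mapping(pairs={0: 1, 1: 0}, total_cost=0.0)
        M_e = Mapping(
            pairs={0: 1, 1: 0},
            total_cost=0.0,
            row_items=[(0, 1), (1, 0)],
            col_items=[(0, 1), (1, 0)],
        )
        M = consensus_mapping(M_v, M_e, 2, 2)
        assert M.pairs == {0: 1, 1: 0}

    def test_equal_votes_fall_back_to_lexicographic(self):
        # vertex votes on one diagonal, edge votes on the other: tie
        M_v = Mapping(pairs={0: 0, 1: 1}, total_cost=0.0)
        M_e = Mapping(
            pairs={0: 0},
            total_cost=0.0,
            row_items=[(0, 1)],
            col_items=[(1, 0)],
        )
        M = consensus_mapping(M_v, M_e, 2, 2)
        np.testing.assert_array_equal(M.votes, [[1, 1], [1, 1]])
        assert M.pairs == {0: 0, 1: 1}

    def test_vote_conservation(self, rng):
        dg_t, dg_s = make_dg(rng, 4), make_dg(rng, 4)
        M_v, M_e, M_c = map_dependency_graphs(dg_t, dg_s)
        assert M_c.votes.sum() == M_c.n_votes

    def test_zero_weight_matches_abstain(self, rng):
        dg_t, dg_s = make_dg(rng, 3), make_dg(rng, 3)
        dg_t.edge_weights[0, 1] = 0.0
        M_v = vertex_mapping(dg_t, dg_s)
        M_e = edge_mapping(dg_t, dg_s)
        M_c = consensus_mapping(M_v, M_e, 3, 3)
        # edges: 6 per side, one target edge weight zeroed -> its match
        # abstains; the 5 remaining edge matches + 3 vertex matches vote
        assert M_c.n_votes == 3 + 2 * 5

    def test_no_votes_is_an_error(self):
        M_v = Mapping(pairs={0: 0}, total_cost=0.0,
                      row_weights=np.zeros(1), col_weights=np.zeros(1))
        M_e = Mapping(pairs={}, total_cost=0.0, row_items=[], col_items=[])
        with pytest.raises(ValueError):
            consensus_mapping(M_v, M_e, 1, 1)

    def test_identical_graphs_identity_at_every_tier(self, rng):
        dg = make_dg(rng, 5)
        M_v, M_e, M_c = map_dependency_graphs(dg, dg)
        assert M_v.pairs == {i: i for i in range(5)}
        assert M_v.total_cost == 0
        assert M_e.total_cost == 0
        assert M_c.pairs == {i: i for i in range(5)}

    def test_consensus_objective_minimal_vs_enumeration(self, rng):
        for m in range(2, 6):
            dg_t, dg_s = make_dg(rng, m), make_dg(rng, m)
            _, _, M_c = map_dependency_graphs(dg_t, dg_s)
            cost = 1.0 - M_c.votes / M_c.n_votes
            achieved = sum(cost[i, j] for i, j in M_c.pairs.items())
            best = brute_force_min(cost)
            assert achieved == pytest.approx(best)


class TestPropagateLabels:
    def test_broadcast_to_cluster_members(self, rng):
        P = Partition([tuple(range(10)), tuple(range(10, 15))])
        dg_s = make_dg(rng, 2, labels=["walk", "run"])
        M = Mapping(pairs={0: 0, 1: 1}, total_cost=0.0)
        X = rng.standard_normal((15, 3))
        out = propagate_labels(P, M, dg_s, X)
        assert list(out["predicted_label"][:10]) == ["walk"] * 10
        assert list(out["predicted_label"][10:]) == ["run"] * 5
        assert not out["fallback_flag"].any()

    def test_permuted_mapping_permutes_labels(self, rng):
        P = Partition([tuple(range(10)), tuple(range(10, 15))])
        dg_s = make_dg(rng, 2, labels=["walk", "run"])
        M = Mapping(pairs={0: 1, 1: 0}, total_cost=0.0)
        out = propagate_labels(P, M, dg_s, rng.standard_normal((15, 3)))
        assert set(out["predicted_label"][:10]) == {"run"}

    def test_dummy_cluster_gets_flagged_fallback(self, rng):
        # cluster 1 unmapped; its members sit on cluster 0's centroid
        X = np.vstack([np.tile([1.0, 0.0], (10, 1)), np.tile([1.0, 0.1], (5, 1))])
        P = Partition([tuple(range(10)), tuple(range(10, 15))])
        dg_s = make_dg(rng, 2, labels=["walk", "run"])
        M = Mapping(pairs={0: 0}, total_cost=0.0)
        out = propagate_labels(P, M, dg_s, X)
        assert list(out["predicted_label"][10:]) == ["walk"] * 5
        assert out["fallback_flag"][10:].all()
        assert not out["fallback_flag"][:10].any()


class TestDirectMap:
    def test_identical_datasets_identity(self, rng):
        X = rng.standard_normal((12, 4))
        members = [tuple(range(0, 4)), tuple(range(4, 8)), tuple(range(8, 12))]
        dg = DependencyGraph(np.ones(3), np.zeros((3, 3)), members,
                             class_labels=["a", "b", "c"])
        M = direct_map(dg, dg, X, X)
        assert M.pairs == {0: 0, 1: 1, 2: 2}
        assert M.total_cost == pytest.approx(0, abs=1e-12)

    def test_single_cluster_each_side(self, rng):
        X = rng.standard_normal((4, 3))
        dg = DependencyGraph(np.ones(1), np.zeros((1, 1)), [tuple(range(4))])
        assert direct_map(dg, dg, X, X).pairs == {0: 0}

    def test_right_angle_centroids_match_enumeration(self):
        Xt = np.array([[1.0, 0], [1, 0], [0, 1], [0, 1]])
        Xs = np.array([[0.0, 1], [0, 1], [1, 0], [1, 0]])
        members = [(0, 1), (2, 3)]
        dg_t = DependencyGraph(np.ones(2), np.zeros((2, 2)), members)
        dg_s = DependencyGraph(np.ones(2), np.zeros((2, 2)), members)
        M = direct_map(dg_t, dg_s, Xt, Xs)
        assert M.pairs == {0: 1, 1: 0}

    def test_dimension_mismatch_rejected(self, rng):
        dg = DependencyGraph(np.ones(1), np.zeros((1, 1)), [(0,)])
        with pytest.raises(ValueError, match="dimensionality"):
            direct_map(dg, dg, rng.standard_normal((1, 3)), rng.standard_normal((1, 4)))
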