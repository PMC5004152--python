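import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from modevo.modularity_metrics import (
    AssociationMatrix,
    Partition,
    TabuParams,
    association_matrix,
    degree_preserving_null,
    exhaustive_faction_oracle,
    faction_cost,
    girvan_newman_partition,
    newman_q,
    tabu_factions,
)
from modevo.network_model import ArchitectureSpec, make_architecture_mask

from conftest import graph_from_edges


class TestAssociationMatrix:
    def test_symmetrizes_full_mask(self):
        adj = association_matrix(np.ones((96, 48), bool))
        assert adj.adjacency.shape == (144, 144)
        assert adj.adjacency.sum() == 2 * 4608
        assert np.array_equal(adj.adjacency, adj.adjacency.T)

    def test_bipartite_blocks_are_empty(self):
        adj = association_matrix(np.ones((4, 3), bool))
        assert not adj.adjacency[:4, :4].any()
        assert not adj.adjacency[4:, 4:].any()

    def test_empty_and_pmn_counts(self):
        assert association_matrix(np.zeros((4, 3), bool)).adjacency.sum() == 0
        pmn = make_architecture_mask(ArchitectureSpec("pmn", 16, 8))
        assert association_matrix(pmn).adjacency.sum() == 128

    def test_graph_roles(self):
        g = association_matrix(np.ones((2, 3), bool)).to_graph()
        assert [g.nodes[n]["role"] for n in range(5)] == ["input"] * 2 + ["hidden"] * 3


class TestNewmanQ:
    def test_single_group_is_zero(self, two_triangles):
        assert newman_q(two_triangles, np.zeros(6, int)) == pytest.approx(0.0)

    def test_two_disjoint_triangles_score_half(self, two_triangles):
        assert newman_q(two_triangles, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.5)

    def test_zero_edge_graph_defined_as_zero(self):
        assert newman_q(np.zeros((4, 4)), np.array([0, 1, 0, 1])) == 0.0

    @pytest.mark.parametrize("n_groups", [2, 3, 4])
    def test_clique_union_closed_form(self, n_groups):
        # G disconnected cliques partitioned as themselves: Q = 1 - 1/G
        blocks = [np.ones((4, 4)) - np.eye(4)] * n_groups
        a = np.zeros((4 * n_groups, 4 * n_groups))
        for g in range(n_groups):
            a[4 * g : 4 * g + 4, 4 * g : 4 * g + 4] = blocks[g]
        labels = np.repeat(np.arange(n_groups), 4)
        assert newman_q(a, labels) == pytest.approx(1 - 1 / n_groups)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_networkx_modularity(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((10, 10)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() == 0:
            return
        labels = rng.integers(0, 3, 10)
        g = nx.from_numpy_array(a)
        communities = [set(np.flatnonzero(labels == k)) for k in range(3)]
        communities = [c for c in communities if c]
        expected = nx.algorithms.community.modularity(g, communities)
        assert newman_q(a, labels) == pytest.approx(expected, abs=1e-12)


class TestFactionCost:
    def test_perfect_cliques_cost_zero(self, two_triangles):
        assert faction_cost(two_triangles, np.array([0, 0, 0, 1, 1, 1])) == 0

    def test_merged_group_counts_missing_ties(self, two_triangles):
        # one group of 6: C(6,2)=15 pairs, 6 edges -> 9 missing within ties
        assert faction_cost(two_triangles, np.zeros(6, int)) == 9

    def test_empty_graph_costs_all_within_pairs(self):
        a = np.zeros((7, 7))
        labels = np.array([0, 0, 0, 1, 1, 2, 2])  # sizes 3, 2, 2
        assert faction_cost(a, labels) == 3 + 1 + 1

    def test_path_of_three(self):
        a = graph_from_edges(3, [(0, 1), (1, 2)])
        # split {0,1} | {2}: no missing within, one between tie
        assert faction_cost(a, np.array([0, 0, 1])) == 1


class TestExhaustiveOracle:
    def test_two_disjoint_edges(self):
        a = graph_from_edges(4, [(0, 1), (2, 3)])
        part = exhaustive_faction_oracle(a, 2)
        assert part.faction_cost == 0
        assert part.labels[0] == part.labels[1] != part.labels[2] == part.labels[3]

    def test_path_of_three_optimum_is_one(self):
        a = graph_from_edges(3, [(0, 1), (1, 2)])
        assert exhaustive_faction_oracle(a, 2).faction_cost == 1

    def test_two_triangles_recovered(self, two_triangles):
        part = exhaustive_faction_oracle(two_triangles, 2)
        assert part.faction_cost == 0
        assert part.q == pytest.approx(0.5)

    def test_rejects_large_graphs(self):
        with pytest.raises(ValueError, match="12"):
            exhaustive_faction_oracle(np.zeros((13, 13)), 2)


class TestTabuFactions:
    def test_recovers_disjoint_triangles(self, two_triangles):
        part = tabu_factions(two_triangles, 2, TabuParams(seed=0))
        assert part.faction_cost == 0
        assert part.q == pytest.approx(0.5)

    def test_deterministic_given_seed(self, barbell):
        a = tabu_factions(barbell, 2, TabuParams(seed=42))
        b = tabu_factions(barbell, 2, TabuParams(seed=42))
        assert np.array_equal(a.labels, b.labels) and a.faction_cost == b.faction_cost

    def test_matches_oracle_on_small_graphs(self, two_triangles, barbell):
        rng = np.random.default_rng(0)
        graphs = [
            two_triangles,
            barbell,
            graph_from_edges(4, [(0, 1), (2, 3)]),
            graph_from_edges(3, [(0, 1), (1, 2)]),
        ]
        a = (rng.random((9, 9)) < 0.35).astype(int)
        a = np.triu(a, 1)
        graphs.append(a + a.T)
        for g in graphs:
            optimum = exhaustive_faction_oracle(g, 2).faction_cost
            costs = [
                tabu_factions(g, 2, TabuParams(seed=s)).faction_cost for s in range(20)
            ]
            assert min(costs) == optimum
            assert np.mean(np.array(costs) == optimum) >= 0.95

    def test_never_worse_than_random_partitions(self, barbell):
        rng = np.random.default_rng(1)
        tabu_cost = tabu_factions(barbell, 2, TabuParams(seed=1)).faction_cost
        random_costs = [
            faction_cost(barbell, rng.integers(0, 2, 6)) for _ in range(50)
        ]
        assert tabu_cost <= min(random_costs)

    def test_rejects_bad_group_counts(self, two_triangles):
        with pytest.raises(ValueError):
            tabu_factions(two_triangles, 1)
        with pytest.raises(ValueError):
            tabu_factions(two_triangles, 7)


class TestGirvanNewman:
    def test_two_triangles(self, two_triangles):
        part = girvan_newman_partition(two_triangles)
        assert part.q == pytest.approx(0.5)
        assert part.n_groups == 2

    def test_single_clique_stays_one_group_without_target(self):
        clique = np.ones((5, 5), int) - np.eye(5, dtype=int)
        part = girvan_newman_partition(clique)
        assert part.n_groups == 1
        assert part.q == pytest.approx(0.0)

    def test_barbell_bridge_removed_first(self, barbell):
        part = girvan_newman_partition(barbell, n_groups=2)
        assert part.n_groups == 2
        assert part.labels[0] == part.labels[1] == part.labels[2]
        assert part.labels[3] == part.labels[4] == part.labels[5]
        assert part.labels[0] != part.labels[3]

    def test_disconnected_graph_components_are_starting_partition(self):
        a = np.zeros((4, 4))
        part = girvan_newman_partition(a, n_groups=2)
        assert part.n_groups == 4  # four isolated nodes


class TestDegreePreservingNull:
    def test_row_degrees_and_total_preserved(self):
        rng = np.random.default_rng(0)
        mask = rng.random((20, 10)) < 0.4
        null = degree_preserving_null(mask, seed=1)
        assert np.array_equal(null.sum(axis=1), mask.sum(axis=1))
        assert null.sum() == mask.sum()

    def test_full_mask_is_fixed_point(self):
        mask = np.ones((6, 4), bool)
        assert np.array_equal(degree_preserving_null(mask, seed=0), mask)

    def test_pmn_null_loses_modularity(self):
        # randomizing each input node's targets destroys the block structure
        pmn = make_architecture_mask(ArchitectureSpec("pmn", 16, 8))
        intact_q = tabu_factions(association_matrix(pmn), 2, TabuParams(seed=0)).q
        assert intact_q == pytest.approx(0.5)
        rng = np.random.default_rng(2)
        null_qs = [
            tabu_factions(
                association_matrix(degree_preserving_null(pmn, rng)),
                2,
                TabuParams(seed=i),
            ).q
            for i in range(100)
        ]
        assert np.mean(null_qs) < intact_q
        assert max(null_qs) < intact_q


class TestPermutationInvariance:
    @given(st.integers(0, 2**31 - 1))
    def test_metrics_invariant_under_node_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((8, 8)) < 0.4).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        labels = rng.integers(0, 3, 8)
        perm = rng.permutation(8)
        a_perm = a[np.ix_(perm, perm)]
        labels_perm = labels[perm]
        assert newman_q(a_perm, labels_perm) == pytest.approx(newman_q(a, labels))
        assert faction_cost(a_perm, labels_perm) == faction_cost(a, labels)
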