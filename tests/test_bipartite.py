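import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biparclust as bp
from biparclust.bipartite import BipartiteNetwork
from biparclust.io_metadata import ExpressionMatrix

from conftest import block_network, exhaustive_best_q, random_network


class TestBuildNetwork:
    def test_log2_weighting(self):
        matrix = ExpressionMatrix(np.array([[8.0], [1.0]]), ["g1", "g2"], ["c1"])
        net = bp.build_network(matrix, ["g1", "g2"])
        np.testing.assert_allclose(net.weights, [[3.0, 0.0]])

    def test_hand_summed_toy(self):
        # X in {1,2,4} -> weights {0,1,2}
        values = np.array([[1.0, 2.0, 4.0], [4.0, 1.0, 2.0], [2.0, 4.0, 1.0]])
        matrix = ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3"])
        net = bp.build_network(matrix, ["g1", "g2", "g3"])
        assert net.m == pytest.approx(9.0)  # three each of 0, 1, 2
        assert net.weights.shape == (3, 3)

    def test_study_shape(self, study_network):
        assert (study_network.n_cases, study_network.n_genes) == (33, 100)

    def test_gene_restriction_preserves_order(self, toy):
        matrix, _ = toy
        net = bp.build_network(matrix, ["TG03", "TG01"])
        assert net.gene_ids == ["TG03", "TG01"]

    def test_empty_gene_list_and_all_zero(self, toy):
        matrix, _ = toy
        with pytest.raises(ValueError, match="empty"):
            bp.build_network(matrix, [])
        ones = ExpressionMatrix(np.ones((2, 2)), ["g1", "g2"], ["c1", "c2"])
        with pytest.raises(ValueError, match="all-zero"):
            bp.build_network(ones, ["g1", "g2"])

    def test_shared_ids_rejected(self):
        with pytest.raises(ValueError, match="both as case and gene"):
            BipartiteNetwork(["x"], ["x"], np.ones((1, 1)))


class TestModularity:
    def test_single_cluster_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            net = random_network(rng, 4, 5)
            q = bp.modularity(net, np.zeros(4, int), np.zeros(5, int))
            assert q == pytest.approx(0.0, abs=1e-15)

    def test_two_equal_blocks_give_half(self, toy_network):
        q = bp.modularity(
            toy_network, np.repeat([0, 1], 4), np.repeat([0, 1], 6)
        )
        assert q == pytest.approx(0.5, abs=1e-15)

    def test_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, 4, 5)
        case_labels = rng.integers(0, 3, 4)
        gene_labels = rng.integers(0, 3, 5)
        m = net.m
        s, t = net.case_strengths, net.gene_strengths
        expected = sum(
            (net.weights[i, j] - s[i] * t[j] / m) / m
            for i in range(4)
            for j in range(5)
            if case_labels[i] == gene_labels[j]
        )
        q = bp.modularity(net, case_labels, gene_labels)
        assert q == pytest.approx(expected, abs=1e-12)

    def test_mapping_interface_and_unknown_node(self, toy_network):
        assignment = {f"case:C{i+1}": 1 for i in range(8)}
        assignment.update({f"gene:TG{j+1:02d}": 1 for j in range(12)})
        assert bp.modularity(toy_network, assignment) == pytest.approx(0.0, abs=1e-15)
        del assignment["gene:TG01"]
        with pytest.raises(ValueError, match="missing node"):
            bp.modularity(toy_network, assignment)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_invariance_under_relabeling_and_reordering(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 5, 6)
        case_labels = rng.integers(0, 4, 5)
        gene_labels = rng.integers(0, 4, 6)
        q = bp.modularity(net, case_labels, gene_labels)
        # relabel clusters by a random label bijection
        relabel = rng.permutation(10)
        q_relab = bp.modularity(net, relabel[case_labels], relabel[gene_labels])
        assert q_relab == pytest.approx(q, abs=1e-12)
        # simultaneously permute node orderings
        pc, pg = rng.permutation(5), rng.permutation(6)
        permuted = BipartiteNetwork(
            [net.case_ids[i] for i in pc],
            [net.gene_ids[j] for j in pg],
            net.weights[np.ix_(pc, pg)],
        )
        q_perm = bp.modularity(permuted, case_labels[pc], gene_labels[pg])
        assert q_perm == pytest.approx(q, abs=1e-12)


class TestMaximizeModularity:
    def test_recovers_two_disjoint_blocks(self, toy_network):
        sol = bp.maximize_modularity(toy_network, seed=0, n_restarts=5)
        assert sol.n_clusters == 2
        assert sol.q == pytest.approx(0.5, abs=1e-12)
        assert len(set(sol.case_labels[:4])) == 1
        assert len(set(sol.case_labels[4:])) == 1
        assert sol.case_labels[0] != sol.case_labels[4]

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_attains_block_closed_form(self, k):
        sol = bp.maximize_modularity(block_network(k), seed=0, n_restarts=10)
        assert sol.q == pytest.approx(1 - 1 / k, abs=1e-12)
        assert sol.n_clusters == k

    def test_matches_exhaustive_search_on_tiny_networks(self):
        rng = np.random.default_rng(11)
        for trial in range(8):
            n, d = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            net = random_network(rng, n, d)
            sol = bp.maximize_modularity(net, seed=trial, n_restarts=50)
            assert sol.q == pytest.approx(exhaustive_best_q(net), abs=1e-12)

    def test_never_below_single_cluster_baseline(self):
        rng = np.random.default_rng(12)
        for trial in range(10):
            net = random_network(rng, 5, 5)
            sol = bp.maximize_modularity(net, seed=trial, n_restarts=3)
            assert sol.q >= 0.0

    def test_monotone_in_restarts(self):
        rng = np.random.default_rng(13)
        net = random_network(rng, 8, 10)
        qs = [
            bp.maximize_modularity(net, seed=42, n_restarts=r).q
            for r in (1, 2, 5, 10)
        ]
        assert qs == sorted(qs)

    def test_labels_contiguous_and_flagging(self, toy_network):
        sol = bp.maximize_modularity(toy_network, seed=1, n_restarts=5)
        labels = set(sol.case_labels) | set(sol.gene_labels)
        assert labels == set(range(1, sol.n_clusters + 1))
        assert sol.single_sided == []

    def test_solution_json_round_trip(self, toy_network, tmp_path):
        sol = bp.maximize_modularity(toy_network, seed=2, n_restarts=5)
        path = tmp_path / "solution.json"
        sol.to_json(path)
        again = bp.BiclusterSolution.from_json(path)
        assert again.assignment == sol.assignment
        assert again.q == pytest.approx(sol.q)


def test_network_json_round_trip(toy_network, tmp_path):
    path = tmp_path / "net.json"
    toy_network.to_json(path)
    again = BipartiteNetwork.from_json(path)
    assert again.case_ids == toy_network.case_ids
    np.testing.assert_allclose(again.weights, toy_network.weights)
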