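"""Edge-list parsing, network assembly, and random walk with restart."""

import numpy as np
import pandas as pd
import pytest

from metabarcode.network import (
    EdgeFileError,
    InteractionEdge,
    assemble_network,
    featurize_combinations,
    load_edges,
    make_seed,
    rwr_steady_state,
    transition_matrix,
)


def write_edges(tmp_path, rows, cols=("protein1", "protein2", "combined_score")):
    path = tmp_path / "edges.tsv"
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, sep="\t", index=False)
    return path


def edge_list(pairs):
    return [InteractionEdge(a, b, w) for a, b, w in pairs]


class TestLoadEdges:
    def test_duplicates_merge_keeping_max_and_rescale(self, tmp_path):
        path = write_edges(tmp_path, [["A", "B", 900], ["B", "A", 700]])
        edges = load_edges(path)
        assert len(edges) == 1
        assert edges[0].weight == pytest.approx(0.9)

    def test_threshold_boundary_inclusive(self, tmp_path):
        path = write_edges(
            tmp_path, [["A", "B", 0.39], ["A", "C", 0.40], ["A", "D", 0.41]]
        )
        assert len(load_edges(path, score_threshold=0.4)) == 2

    def test_self_loops_dropped(self, tmp_path):
        path = write_edges(tmp_path, [["A", "A", 500], ["A", "B", 500]])
        assert len(load_edges(path)) == 1

    def test_negative_score_rejected_with_row(self, tmp_path):
        path = write_edges(tmp_path, [["A", "B", 500], ["A", "C", -1]])
        with pytest.raises(EdgeFileError, match="row 3"):
            load_edges(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"a": ["x"], "b": ["y"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(EdgeFileError, match="3 columns"):
            load_edges(path)


class TestAssembleNetwork:
    def test_components_without_metabolites_removed(self):
        net = assemble_network(
            ["M"],
            edge_list([("M", "P1", 1.0)]),
            edge_list([("P1", "P2", 1.0), ("P3", "P4", 1.0)]),
        )
        assert net.node_ids == ["M", "P1", "P2"]
        assert net.node_kind == ["metabolite", "protein", "protein"]

    def test_shared_protein_joins_metabolites(self):
        net = assemble_network(
            ["M1", "M2"],
            edge_list([("M1", "P1", 1.0), ("M2", "P1", 0.5)]),
            [],
        )
        assert net.N == 3 and net.n_edges == 2

    def test_no_connection_is_an_error(self):
        with pytest.raises(ValueError, match="no metabolite"):
            assemble_network(["M"], [], edge_list([("P1", "P2", 1.0)]))


class TestTransitionMatrix:
    def test_path_graph_rows(self):
        net = assemble_network(
            ["A"], edge_list([("A", "B", 1.0)]), edge_list([("B", "C", 1.0)])
        )
        W = transition_matrix(net)
        idx = {n: i for i, n in enumerate(net.node_ids)}
        assert W[idx["A"]][idx["B"]] == 1.0
        assert W[idx["B"]][idx["A"]] == 0.5 and W[idx["B"]][idx["C"]] == 0.5
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)

    def test_weighted_star(self):
        net = assemble_network(
            ["M"], edge_list([("M", "P1", 1.0), ("M", "P2", 3.0)]), []
        )
        W = transition_matrix(net)
        i = net.index_of("M")
        assert W[i][net.index_of("P1")] == pytest.approx(0.25)
        assert W[i][net.index_of("P2")] == pytest.approx(0.75)

    def test_random_fixture_rows_sum_to_one(self, small_network):
        W = transition_matrix(small_network.net)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)


class TestSeedVector:
    def test_partial_target_presence(self, small_network):
        net = small_network.net
        present = [n for n in net.node_ids if n.startswith("P")][:2]
        p0 = make_seed(present + ["NOT_A_NODE"], net)
        assert p0.sum() == pytest.approx(1.0)
        assert sorted(p0[p0 > 0]) == [0.5, 0.5]

    def test_union_idempotence(self, small_network):
        net = small_network.net
        targets = [n for n in net.node_ids if n.startswith("P")][:3]
        assert np.array_equal(make_seed(targets, net), make_seed(targets * 2, net))

    def test_all_absent_raises(self, small_network):
        with pytest.raises(ValueError, match="no target"):
            make_seed(["NOPE"], small_network.net)


class TestRWR:
    def two_node(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        return W, np.array([1.0, 0.0])

    def test_restart_only_limit_returns_seed(self):
        W, p0 = self.two_node()
        assert np.allclose(rwr_steady_state(W, p0, lam=1.0).pt, p0)

    def test_two_node_closed_form(self):
        W, p0 = self.two_node()
        for method in ("closed", "iterative"):
            pt = rwr_steady_state(W, p0, lam=0.5, method=method).pt
            assert pt == pytest.approx([2 / 3, 1 / 3], abs=1e-9)

    def test_complete_graph_uniform(self):
        n = 5
        A = np.ones((n, n)) - np.eye(n)
        W = A / A.sum(axis=1, keepdims=True)
        pt = rwr_steady_state(W, np.full(n, 1 / n), lam=0.3).pt
        assert pt == pytest.approx(np.full(n, 1 / n), abs=1e-10)

    def test_brute_force_oracle_small_graphs(self):
        """On tiny graphs the steady state must match plain fixed-point
        iteration of the recursion written out with explicit loops."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            A = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
            A = np.triu(A, 1)
            A = A + A.T
            A[A.sum(axis=1) == 0, rng.integers(0, n)] = 1.0  # no dead nodes
            A = np.maximum(A, A.T)
            np.fill_diagonal(A, 0.0)
            W = A / A.sum(axis=1, keepdims=True)
            p0 = np.zeros(n)
            p0[int(rng.integers(0, n))] = 1.0
            lam = float(rng.uniform(0.2, 0.9))
            # brute-force: iterate the recursion element-wise
            p = list(p0)
            for _ in range(5000):
                nxt = [
                    (1 - lam) * sum(W[j][i] * p[j] for j in range(n)) + lam * p0[i]
                    for i in range(n)
                ]
                p = nxt
            pt = rwr_steady_state(W, p0, lam=lam, method="closed").pt
            assert pt == pytest.approx(np.array(p), abs=1e-8)

    def test_mass_conserved_and_methods_agree(self, small_network):
        net = small_network.net
        W = transition_matrix(net)
        p0 = make_seed([net.node_ids[-1]], net)
        closed = rwr_steady_state(W, p0, method="closed").pt
        iterative = rwr_steady_state(W, p0, method="iterative", tol=1e-12).pt
        assert closed.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.abs(closed - iterative).sum() < 1e-8

    def test_decreasing_lambda_decreases_seed_mass(self):
        W, p0 = self.two_node()
        masses = [
            rwr_steady_state(W, p0, lam=lam).pt[0] for lam in (0.9, 0.5, 0.2)
        ]
        assert masses[0] > masses[1] > masses[2]

    def test_invalid_lambda(self):
        W, p0 = self.two_node()
        with pytest.raises(ValueError, match="lambda"):
            rwr_steady_state(W, p0, lam=0.0)


class TestFeaturize:
    def test_rows_sum_to_one(self, small_network):
        net, targets = small_network.net, {}
        prots = [n for n in net.node_ids if n.startswith("P")]
        targets = {"d1": prots[:2], "d2": prots[2:4], "d3": prots[1:3]}
        X = featurize_combinations([("d1", "d2"), ("d1", "d3")], targets, net)
        assert X.shape == (2, net.N)
        assert np.allclose(X.sum(axis=1), 1.0, atol=1e-9)
        assert list(X.columns) == net.node_ids

    def test_identical_target_sets_identical_rows(self, small_network):
        net = small_network.net
        prots = [n for n in net.node_ids if n.startswith("P")]
        targets = {"a": prots[:3], "b": prots[:3], "c": prots[3:5]}
        X = featurize_combinations([("a", "c"), ("b", "c")], targets, net)
        assert np.allclose(X.loc["a+c"], X.loc["b+c"])

    def test_node_relabeling_equivariance(self):
        met_prot = edge_list([("M", "P1", 1.0), ("M", "P2", 0.5)])
        prot_prot = edge_list([("P1", "P2", 0.8), ("P2", "P3", 0.6)])
        net = assemble_network(["M"], met_prot, prot_prot)
        relabel = {"M": "M", "P1": "Q3", "P2": "Q1", "P3": "Q2"}
        net2 = assemble_network(
            ["M"],
            [InteractionEdge(relabel[e.node_a], relabel[e.node_b], e.weight) for e in met_prot],
            [InteractionEdge(relabel[e.node_a], relabel[e.node_b], e.weight) for e in prot_prot],
        )
        targets = {"d": ["P1"], "e": ["P3"]}
        targets2 = {"d": ["Q3"], "e": ["Q2"]}
        X = featurize_combinations([("d", "e")], targets, net)
        X2 = featurize_combinations([("d", "e")], targets2, net2)
        for old, new in relabel.items():
            assert X.loc["d+e", old] == pytest.approx(X2.loc["d+e", new])

    def test_missing_targets_collected(self, small_network):
        net = small_network.net
        with pytest.raises(ValueError, match="no in-network target"):
            featurize_combinations([("x", "y")], {"x": ["Z"], "y": []}, net)
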