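import numpy as np
import pytest

from netsgcca.graph import (PriorGraph, align_graph, build_laplacian,
                            graph_summary, largest_eigenvalue, load_graph,
                            pairwise_distances, permute_labels, remove_edges)


class TestLoadGraph:
    def test_reversed_duplicate_edges_collapse(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("A B\nB A\nA B\n")
        g = load_graph(f)
        assert g.n_edges == 1 and g.edges == {frozenset(("A", "B"))}

    def test_sif_fans_out_over_targets(self, tmp_path):
        f = tmp_path / "g.sif"
        f.write_text("A\tinteracts-with\tB\tC\n")
        g = load_graph(f, format="sif")
        assert g.edges == {frozenset(("A", "B")), frozenset(("A", "C"))}

    def test_self_loop_dropped(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("A A\nA B\n")
        g = load_graph(f)
        assert g.n_edges == 1 and "A" in g.nodes

    def test_malformed_line_reports_number(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("A B\nA\n")
        with pytest.raises(ValueError, match=":2"):
            load_graph(f)

    def test_comment_and_weight_column(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("# comment\nA B 2.5\n")
        g = load_graph(f)
        assert g.g["A"]["B"]["weight"] == 2.5


class TestAlign:
    def test_missing_feature_becomes_isolated(self):
        g = PriorGraph.from_edges(["g1", "g2"], [("g1", "g2")])
        a = align_graph(g, ["g1", "g2", "g3"])
        assert a.nodes == ["g1", "g2", "g3"]
        assert a.n_edges == 1 and a.degree("g3") == 0

    def test_duplicate_features_copy_edges(self):
        g = PriorGraph.from_edges(["N", "a", "b"], [("N", "a"), ("N", "b")])
        a = align_graph(g, ["f1", "f2", "a", "b"],
                        feature_to_node={"f1": "N", "f2": "N"})
        assert a.degree("f1") == 2 and a.degree("f2") == 2
        assert frozenset(("f1", "a")) in a.edges
        assert frozenset(("f2", "b")) in a.edges

    def test_extra_graph_nodes_dropped(self):
        g = PriorGraph.from_edges(["g1", "g2", "z"], [("g1", "z")])
        a = align_graph(g, ["g1", "g2"])
        assert "z" not in a.nodes and a.n_edges == 0

    def test_empty_feature_list_rejected(self, p3_graph):
        with pytest.raises(ValueError):
            align_graph(p3_graph, [])


class TestLaplacian:
    def test_raw_path_matrix(self, p3_graph):
        L = build_laplacian(p3_graph, "raw")
        np.testing.assert_allclose(
            L.matrix.toarray(), [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_normalized_path_matrix(self, p3_graph):
        L = build_laplacian(p3_graph, "normalized")
        r = 1 / np.sqrt(2)
        np.testing.assert_allclose(
            L.matrix.toarray(), [[1, -r, 0], [-r, 1, -r], [0, -r, 1]],
            atol=1e-12)

    def test_isolated_node_zero_row_both_variants(self):
        g = PriorGraph.from_edges(["a", "b", "c"], [("a", "b")])
        for variant in ("raw", "normalized"):
            L = build_laplacian(g, variant).matrix.toarray()
            assert np.all(L[2] == 0) and np.all(L[:, 2] == 0)

    def test_lambda_max_path_is_three(self, p3_graph):
        L = build_laplacian(p3_graph, "raw")
        assert largest_eigenvalue(L) == pytest.approx(3.0, rel=1e-6)

    def test_lambda_max_normalized_edge_is_two(self):
        g = PriorGraph.from_edges(["a", "b"], [("a", "b")])
        L = build_laplacian(g, "normalized")
        assert largest_eigenvalue(L) == pytest.approx(2.0, rel=1e-6)

    def test_edgeless_lambda_max_zero(self):
        g = PriorGraph.from_edges(["a", "b"], [])
        assert largest_eigenvalue(build_laplacian(g, "raw")) == 0.0

    @pytest.mark.parametrize("variant", ["raw", "normalized"])
    def test_psd_and_dense_oracle_agreement(self, variant):
        rng = np.random.default_rng(7)
        for trial in range(5):
            p = int(rng.integers(5, 60))
            nodes = [f"n{i}" for i in range(p)]
            edges = [(nodes[i], nodes[j]) for i in range(p) for j in range(i + 1, p)
                     if rng.random() < 0.1]
            g = PriorGraph.from_edges(nodes, edges)
            L = build_laplacian(g, variant)
            dense = np.linalg.eigvalsh(L.matrix.toarray())
            assert dense[0] > -1e-10  # PSD
            lam = largest_eigenvalue(L)
            assert lam == pytest.approx(max(dense[-1], 0.0), rel=1e-6, abs=1e-9)
            if variant == "normalized":
                assert lam <= 2 + 1e-9
            # quadratic form nonnegative on random vectors
            for _ in range(3):
                w = rng.standard_normal(p)
                assert w @ (L.matrix @ w) >= -1e-9


class TestPermuteAndRemove:
    def test_permute_preserves_degree_multiset_and_summary(self, p3_graph):
        perm = permute_labels(p3_graph, seed=3)
        assert sorted(perm.g.degree[v] for v in perm.nodes) == [1, 1, 2]
        a, b = graph_summary(p3_graph), graph_summary(perm)
        assert a == b

    def test_permute_deterministic(self, p3_graph):
        assert permute_labels(p3_graph, 5).edges == permute_labels(p3_graph, 5).edges

    def test_single_node_identity(self):
        g = PriorGraph.from_edges(["x"], [])
        assert permute_labels(g, 0).nodes == ["x"]

    def test_remove_fraction_zero_and_one(self, p3_graph):
        assert remove_edges(p3_graph, "random", fraction=0.0).edges == p3_graph.edges
        empty = remove_edges(p3_graph, "random", fraction=1.0)
        assert empty.n_edges == 0 and empty.nodes == p3_graph.nodes

    def test_fraction_out_of_range(self, p3_graph):
        with pytest.raises(ValueError):
            remove_edges(p3_graph, "random", fraction=1.5)

    def test_isolate_zeroes_subset_degrees(self, p3_graph):
        out = remove_edges(p3_graph, "isolate", node_subset={"g2"})
        assert out.degree("g2") == 0

    def test_inner_then_outer_equals_isolate(self):
        rng = np.random.default_rng(11)
        nodes = [f"n{i}" for i in range(12)]
        edges = [(nodes[i], nodes[j]) for i in range(12) for j in range(i + 1, 12)
                 if rng.random() < 0.3]
        g = PriorGraph.from_edges(nodes, edges)
        S = set(nodes[:5])
        step = remove_edges(remove_edges(g, "inner", node_subset=S),
                            "outer", node_subset=S)
        direct = remove_edges(g, "isolate", node_subset=S)
        assert step.edges == direct.edges

    def test_subset_modes_require_subset(self, p3_graph):
        with pytest.raises(ValueError):
            remove_edges(p3_graph, "inner", node_subset=set())


class TestSummaryAndDistances:
    def test_path_summary(self, p3_graph):
        s = graph_summary(p3_graph)
        assert s["n_nodes"] == 3 and s["n_edges"] == 2
        assert s["density"] == pytest.approx(2 / 3)
        assert s["isolated_fraction"] == 0
        assert s["diameter"] == 2 and s["radius"] == 1

    def test_edgeless_summary(self):
        g = PriorGraph.from_edges(list("abcd"), [])
        s = graph_summary(g)
        assert s["density"] == 0 and s["isolated_fraction"] == 1.0

    def test_complete_graph_summary(self):
        nodes = list("abcd")
        edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        s = graph_summary(PriorGraph.from_edges(nodes, edges))
        assert s["density"] == 1.0 and s["diameter"] == 1

    def test_distances(self, p3_graph):
        d = pairwise_distances(p3_graph, ["g1", "g3"])
        assert d[("g1", "g3")] == 2 and d[("g1", "g1")] == 0

    def test_disconnected_pair_infinite(self):
        g = PriorGraph.from_edges(["a", "b", "c"], [("a", "b")])
        d = pairwise_distances(g, ["a", "c"])
        assert np.isinf(d[("a", "c")])

    def test_unknown_node_rejected(self, p3_graph):
        with pytest.raises(KeyError):
            pairwise_distances(p3_graph, ["g1", "zz"])
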