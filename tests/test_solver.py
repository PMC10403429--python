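import numpy as np
import pytest

from netsgcca import SyntheticSpec, simulate_two_block
from netsgcca.blocks import Block, ConnectionDesign, GraphPenaltyConfig
from netsgcca.graph import PriorGraph, build_laplacian
from netsgcca.model import (NetSGCCA, PenaltyTerm, SolverSettings,
                            block_gradient, deflate, graphnet_value,
                            initial_step, objective)

from conftest import random_blocks


def two_column_blocks():
    col = np.array([[1.0], [-1.0]])
    return [
        Block("a", col, ["fa"], ["s0", "s1"]),
        Block("b", col.copy(), ["fb"], ["s0", "s1"]),
    ]


def p3_penalty(gamma, block_index=0):
    g = PriorGraph.from_edges(["g1", "g2", "g3"], [("g1", "g2"), ("g2", "g3")])
    return PenaltyTerm(laplacian=build_laplacian(g, "raw"), gamma=gamma,
                       block_index=block_index)


class TestObjective:
    def test_two_block_hand_value(self):
        blocks = two_column_blocks()
        val = objective(blocks, [np.array([1.0]), np.array([1.0])],
                        ConnectionDesign.complete(2))
        assert val == pytest.approx(-2.0)  # both ordered pairs contribute -1

    def test_zero_weights_zero(self):
        blocks = two_column_blocks()
        assert objective(blocks, [np.zeros(1), np.zeros(1)],
                         ConnectionDesign.complete(2)) == 0.0

    def test_gamma_zero_matches_no_penalty(self):
        rng = np.random.default_rng(0)
        blocks = random_blocks(4, n=10, J=2, p_max=3)
        ws = [rng.standard_normal(b.n_features) for b in blocks]
        d = ConnectionDesign.complete(2)
        g = PriorGraph.from_edges(blocks[0].feature_names,
                                  [tuple(blocks[0].feature_names[:2])])
        pen = PenaltyTerm(build_laplacian(g, "raw"), gamma=0.0, block_index=0)
        assert objective(blocks, ws, d, pen) == objective(blocks, ws, d, None)


class TestGraphnetValue:
    def test_zero_weight(self):
        assert graphnet_value(np.zeros(3), p3_penalty(2.0)) == 0.0

    def test_unit_basis_vector(self):
        # w'Lw = L_11 = 1, lambda_max = 3, gamma = 3 -> value 1
        val = graphnet_value(np.array([1.0, 0.0, 0.0]), p3_penalty(3.0))
        assert val == pytest.approx(1.0, rel=1e-6)

    def test_lambda_max_bound_for_unit_vectors(self):
        rng = np.random.default_rng(1)
        pen = p3_penalty(5.0)
        for _ in range(20):
            w = rng.standard_normal(3)
            w /= np.linalg.norm(w)
            assert graphnet_value(w, pen) <= 5.0 * (1 + 1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            graphnet_value(np.zeros(5), p3_penalty(1.0))


class TestGradient:
    def test_finite_difference_agreement(self):
        rng = np.random.default_rng(2)
        blocks = random_blocks(5, n=12, J=3, p_max=6)
        d = ConnectionDesign.complete(3)
        g = PriorGraph.from_edges(blocks[0].feature_names,
                                  [(blocks[0].feature_names[0],
                                    blocks[0].feature_names[1])])
        pen = PenaltyTerm(build_laplacian(g, "raw"), gamma=1.7, block_index=0)
        ws = [rng.standard_normal(b.n_features) for b in blocks]
        eps = 1e-6
        for j in range(3):
            grad = block_gradient(j, blocks, ws, d, pen)
            for i in range(blocks[j].n_features):
                wp = [w.copy() for w in ws]
                wm = [w.copy() for w in ws]
                wp[j][i] += eps
                wm[j][i] -= eps
                fd = (objective(blocks, wp, d, pen)
                      - objective(blocks, wm, d, pen)) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_zero_partner_weights_no_penalty(self):
        blocks = random_blocks(6, n=10, J=2, p_max=4)
        d = ConnectionDesign.complete(2)
        ws = [np.ones(blocks[0].n_features), np.zeros(blocks[1].n_features)]
        np.testing.assert_allclose(block_gradient(0, blocks, ws, d, None), 0.0)


class TestStepAndDeflate:
    def test_initial_step_values(self):
        assert initial_step(5.0) == pytest.approx(0.1)
        assert initial_step(0.0) == 1.0

    def test_deflation_zeroes_self_column(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 4))
        b = Block("b", X, list("abcd"), [f"s{i}" for i in range(10)])
        out, _ = deflate(b, X[:, 1])
        np.testing.assert_allclose(out.matrix[:, 1], 0, atol=1e-10)
        # all columns orthogonal to the component
        np.testing.assert_allclose(X[:, 1] @ out.matrix, 0, atol=1e-9)

    def test_deflation_idempotent(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((8, 3))
        b = Block("b", X, list("abc"), [f"s{i}" for i in range(8)])
        t = rng.standard_normal(8)
        once, _ = deflate(b, t)
        twice, _ = deflate(once, t)
        np.testing.assert_allclose(once.matrix, twice.matrix, atol=1e-10)

    def test_zero_component_rejected(self):
        b = Block("b", np.eye(3), list("abc"), list("xyz"))
        with pytest.raises(ValueError):
            deflate(b, np.zeros(3))


class TestFit:
    def test_perfectly_correlated_single_features(self):
        model = NetSGCCA(two_column_blocks(), sparsity=[1.0, 1.0])
        res = model.fit()
        for w in res.weights[0]:
            assert abs(abs(w[0]) - 1.0) < 1e-6
        # covariance of the scaled columns is 1 -> objective -2
        assert res.objective_value() == pytest.approx(-2.0, abs=1e-6)

    def test_component_tracks_latent_factor(self):
        ds = simulate_two_block(SyntheticSpec(
            n=100, p1=50, p2=50, support_size=10, seed=1,
            graph_params={"n_communities": 5, "size": 10}))
        res = NetSGCCA(ds.blocks, sparsity=[3.0, 3.0]).fit()
        t1, t2 = res.components[0]
        # block 2 noise is independent, so its component can track the
        # latent factor almost perfectly
        assert abs(np.corrcoef(t2, ds.latent)[0, 1]) > 0.9
        # block-1 support noise is graph-correlated and does not average
        # out; the fitted component must track the latent factor at least
        # as well as the oracle equal-weight support component does
        sup = [i for i, nm in enumerate(ds.blocks[0].feature_names)
               if nm in ds.truth]
        w_oracle = np.zeros(ds.blocks[0].n_features)
        w_oracle[sup] = 1.0
        oracle_corr = abs(np.corrcoef(ds.blocks[0].matrix @ w_oracle,
                                      ds.latent)[0, 1])
        assert abs(np.corrcoef(t1, ds.latent)[0, 1]) > 0.95 * oracle_corr

    def test_gamma_zero_trace_equals_unpenalized_run(self, synth_ds):
        sp = [2.0, 2.0]
        pen = GraphPenaltyConfig(target_block="block1", gamma=0.0)
        r0 = NetSGCCA(synth_ds.blocks, sparsity=sp).fit()
        r1 = NetSGCCA(synth_ds.blocks, sparsity=sp, penalty=pen,
                      graph=synth_ds.graph).fit()
        np.testing.assert_allclose(r0.objective_traces[0],
                                   r1.objective_traces[0], rtol=1e-12)

    def test_same_seed_reproducible(self, fast_settings):
        blocks = random_blocks(7, n=15, J=2, p_max=8)
        r1 = NetSGCCA(blocks, sparsity=[1.5, 1.5]).fit(settings=fast_settings)
        r2 = NetSGCCA(blocks, sparsity=[1.5, 1.5]).fit(settings=fast_settings)
        for a, b in zip(r1.weights[0], r2.weights[0]):
            np.testing.assert_array_equal(a, b)

    def test_sign_canonicalization(self, fast_settings):
        blocks = random_blocks(8, n=15, J=2, p_max=8)
        res = NetSGCCA(blocks, sparsity=[1.5, 1.5]).fit(settings=fast_settings)
        w0 = res.weights[0][0]
        assert w0[int(np.argmax(np.abs(w0)))] >= 0

    def test_edgeless_graph_with_positive_gamma_rejected(self):
        blocks = random_blocks(9, n=10, J=2, p_max=5)
        g = PriorGraph.from_edges(blocks[0].feature_names, [])
        pen = GraphPenaltyConfig(target_block="b0", gamma=1.0)
        with pytest.raises(ValueError, match="gamma = 0"):
            NetSGCCA(blocks, sparsity=[1.5, 1.5], penalty=pen, graph=g)

    def test_second_component_orthogonal_scores(self, fast_settings):
        blocks = random_blocks(10, n=25, J=2, p_max=10)
        res = NetSGCCA(blocks, sparsity=[2.0, 2.0]).fit(
            n_components=2, settings=fast_settings)
        for j in range(2):
            t1, t2 = res.components[0][j], res.components[1][j]
            assert abs(t1 @ t2) < 1e-6 * np.linalg.norm(t1) * np.linalg.norm(t2) + 1e-8


class TestTransform:
    def test_training_data_reproduces_components(self, fast_settings):
        blocks = random_blocks(11, n=20, J=2, p_max=8)
        res = NetSGCCA(blocks, sparsity=[1.5, 1.5]).fit(
            n_components=2, settings=fast_settings)
        scores = res.transform(blocks)
        for j, name in enumerate(res.block_names):
            for k in range(2):
                np.testing.assert_allclose(scores[name][:, k],
                                           res.components[k][j], atol=1e-10)

    def test_permuted_feature_columns_identical(self, fast_settings):
        blocks = random_blocks(12, n=20, J=2, p_max=8)
        res = NetSGCCA(blocks, sparsity=[1.5, 1.5]).fit(settings=fast_settings)
        b = blocks[0]
        perm = np.arange(b.n_features)[::-1]
        shuffled = Block(b.name, b.matrix[:, perm],
                         [b.feature_names[i] for i in perm],
                         list(b.sample_ids))
        out1 = res.transform({b.name: b}, partial=True)
        out2 = res.transform({b.name: shuffled}, partial=True)
        np.testing.assert_allclose(out1[b.name], out2[b.name], atol=1e-12)

    def test_feature_mismatch_listed(self, fast_settings):
        blocks = random_blocks(13, n=20, J=2, p_max=8)
        res = NetSGCCA(blocks, sparsity=[1.5, 1.5]).fit(settings=fast_settings)
        b = blocks[0]
        bad = Block(b.name, b.matrix, [f"x{i}" for i in range(b.n_features)],
                    list(b.sample_ids))
        with pytest.raises(ValueError, match="mismatch"):
            res.transform({b.name: bad}, partial=True)

    def test_missing_block_requires_partial(self, fast_settings):
        blocks = random_blocks(14, n=20, J=2, p_max=8)
        res = NetSGCCA(blocks, sparsity=[1.5, 1.5]).fit(settings=fast_settings)
        with pytest.raises(ValueError, match="missing block"):
            res.transform({blocks[0].name: blocks[0]})


class TestResultsSurface:
    def test_summary_and_save(self, tmp_path, fast_settings):
        blocks = random_blocks(15, n=15, J=2, p_max=6)
        res = NetSGCCA(blocks, sparsity=[1.5, 1.5]).fit(settings=fast_settings)
        text = res.summary()
        assert "netSGCCA" in text and "b0" in text
        res.save(tmp_path / "out")
        assert (tmp_path / "out" / "weights_b0.tsv").exists()
        assert (tmp_path / "out" / "components.tsv").exists()
        assert (tmp_path / "out" / "run_metadata.json").exists()

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SolverSettings(outer_tol=0)
        with pytest.raises(ValueError):
            SolverSettings(init="bogus")
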