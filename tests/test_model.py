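"""Graph attention auto-encoder, contrastive components and training."""

import numpy as np
import pytest

from spotfuse import RunConfig, SpotDataset, build_graph
from spotfuse.autograd import Parameter, Tensor
from spotfuse.graph import SpatialGraph
from spotfuse.model import (
    GATLayer,
    GclModel,
    attention_coefficients,
    contrastive_loss,
    corrupt,
    discriminate,
    neighborhood_softmax,
    readout,
    reconstruction_loss,
    train,
)


def _graph_from_edges(n, undirected_edges):
    """Directed edge arrays with self-loops from an undirected edge list."""
    src, dst = [], []
    for i in range(n):
        src.append(i)
        dst.append(i)
    for i, j in undirected_edges:
        src += [i, j]
        dst += [j, i]
    return SpatialGraph(
        n=n, radius=1.0, edge_src=np.array(src), edge_dst=np.array(dst)
    )


def _random_graph(n, seed, p=0.3):
    rng = np.random.default_rng(seed)
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return _graph_from_edges(n, edges)


class TestNeighborhoodSoftmax:
    def test_self_only_neighbor_gives_one(self):
        g = _graph_from_edges(1, [])
        e = Tensor(np.array([[0.37]]))
        alpha = neighborhood_softmax(e, g.edge_dst, 1)
        assert alpha.data[0, 0] == pytest.approx(1.0)

    def test_equal_scores_give_uniform_weights(self):
        g = _graph_from_edges(3, [(0, 1), (0, 2)])
        e = Tensor(np.full((g.n_edges, 1), 0.42))
        alpha = neighborhood_softmax(e, g.edge_dst, 3).data[:, 0]
        deg = np.bincount(g.edge_dst)
        np.testing.assert_allclose(alpha, 1.0 / deg[g.edge_dst])

    def test_log_two_gap_gives_one_third_two_thirds(self):
        # scores {0, ln 2} over a two-member neighborhood -> {1/3, 2/3}
        src = np.array([0, 1])
        dst = np.array([0, 0])
        e = Tensor(np.array([[0.0], [np.log(2.0)]]))
        alpha = neighborhood_softmax(e, dst, 1).data[:, 0]
        np.testing.assert_allclose(alpha, [1 / 3, 2 / 3])

    def test_rows_sum_to_one_on_random_graphs(self):
        for seed in range(20):
            n = int(np.random.default_rng(seed).integers(2, 50))
            g = _random_graph(n, seed)
            e = Tensor(np.random.default_rng(seed + 1).normal(size=(g.n_edges, 1)))
            alpha = neighborhood_softmax(e, g.edge_dst, n)
            sums = np.bincount(g.edge_dst, weights=alpha.data[:, 0], minlength=n)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)


class TestAttention:
    def test_attention_matches_dense_formula(self):
        """Hand-evaluated edge scores and softmax on a 2-node path graph."""
        rng = np.random.default_rng(0)
        g = _graph_from_edges(2, [(0, 1)])
        Z = Tensor(rng.normal(size=(2, 3)))
        W = Parameter(rng.normal(size=(4, 3)))
        v_s = Parameter(rng.normal(size=(4, 1)))
        v_k = Parameter(rng.normal(size=(4, 1)))
        alpha, Wh = attention_coefficients(
            Z, W, v_s, v_k, g.edge_src, g.edge_dst, 2
        )

        def elu(x):
            return np.where(x > 0, x, np.expm1(x))

        gz = elu(Z.data @ W.data.T)
        es = gz @ v_s.data
        ek = gz @ v_k.data
        e = 1 / (1 + np.exp(-(es[g.edge_dst] + ek[g.edge_src])))
        expected = np.vstack(
            [
                np.exp(e[k]) / sum(
                    np.exp(e[m])
                    for m in range(g.n_edges)
                    if g.edge_dst[m] == g.edge_dst[k]
                )
                for k in range(g.n_edges)
            ]
        )
        np.testing.assert_allclose(alpha.data, expected, atol=1e-10)
        np.testing.assert_allclose(Wh.data, Z.data @ W.data.T)


class TestEncodeDecode:
    def _model(self, f1=6, f2=4, hidden=5, seed=0):
        cfg = RunConfig(
            seed=seed, hidden=hidden, f1_latent=3, f2_latent=2, f_joint=5, f_embed=2
        )
        return GclModel(f1, f2, cfg), cfg

    def test_zero_inputs_zero_weights_give_zero_embedding(self):
        model, _ = self._model()
        for layer in model.expr_layers + model.img_layers + [model.joint_layer]:
            layer.W.data[:] = 0.0
        g = _random_graph(5, 1)
        emb = model.encode(Tensor(np.zeros((5, 6))), Tensor(np.zeros((5, 4))), g)
        np.testing.assert_allclose(emb.H.data, 0.0)  # ELU(0) = 0

    def test_single_layer_matches_dense_oracle(self):
        """GAT layer on a 2-node path graph vs dense matrix-product oracle."""
        rng = np.random.default_rng(2)
        layer = GATLayer(3, 4, rng)
        g = _graph_from_edges(2, [(0, 1)])
        Z = Tensor(rng.normal(size=(2, 3)))
        out, alpha = layer.encode(Z, g)

        def elu(x):
            return np.where(x > 0, x, np.expm1(x))

        A = np.zeros((2, 2))
        for k in range(g.n_edges):
            A[g.edge_dst[k], g.edge_src[k]] = alpha.data[k, 0]
        expected = elu(A @ (Z.data @ layer.W.data.T))
        np.testing.assert_allclose(out.data, expected, atol=1e-8)

    def test_default_embedding_width_is_30(self, small_dataset):
        g = build_graph(small_dataset.coords, spacing=small_dataset.spot_spacing)
        X = np.random.default_rng(0).normal(size=(small_dataset.n_spots, 40))
        model, H, _ = train(X, None, g, RunConfig(seed=0), epochs=2)
        assert H.shape == (small_dataset.n_spots, 30)

    def test_decoder_adds_no_parameters(self):
        model, _ = self._model()
        n_with = model.parameter_count(include_decoder=True)
        n_without = model.parameter_count(include_decoder=False)
        assert n_with == n_without
        # explicit census: every tensor belongs to the encoder or the
        # discriminator; decoding reuses them (W transposed, alpha shared)
        expected = sum(
            w.data.size
            for layer in model.expr_layers + model.img_layers + [model.joint_layer]
            for w in layer.parameters()
        ) + model.B.data.size
        assert n_with == expected
        assert not any(k.startswith("dec") for k in model.state_dict())

    def test_decode_shapes_and_gradient_flow_into_encoder(self):
        model, _ = self._model()
        g = _random_graph(5, 3)
        rng = np.random.default_rng(4)
        emb = model.encode(
            Tensor(rng.normal(size=(5, 6))), Tensor(rng.normal(size=(5, 4))), g
        )
        xhat, ihat = model.decode(emb, g)
        assert xhat.shape == (5, 6) and ihat.shape == (5, 4)
        (xhat.row_norms().sum() + ihat.row_norms().sum()).backward()
        for layer in model.expr_layers + model.img_layers + [model.joint_layer]:
            assert layer.W.grad is not None and np.any(layer.W.grad != 0)

    def test_decode_matches_dense_oracle_on_tiny_graph(self):
        """Joint decode with tied weight and reused attention, checked
        against an explicit dense computation."""
        rng = np.random.default_rng(5)
        cfg = RunConfig(
            seed=5, hidden=3, f1_latent=2, f2_latent=2, f_joint=4, f_embed=2
        )
        model = GclModel(3, 3, cfg)
        g = _graph_from_edges(2, [(0, 1)])
        emb = model.encode(
            Tensor(rng.normal(size=(2, 3))), Tensor(rng.normal(size=(2, 3))), g
        )
        h0 = model.joint_layer.decode(emb.H, emb.alpha_joint, g)

        def elu(x):
            return np.where(x > 0, x, np.expm1(x))

        A = np.zeros((2, 2))
        for k in range(g.n_edges):
            A[g.edge_dst[k], g.edge_src[k]] = emb.alpha_joint.data[k, 0]
        expected = elu(A @ (emb.H.data @ model.joint_layer.W.data))
        np.testing.assert_allclose(h0.data, expected, atol=1e-8)

    def test_expression_only_mode(self):
        cfg = RunConfig(seed=0, hidden=8, f1_latent=4, f2_latent=4, f_joint=8,
                        f_embed=3)
        model = GclModel(6, None, cfg)
        g = _random_graph(4, 6)
        emb = model.encode(Tensor(np.random.default_rng(0).normal(size=(4, 6))),
                           None, g)
        assert emb.H.shape == (4, 3)
        xhat, ihat = model.decode(emb, g)
        assert xhat.shape == (4, 6) and ihat is None

    def test_dimension_mismatch_rejected(self):
        model, _ = self._model()
        g = _random_graph(3, 7)
        with pytest.raises(ValueError, match="columns"):
            model.encode(Tensor(np.zeros((3, 99))), Tensor(np.zeros((3, 4))), g)


class TestCorrupt:
    def test_identity_permutation(self):
        X = np.arange(12.0).reshape(4, 3)
        Xt, It, perm = corrupt(X, None, permutation=np.arange(4))
        np.testing.assert_array_equal(Xt, X)

    def test_row_multiset_preserved_and_shared_permutation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 3))
        I = rng.normal(size=(7, 2))
        Xt, It, perm = corrupt(X, I, rng=42)
        assert sorted(map(tuple, Xt)) == sorted(map(tuple, X))
        np.testing.assert_array_equal(Xt, X[perm])
        np.testing.assert_array_equal(It, I[perm])

    def test_recorded_permutation_reproduces(self):
        X = np.random.default_rng(1).normal(size=(4, 2))
        Xt, _, perm = corrupt(X, None, rng=7)
        Xt2, _, _ = corrupt(X, None, permutation=perm)
        np.testing.assert_array_equal(Xt, Xt2)

    def test_small_n_warns_identity(self):
        with pytest.warns(UserWarning):
            Xt, _, perm = corrupt(np.ones((1, 2)), None, rng=0)
        assert perm.tolist() == [0]


class TestContrastiveParts:
    def test_readout_closed_forms(self):
        np.testing.assert_allclose(readout(np.zeros((5, 4))).data, 0.5)
        h = np.random.default_rng(0).normal(size=(1, 6))
        np.testing.assert_allclose(readout(h).data, 1 / (1 + np.exp(-h[0])))
        np.testing.assert_allclose(
            readout(np.full((1, 3), np.log(3.0))).data, 0.75
        )

    def test_discriminate_closed_forms(self):
        B = Tensor(np.eye(3))
        s = np.array([1.0, 0.0, 0.0])
        assert discriminate(np.zeros((1, 3)), s, B).data[0, 0] == pytest.approx(0.5)
        e1 = np.array([[1.0, 0.0, 0.0]])
        assert discriminate(e1, s, B).data[0, 0] == pytest.approx(
            1 / (1 + np.exp(-1.0))
        )

    def test_discriminate_bilinear_transpose_identity(self):
        rng = np.random.default_rng(1)
        B = rng.normal(size=(4, 4))
        h = rng.normal(size=(4,))
        s = rng.normal(size=(4,))
        d1 = discriminate(h[None, :], s, Tensor(B)).data[0, 0]
        d2 = discriminate(s[None, :], h, Tensor(B.T)).data[0, 0]
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_contrastive_loss_at_half_is_log_two(self):
        rng = np.random.default_rng(2)
        H = Tensor(rng.normal(size=(6, 3)))
        Hn = Tensor(rng.normal(size=(6, 3)))
        s = Tensor(rng.normal(size=(3,)))
        B = Parameter(np.zeros((3, 3)))  # D == 0.5 everywhere
        loss, dp, dn = contrastive_loss(H, Hn, s, B)
        assert loss.item() == pytest.approx(np.log(2.0), abs=1e-12)
        assert dp == pytest.approx(0.5) and dn == pytest.approx(0.5)

    def test_contrastive_loss_near_zero_for_perfect_discrimination(self):
        ones = np.ones((4, 2))
        B = Tensor(np.eye(2) * 1e4)
        loss, _, _ = contrastive_loss(
            Tensor(ones), Tensor(-ones), Tensor(np.ones(2)), B
        )
        assert 0.0 <= loss.item() < 1e-6

    def test_contrastive_loss_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        H = rng.normal(size=(9, 4))
        Hn = rng.normal(size=(9, 4))
        s = rng.normal(size=(4,))
        B = rng.normal(size=(4, 4))
        loss, _, _ = contrastive_loss(Tensor(H), Tensor(Hn), Tensor(s), Tensor(B))
        acc = 0.0
        for i in range(9):
            dp = 1 / (1 + np.exp(-(H[i] @ B @ s)))
            dn = 1 / (1 + np.exp(-(Hn[i] @ B @ s)))
            acc += np.log(dp) + np.log(1 - dn)
        np.testing.assert_allclose(loss.item(), -acc / 18, atol=1e-10)


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        assert reconstruction_loss(X, Tensor(X.copy()), None, None).item() == 0.0

    def test_unit_offset_costs_one(self):
        X = np.zeros((4, 3))
        Xhat = X.copy()
        Xhat[2, 0] = 1.0  # one spot offset by a unit vector
        I = np.ones((4, 2))
        loss = reconstruction_loss(X, Tensor(Xhat), I, Tensor(I.copy()))
        assert loss.item() == pytest.approx(1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        X, Xh = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        I, Ih = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        loss = reconstruction_loss(X, Tensor(Xh), I, Tensor(Ih))
        acc = sum(
            np.linalg.norm(X[i] - Xh[i]) + np.linalg.norm(I[i] - Ih[i])
            for i in range(6)
        )
        np.testing.assert_allclose(loss.item(), acc, atol=1e-10)


@pytest.fixture(scope="module")
def tiny_problem():
    rng = np.random.default_rng(0)
    n = 40
    coords = np.column_stack([np.arange(n) % 8, np.arange(n) // 8]) * 1.0
    g = build_graph(coords, radius=1.2, spacing=1.0)
    X = rng.normal(size=(n, 12))
    I = rng.normal(size=(n, 6))
    return X, I, g


class TestTraining:
    def test_beta_zero_total_equals_gate(self, tiny_problem):
        X, I, g = tiny_problem
        cfg = RunConfig(seed=0, beta=0.0, hidden=8, f1_latent=4, f2_latent=4,
                        f_joint=8, f_embed=3)
        _, _, rep = train(X, I, g, cfg, epochs=5)
        np.testing.assert_array_equal(rep.l_total, rep.l_gate)

    def test_beta_zero_contrastive_has_no_gradient_effect(self, tiny_problem):
        """Keeping the (zero-weighted) contrastive term in the graph leaves
        the parameter trajectory bit-identical to skipping it."""
        X, I, g = tiny_problem
        cfg = RunConfig(seed=3, beta=0.0, hidden=8, f1_latent=4, f2_latent=4,
                        f_joint=8, f_embed=3)
        m1, H1, _ = train(X, I, g, cfg, epochs=6)
        m2, H2, _ = train(X, I, g, cfg, epochs=6, force_contrastive_graph=True)
        for k, v in m1.state_dict().items():
            np.testing.assert_array_equal(v, m2.state_dict()[k], err_msg=k)
        np.testing.assert_array_equal(H1, H2)

    def test_loss_identities_every_epoch(self, tiny_problem):
        X, I, g = tiny_problem
        cfg = RunConfig(seed=1, hidden=8, f1_latent=4, f2_latent=4, f_joint=8,
                        f_embed=3)
        _, _, rep = train(X, I, g, cfg, epochs=8)
        for t in range(8):
            assert rep.l_gate[t] == pytest.approx(
                rep.l_gate_p[t] + rep.l_gate_n[t], abs=1e-10
            )
            assert rep.l_total[t] == pytest.approx(
                rep.l_gate[t] + cfg.beta * rep.l_cl[t], abs=1e-10
            )

    def test_training_reduces_loss(self, tiny_problem):
        X, I, g = tiny_problem
        cfg = RunConfig(seed=2, hidden=8, f1_latent=4, f2_latent=4, f_joint=8,
                        f_embed=3, lr=1e-3)
        _, _, rep = train(X, I, g, cfg, epochs=40)
        assert rep.l_total[-1] < rep.l_total[0]

    def test_seed_determinism(self, tiny_problem):
        X, I, g = tiny_problem
        cfg = RunConfig(seed=9, hidden=8, f1_latent=4, f2_latent=4, f_joint=8,
                        f_embed=3)
        _, H1, _ = train(X, I, g, cfg, epochs=5)
        _, H2, _ = train(X, I, g, cfg, epochs=5)
        np.testing.assert_allclose(H1, H2, atol=1e-6)

    def test_fixed_corruption_mode(self, tiny_problem):
        X, I, g = tiny_problem
        cfg = RunConfig(seed=4, hidden=8, f1_latent=4, f2_latent=4, f_joint=8,
                        f_embed=3)
        _, _, rep = train(X, I, g, cfg, epochs=3, redraw_corruption=False)
        assert len(rep.l_total) == 3

    def test_checkpoint_round_trip(self, tiny_problem):
        X, I, g = tiny_problem
        cfg = RunConfig(seed=5, hidden=8, f1_latent=4, f2_latent=4, f_joint=8,
                        f_embed=3)
        m1, _, _ = train(X, I, g, cfg, epochs=2)
        m2 = GclModel(X.shape[1], I.shape[1], cfg, dtype=np.float32)
        m2.load_state_dict(m1.state_dict())
        for k, v in m1.state_dict().items():
            np.testing.assert_array_equal(v, m2.state_dict()[k])
        bad = {k: v for k, v in m1.state_dict().items() if k != "discriminator.B"}
        with pytest.raises(ValueError, match="discriminator.B"):
            m2.load_state_dict(bad)
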