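"""Model-layer oracles: attention kernel, message passing, readout, fusion,
and end-to-end forward determinism."""

import dataclasses
import math

import numpy as np
import pytest

from molhgt.autodiff import Tensor
from molhgt.chemgraph import build_hetero_graph
from molhgt.model import (
    MessageState,
    ModelConfig,
    VARIANT_VIEWS,
    compile_graph,
    embed_initial,
    forward,
    fuse_views,
    init_params,
    load_checkpoint,
    message_passing_step,
    multi_view_attention,
    predict,
    readout_attention,
    save_checkpoint,
    view_readout,
    ViewEmbedding,
)
from molhgt.nn import iter_params

from .oracles import dense_attention, gru_recurrence, unrolled_forward

TINY = ModelConfig(hidden_dim=4, num_heads=2, depth=2, dropout=0.0, seed=3)


def _params_like(config, n_tasks=1, scale=None, seed=None):
    params = init_params(
        config if seed is None else dataclasses.replace(config, seed=seed), n_tasks
    )
    if scale:
        for _, p in iter_params(params):
            p.data *= scale
    return params


class TestMultiViewAttention:
    def test_singleton_identity_omega_returns_value(self):
        V = np.array([[1.5, -2.0]])
        out = multi_view_attention(
            {"a": np.array([[1.0, 0.0]])},
            {"a": np.array([[3.0, 1.0]])},
            {"a": V},
            {"a": np.eye(2)},
            d_k=2,
        )
        np.testing.assert_allclose(out.data, V)

    def test_zero_scores_uniform_weights(self):
        V = np.array([[2.0, 0.0], [0.0, 4.0]])
        Om = np.array([[1.0, 1.0], [0.0, 1.0]])
        out = multi_view_attention(
            {"a": np.zeros((1, 2))},
            {"a": np.zeros((2, 2))},
            {"a": V},
            {"a": Om},
            d_k=2,
        )
        np.testing.assert_allclose(out.data, V.mean(axis=0, keepdims=True) @ Om)

    def test_empty_type_contributes_zero(self):
        out = multi_view_attention(
            {"a": np.ones((2, 3)), "b": np.ones((2, 3))},
            {"a": np.ones((0, 3)), "b": np.ones((1, 3))},
            {"a": np.ones((0, 3)), "b": np.full((1, 3), 2.0)},
            {"a": np.eye(3), "b": np.eye(3)},
            d_k=3,
        )
        np.testing.assert_allclose(out.data, np.full((2, 3), 2.0))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="key"):
            multi_view_attention(
                {"a": np.ones((1, 2))}, {"a": np.ones((1, 3))},
                {"a": np.ones((1, 2))}, {"a": np.eye(2)}, d_k=2,
            )

    @pytest.mark.parametrize("sigma", ["softmax", "sigmoid"])
    def test_matches_dense_oracle(self, sigma, rng):
        """Random <=4x4 instances vs explicit-exponential reference."""
        for _ in range(50):
            nq, dk = rng.integers(1, 5), int(rng.integers(1, 5))
            types = ["p", "q"][: rng.integers(1, 3)]
            Q = {t: rng.integers(-3, 4, (nq, dk)).astype(float) for t in types}
            K = {t: rng.integers(-3, 4, (rng.integers(1, 5), dk)).astype(float) for t in types}
            V = {t: rng.standard_normal((K[t].shape[0], dk)) for t in types}
            Om = {t: rng.standard_normal((dk, dk)) for t in types}
            out = multi_view_attention(Q, K, V, Om, d_k=dk, sigma=sigma)
            np.testing.assert_allclose(
                out.data, dense_attention(Q, K, V, Om, dk, sigma=sigma), atol=1e-6
            )


class TestEmbedInitial:
    def test_single_node_edgeless_view(self):
        g = build_hetero_graph("C")
        params = _params_like(TINY)
        state = embed_initial(g.atom_view, params["views"]["alpha"], TINY)
        assert state.H_V.shape == (1, TINY.hidden_dim)
        assert state.H_E.shape == (0, TINY.hidden_dim)
        assert np.all(np.isfinite(state.H_V.data))

    def test_shape_contract_all_views(self):
        g = build_hetero_graph("CC(=O)NCc1ccccc1")
        params = _params_like(TINY)
        cg = compile_graph(g)
        for tag in ("alpha", "beta", "gamma"):
            state = embed_initial(cg.views[tag], params["views"][tag], TINY)
            view = g.view(tag)
            assert state.H_V.shape == (view.n_nodes, TINY.hidden_dim)
            assert state.H_E.shape == (view.n_edges, TINY.hidden_dim)


class TestMessagePassing:
    def test_edgeless_view_keeps_hidden(self):
        g = build_hetero_graph("C")
        params = _params_like(TINY)
        state = embed_initial(g.atom_view, params["views"]["alpha"], TINY)
        h0 = state.H_V.data.copy()
        for _ in range(TINY.depth):
            state = message_passing_step(state, g.atom_view, params["views"]["alpha"], TINY)
        np.testing.assert_array_equal(state.H_V.data, h0)
        np.testing.assert_array_equal(state.M_V.data, 0.0)

    def test_zero_parameters_give_residual_identity(self):
        """All-zero step parameters produce zero messages at t>1: H^t = H^{t-1}."""
        g = build_hetero_graph("CCO")
        params = _params_like(TINY)
        for key in ("W_Q", "W_K", "W_V", "W_lin", "b_lin"):
            params["views"]["alpha"]["step"][key].data *= 0.0
        for h in range(TINY.num_heads):
            params["views"]["alpha"]["step"]["Omega"][f"h{h}"].data *= 0.0
        state = embed_initial(g.atom_view, params["views"]["alpha"], TINY)
        state = message_passing_step(state, g.atom_view, params["views"]["alpha"], TINY)
        h_v, h_e = state.H_V.data.copy(), state.H_E.data.copy()
        state = message_passing_step(state, g.atom_view, params["views"]["alpha"], TINY)
        np.testing.assert_array_equal(state.H_V.data, h_v)
        np.testing.assert_array_equal(state.H_E.data, h_e)

    def test_step_past_depth_raises(self):
        g = build_hetero_graph("CC")
        params = _params_like(TINY)
        state = embed_initial(g.atom_view, params["views"]["alpha"], TINY)
        for _ in range(TINY.depth):
            state = message_passing_step(state, g.atom_view, params["views"]["alpha"], TINY)
        with pytest.raises(RuntimeError):
            message_passing_step(state, g.atom_view, params["views"]["alpha"], TINY)


class TestReadout:
    def test_single_node_equals_one_gru_step(self):
        cfg = ModelConfig(hidden_dim=4, num_heads=1, depth=1, dropout=0.0, seed=0)
        params = _params_like(cfg)
        g = build_hetero_graph("C")
        state = embed_initial(g.atom_view, params["views"]["alpha"], cfg)
        z = view_readout(state, g.atom_view, params["views"]["alpha"]["gru"])
        expected = gru_recurrence(
            {k: v.data for k, v in params["views"]["alpha"]["gru"].items()},
            state.H_V.data,
        )
        np.testing.assert_allclose(z.data.ravel(), expected, atol=1e-12)

    def test_three_node_recurrence_oracle(self, rng):
        cfg = ModelConfig(hidden_dim=3, num_heads=1, depth=1, dropout=0.0, seed=1)
        params = _params_like(cfg)
        gru = params["views"]["beta"]["gru"]
        inputs = rng.standard_normal((3, 3))
        z = view_readout(
            MessageState(H_V=Tensor(inputs), H_E=Tensor(np.zeros((0, 3))),
                         M_V=None, M_E=None, M_E_1=None, t=1),
            build_hetero_graph("CCO").pharm_view.__class__(
                view_tag="beta", node_types=["pharm"] * 3,
                node_features=np.zeros((3, 1)), directed_edges=[], edge_types=[],
                edge_features=np.zeros((0, 1)), reverse_index=np.zeros(0, dtype=int),
            ),
            gru,
        )
        expected = gru_recurrence({k: v.data for k, v in gru.items()}, inputs)
        np.testing.assert_allclose(z.data.ravel(), expected, atol=1e-12)


class TestReadoutAttentionAndFusion:
    def test_orthogonal_halves_gate(self):
        X = Tensor(np.array([[1.0, 2.0]]))
        Y = Tensor(np.array([[2.0, -1.0]]))
        np.testing.assert_allclose(readout_attention(X, Y, 4).data, 0.5 * X.data)

    def test_zero_x_gives_zero(self):
        X = Tensor(np.zeros((1, 3)))
        Y = Tensor(np.ones((1, 3)))
        np.testing.assert_array_equal(readout_attention(X, Y, 9).data, 0.0)

    def test_scalar_example(self):
        out = readout_attention(
            Tensor(np.array([[1.0, 1.0]])), Tensor(np.array([[2.0, 0.0]])), 4
        )
        gate = 1.0 / (1.0 + math.exp(-1.0))  # sigmoid((1*2+1*0)/sqrt(4))
        np.testing.assert_allclose(out.data, gate * np.array([[1.0, 1.0]]))

    def test_width_mismatch(self):
        with pytest.raises(ValueError):
            readout_attention(Tensor(np.ones((1, 2))), Tensor(np.ones((1, 3))), 2)

    def test_alpha_variant_identity(self):
        cfg = dataclasses.replace(TINY, views_enabled=("alpha",), fusion_variant="alpha")
        z = Tensor(np.array([[1.0, 2.0, 3.0, 4.0]]))
        emb = ViewEmbedding(Z_alpha=z)
        assert fuse_views(emb, cfg) is z

    def test_chained_zero_gates(self):
        """Orthogonal view vectors: both sigmoid gates are 1/2."""
        cfg = TINY
        emb = ViewEmbedding(
            Z_alpha=Tensor(np.array([[2.0, 0.0, 0.0, 0.0]])),
            Z_beta=Tensor(np.array([[0.0, 1.0, 0.0, 0.0]])),
            Z_gamma=Tensor(np.array([[0.0, 0.0, 1.0, 0.0]])),
        )
        z = fuse_views(emb, cfg)
        np.testing.assert_allclose(emb.Z_gamma_beta.data, [[0.0, 0.0, 0.5, 0.0]])
        np.testing.assert_allclose(z.data, [[1.0, 0.0, 0.0, 0.0]])

    def test_missing_view_raises(self):
        with pytest.raises(ValueError):
            fuse_views(ViewEmbedding(Z_alpha=Tensor(np.ones((1, 4)))), TINY)

    @pytest.mark.parametrize("n_tasks", [1, 12, 27])
    def test_predict_task_counts(self, n_tasks):
        params = _params_like(TINY, n_tasks=n_tasks)
        out = predict(Tensor(np.ones((1, TINY.hidden_dim))), params["head"])
        assert out.shape == (1, n_tasks)


class TestForward:
    def test_unrolled_oracle_two_fragment_molecule(self):
        """d=2, single head, T=2: forward equals the scalar unrolling of the
        embedding, both propagation steps (incl. reverse-edge subtraction and
        residuals), GRU readout and the gated fusion chain."""
        cfg = ModelConfig(hidden_dim=2, num_heads=1, depth=2, dropout=0.0, seed=7)
        g = build_hetero_graph("CC(=O)NC")  # one cleaved amide: two fragments
        assert g.assignment.n_fragments == 2
        params = _params_like(cfg, n_tasks=1, seed=7)
        scores, emb = forward(g, params, cfg)
        ref_scores, ref_Z = unrolled_forward(g, params, cfg)
        np.testing.assert_allclose(scores.data.ravel(), ref_scores, atol=1e-6)
        np.testing.assert_allclose(emb.Z.data.ravel(), ref_Z, atol=1e-6)

    @pytest.mark.parametrize("variant", sorted(VARIANT_VIEWS))
    def test_unrolled_oracle_all_variants(self, variant):
        cfg = ModelConfig(
            hidden_dim=2, num_heads=1, depth=2, dropout=0.0, seed=11,
            views_enabled=tuple(sorted(VARIANT_VIEWS[variant])), fusion_variant=variant,
        )
        g = build_hetero_graph("CCOC(=O)c1ccccc1")
        params = _params_like(cfg, n_tasks=2, seed=11)
        scores, emb = forward(g, params, cfg)
        ref_scores, ref_Z = unrolled_forward(g, params, cfg)
        np.testing.assert_allclose(scores.data.ravel(), ref_scores, atol=1e-6)

    def test_spelling_invariance(self):
        params = _params_like(TINY)
        sa, _ = forward(build_hetero_graph("CCO"), params, TINY)
        sb, _ = forward(build_hetero_graph("OCC"), params, TINY)
        np.testing.assert_array_equal(sa.data, sb.data)

    def test_view_isolation_alpha(self):
        cfg = dataclasses.replace(TINY, views_enabled=("alpha",), fusion_variant="alpha")
        params = _params_like(cfg)
        g = compile_graph(build_hetero_graph("CC(=O)NC"))
        base, _ = forward(g, params, cfg)
        g.views["beta"].X_v.data += 100.0
        g.views["gamma"].X_v.data -= 50.0
        perturbed, _ = forward(g, params, cfg)
        np.testing.assert_array_equal(base.data, perturbed.data)

    def test_seeded_determinism(self):
        a = _params_like(TINY, seed=9)
        b = _params_like(TINY, seed=9)
        for (pa, ta), (pb, tb) in zip(iter_params(a), iter_params(b)):
            assert pa == pb
            np.testing.assert_array_equal(ta.data, tb.data)
        g = build_hetero_graph("CC(=O)NC")
        np.testing.assert_array_equal(
            forward(g, a, TINY)[0].data, forward(g, b, TINY)[0].data
        )

    def test_finite_on_fixture_set(self, fixture_smiles):
        params = _params_like(TINY)
        for smi in fixture_smiles[:10]:
            scores, emb = forward(build_hetero_graph(smi), params, TINY)
            assert np.all(np.isfinite(scores.data))
            assert np.all(np.isfinite(emb.Z.data))


class TestConfigAndCheckpoint:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=5, num_heads=2)
        with pytest.raises(ValueError):
            ModelConfig(depth=0)
        with pytest.raises(ValueError, match="fusion_variant"):
            ModelConfig(fusion_variant="bogus")
        with pytest.raises(ValueError):
            ModelConfig(views_enabled=("alpha",), fusion_variant="full")

    def test_checkpoint_round_trip(self, tmp_path):
        params = _params_like(TINY, n_tasks=3)
        path = tmp_path / "ck.npz"
        save_checkpoint(path, params, TINY, n_tasks=3, meta={"note": "x"})
        loaded, cfg, n_tasks, meta = load_checkpoint(path)
        assert cfg == TINY and n_tasks == 3 and meta == {"note": "x"}
        for (ka, ta), (kb, tb) in zip(iter_params(params), iter_params(loaded)):
            assert ka == kb
            np.testing.assert_array_equal(ta.data, tb.data)
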