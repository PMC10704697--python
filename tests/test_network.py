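"""Numpy network internals: propagation, readout, gradients, determinism."""

import numpy as np
import pytest

from solubgcn.network import (
    NetConfig,
    backward,
    forward,
    init_params,
    pack_batch,
    rmse_loss_grad,
    train_network,
)


def sym_norm(contact):
    L = contact.shape[0]
    A = contact.copy()
    np.fill_diagonal(A, 0.0)
    A = A + np.eye(L)
    d = A.sum(1) ** -0.5
    return A * d[:, None] * d[None, :]


def make_config(C, **overrides):
    params = dict(
        n_channels=C,
        gcn_layers=2,
        gcn_hidden=6,
        attention_hidden=4,
        attention_heads=1,
        dropout=0.0,
        use_afr=True,
        afr_bias=True,
        seed=0,
    )
    params.update(overrides)
    return NetConfig(**params)


def single_batch(rng, L=5, C=4, y=0.4):
    X = rng.standard_normal((L, C))
    m = rng.random((L, L))
    A = sym_norm((m + m.T) / 2)
    return pack_batch([X], [A], np.array([y]))


class TestGCNLayerSemantics:
    def test_identity_adjacency_and_weights_pass_positive_input(self, rng):
        """A = I, W = I, positive pre-activations: the layer is a no-op."""
        C = 4
        cfg = make_config(C, gcn_layers=1, gcn_hidden=C, use_afr=False)
        params = init_params(cfg, np.random.default_rng(0))
        params["gcn_W0"] = np.eye(C)
        params["gcn_b0"] = np.zeros(C)
        X = np.abs(rng.standard_normal((5, C))) + 0.1
        batch = pack_batch([X], [np.eye(5)])
        cache = forward(params, batch, cfg)
        np.testing.assert_allclose(cache["Xs"][0], X, atol=1e-12)

    def test_identical_connected_nodes_stay_identical(self, rng):
        """Symmetry preservation: automorphic nodes get identical outputs."""
        cfg = make_config(3, use_afr=False)
        params = init_params(cfg, np.random.default_rng(1))
        row = rng.standard_normal(3)
        X = np.vstack([row, row])
        A = sym_norm(np.array([[0.0, 1.0], [1.0, 0.0]]))
        cache = forward(params, pack_batch([X], [A]), cfg)
        for layer_out in cache["Xs"]:
            np.testing.assert_allclose(layer_out[0], layer_out[1], atol=1e-12)

    def test_propagation_matches_triple_loop(self, rng):
        """One layer's pre-activation equals the explicit sum over nodes/dims."""
        C, h, L = 3, 4, 4
        cfg = make_config(C, gcn_layers=1, gcn_hidden=h, use_afr=False)
        params = init_params(cfg, np.random.default_rng(2))
        X = rng.standard_normal((L, C))
        m = rng.random((L, L))
        A = sym_norm((m + m.T) / 2)
        cache = forward(params, pack_batch([X], [A]), cfg)
        W, b = params["gcn_W0"], params["gcn_b0"]
        U_ref = np.zeros((L, h))
        for i in range(L):
            for o in range(h):
                acc = b[o]
                for j in range(L):
                    for c in range(C):
                        acc += A[i, j] * X[j, c] * W[c, o]
                U_ref[i, o] = acc
        np.testing.assert_allclose(cache["Us"][0], U_ref, atol=1e-10)


class TestAttentionReadout:
    def test_single_residue_gets_full_attention(self, rng):
        cfg = make_config(3, use_afr=False)
        params = init_params(cfg, np.random.default_rng(3))
        batch = pack_batch([rng.standard_normal((1, 3))], [np.eye(1)])
        cache = forward(params, batch, cfg)
        np.testing.assert_allclose(cache["alpha"], [[1.0]])

    def test_identical_node_states_give_uniform_attention(self, rng):
        cfg = make_config(3, use_afr=False)
        params = init_params(cfg, np.random.default_rng(4))
        row = rng.standard_normal(3)
        X = np.tile(row, (6, 1))
        cache = forward(params, pack_batch([X], [np.eye(6)]), cfg)
        np.testing.assert_allclose(cache["alpha"][:, 0], np.full(6, 1 / 6), atol=1e-12)

    def test_attention_sums_to_one_and_pooled_is_weighted_sum(self, rng):
        cfg = make_config(4)
        params = init_params(cfg, np.random.default_rng(5))
        batch = pack_batch(
            [rng.standard_normal((5, 4)), rng.standard_normal((3, 4))],
            [sym_norm(np.eye(5)), sym_norm(np.eye(3))],
        )
        cache = forward(params, batch, cfg)
        alpha = cache["alpha"][:, 0]
        assert alpha.min() >= 0
        np.testing.assert_allclose(
            [alpha[:5].sum(), alpha[5:].sum()], [1.0, 1.0], atol=1e-6
        )
        X_last = cache["Xs"][-1]
        pooled_ref = np.vstack(
            [(alpha[:5, None] * X_last[:5]).sum(0), (alpha[5:, None] * X_last[5:]).sum(0)]
        )
        np.testing.assert_allclose(cache["g"], pooled_ref, atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("use_afr,heads", [(True, 1), (False, 1), (True, 2)])
    def test_backward_matches_finite_differences(self, rng, use_afr, heads):
        """Analytic gradients agree with central differences to 1e-4 relative."""
        cfg = make_config(4, use_afr=use_afr, attention_heads=heads)
        params = init_params(cfg, np.random.default_rng(6))
        batch = pack_batch(
            [rng.standard_normal((4, 4)), rng.standard_normal((6, 4))],
            [sym_norm(np.eye(4) + 0.3), sym_norm(np.eye(6) + 0.2)],
            np.array([0.3, 0.8]),
        )

        def loss_of(p):
            return rmse_loss_grad(forward(p, batch, cfg)["s_hat"], batch.y)[0]

        cache = forward(params, batch, cfg)
        _, ds = rmse_loss_grad(cache["s_hat"], batch.y)
        grads = backward(params, batch, cfg, cache, ds)
        eps = 1e-6
        for key in params:
            numeric = np.zeros_like(params[key])
            it = np.nditer(params[key], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = params[key][idx]
                params[key][idx] = orig + eps
                lp = loss_of(params)
                params[key][idx] = orig - eps
                lm = loss_of(params)
                params[key][idx] = orig
                numeric[idx] = (lp - lm) / (2 * eps)
            scale = max(np.abs(numeric).max(), 1e-6)
            assert np.abs(grads[key] - numeric).max() / scale < 1e-4, key


class TestTraining:
    def _items(self, rng, n=12, C=4):
        items = []
        for _ in range(n):
            L = int(rng.integers(4, 8))
            X = rng.standard_normal((L, C))
            m = rng.random((L, L))
            A = sym_norm((m + m.T) / 2)
            y = 1 / (1 + np.exp(-X[:, 0].mean() * 3))
            items.append((X, A, float(y)))
        return items

    def test_deterministic_given_seed(self, rng):
        items = self._items(rng)
        cfg = make_config(4, gcn_hidden=5, attention_hidden=3)
        cfg.max_epochs = 5
        p1, h1 = train_network(items, cfg)
        p2, h2 = train_network(items, cfg)
        for key in p1:
            np.testing.assert_array_equal(p1[key], p2[key])
        assert h1[-1] == h2[-1]

    def test_training_reduces_rmse(self, rng):
        items = self._items(rng, n=20)
        cfg = make_config(4, gcn_hidden=8, attention_hidden=4)
        cfg.max_epochs = 40
        params, history = train_network(items, cfg)
        epochs = [h for h in history if "train_rmse" in h]
        assert history[-1]["final_train_rmse"] < epochs[0]["train_rmse"]

    def test_predictions_strictly_inside_unit_interval(self, rng):
        items = self._items(rng)
        cfg = make_config(4, gcn_hidden=5, attention_hidden=3)
        cfg.max_epochs = 3
        params, _ = train_network(items, cfg)
        batch = pack_batch([f for f, _, _ in items], [a for _, a, _ in items])
        s = forward(params, batch, cfg)["s_hat"]
        assert ((s > 0) & (s < 1)).all()

    def test_early_stopping_restores_best(self, rng):
        items = self._items(rng, n=16)
        cfg = make_config(4, gcn_hidden=5, attention_hidden=3)
        cfg.max_epochs = 60
        cfg.patience = 5
        params, history = train_network(items[:12], cfg, items[12:])
        restored = [h for h in history if h.get("restored_best")]
        assert restored, "validation-monitored run must restore best parameters"
        epochs = [h for h in history if "val_rmse" in h and "epoch" in h and "restored_best" not in h]
        assert restored[0]["val_rmse"] == pytest.approx(min(h["val_rmse"] for h in epochs))
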