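"""Attention algebra, forward-pass invariances, gradients, and training
bookkeeping.

The self-attention layer is checked against an explicit-loop oracle (no
matrix shortcuts) and the analytic gradients against central finite
differences.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wsimil.model import (ModelParams, TrainConfig, _backward, _forward_cache,
                          attention_forward, bag_loss, load_checkpoint,
                          model_forward, save_checkpoint, tile_weights, train)
from wsimil.synthetic import generate_feature_bags


def attention_oracle(h, params):
    """Explicit loops over tiles; independent of the vectorized path."""
    n, _ = h.shape
    F = np.array([params.Wf @ h[i] for i in range(n)])
    G = np.array([params.Wg @ h[j] for j in range(n)])
    scores = np.empty((n, n))
    for j in range(n):
        for i in range(n):
            scores[j, i] = float(F[i] @ G[j])
    alpha = np.empty_like(scores)
    for j in range(n):
        e = np.exp(scores[j] - scores[j].max())
        alpha[j] = e / e.sum()
    o = np.zeros_like(h)
    for j in range(n):
        for i in range(n):
            o[j] += alpha[j, i] * h[i]
    y = h + params.gamma * o
    return alpha, o, y.mean(axis=0)


def _params(dim=16, seed=0, d_attn=4):
    return ModelParams.initialize(dim, d_attn=d_attn, seed=seed)


class TestAttentionForward:
    def test_single_tile(self):
        p = _params()
        h = np.random.default_rng(0).standard_normal((1, 128))
        st_ = attention_forward(h, p)
        np.testing.assert_allclose(st_.alpha, [[1.0]])
        np.testing.assert_allclose(st_.o, h)
        np.testing.assert_allclose(st_.y_global, (1 + p.gamma) * h[0])

    def test_gamma_zero_is_mean_pooling(self):
        p = _params()
        p.gamma = 0.0
        h = np.random.default_rng(1).standard_normal((6, 128))
        st_ = attention_forward(h, p)
        np.testing.assert_allclose(st_.y_global, h.mean(axis=0))

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_matches_explicit_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        p = _params(seed=n)
        h = rng.standard_normal((n, 128))
        st_ = attention_forward(h, p)
        alpha, o, y_global = attention_oracle(h, p)
        np.testing.assert_allclose(st_.alpha, alpha, atol=1e-6)
        np.testing.assert_allclose(st_.o, o, atol=1e-6)
        np.testing.assert_allclose(st_.y_global, y_global, atol=1e-6)

    def test_rows_stochastic(self, rng):
        p = _params()
        h = rng.standard_normal((7, 128))
        st_ = attention_forward(h, p)
        np.testing.assert_allclose(st_.alpha.sum(axis=1), 1.0, atol=1e-6)
        assert (st_.alpha > 0).all() and (st_.alpha < 1).all()

    def test_nonfinite_rejected(self):
        p = _params()
        h = np.full((3, 128), np.nan)
        with pytest.raises(ValueError, match="finite"):
            attention_forward(h, p)


class TestModelForward:
    def test_probabilities_sum_to_one(self, rng):
        p = _params(dim=8)
        for _ in range(100):
            x = rng.standard_normal((int(rng.integers(1, 12)), 8))
            probs, _ = model_forward(x, p)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert (probs >= 0).all()

    def test_permutation_invariance(self, rng):
        p = _params(dim=8)
        x = rng.standard_normal((9, 8))
        probs, state = model_forward(x, p)
        perm = rng.permutation(9)
        probs_p, state_p = model_forward(x[perm], p)
        np.testing.assert_allclose(probs_p, probs, atol=1e-5)
        beta = tile_weights(state, p.gamma).beta
        beta_p = tile_weights(state_p, p.gamma).beta
        np.testing.assert_allclose(beta_p, beta[perm], atol=1e-5)

    def test_duplicated_bag_gamma_zero_unchanged(self, rng):
        p = _params(dim=8)
        p.gamma = 0.0
        x = rng.standard_normal((5, 8))
        probs, _ = model_forward(x, p)
        probs_dup, _ = model_forward(np.vstack([x, x]), p)
        np.testing.assert_allclose(probs_dup, probs, atol=1e-9)

    def test_gamma_zero_equals_mean_pool_mlp(self, rng):
        # the attention must have no effect on the output when gamma = 0
        p = _params(dim=8)
        p.gamma = 0.0
        x = rng.standard_normal((6, 8))
        probs, _ = model_forward(x, p)
        h1 = np.maximum(x @ p.W1.T + p.b1, 0)
        h = np.maximum(h1 @ p.W2.T + p.b2, 0)
        logits = p.Wout @ h.mean(axis=0) + p.bout
        ref = np.exp(logits - logits.max())
        ref /= ref.sum()
        np.testing.assert_allclose(probs, ref, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dim"):
            model_forward(rng.standard_normal((3, 9)), _params(dim=8))


class TestTileWeights:
    def test_gamma_zero_all_ones(self, rng):
        alpha = np.full((4, 4), 0.25)
        np.testing.assert_allclose(tile_weights(alpha, 0.0).beta, 1.0)

    def test_single_tile_gamma_one(self):
        np.testing.assert_allclose(tile_weights(np.array([[1.0]]), 1.0).beta, [2.0])

    @given(st.integers(2, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_beta_total_is_n_times_one_plus_gamma(self, n, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random((n, n)) + 1e-6
        alpha = raw / raw.sum(axis=1, keepdims=True)
        gamma = float(rng.uniform(-0.9, 3.0))
        beta = tile_weights(alpha, gamma).beta
        assert beta.sum() == pytest.approx(n * (1 + gamma), rel=1e-9)


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        rng = np.random.default_rng(42)
        p = _params(dim=8, seed=1)
        x = rng.standard_normal((5, 8))
        cache = _forward_cache(x, p)
        grads = _backward(cache, 1, p)
        eps = 1e-6
        for key in ("W1", "b1", "W2", "b2", "Wf", "Wg", "Wout", "bout"):
            arr = getattr(p, key)
            for _ in range(3):
                idx = tuple(int(rng.integers(0, s)) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                up = bag_loss(x, 1, p)
                arr[idx] = orig - eps
                down = bag_loss(x, 1, p)
                arr[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grads[key][idx] == pytest.approx(fd, abs=1e-6), key
        orig = p.gamma
        p.gamma = orig + eps
        up = bag_loss(x, 1, p)
        p.gamma = orig - eps
        down = bag_loss(x, 1, p)
        p.gamma = orig
        assert grads["gamma"] == pytest.approx((up - down) / (2 * eps), abs=1e-6)


class TestTraining:
    def test_history_bookkeeping(self):
        bs = generate_feature_bags(20, dim=8, effect_size=1.0, seed=1)
        cfg = TrainConfig(epochs=3, seed=0)
        _, history = train(bs.bags[:14], bs.bag_labels[:14], cfg,
                           bs.bags[14:], bs.bag_labels[14:])
        assert len(history) == 3
        assert [h["epoch"] for h in history] == [0, 1, 2]
        assert all(np.isfinite(h["train_loss"]) for h in history)

    def test_best_params_achieve_max_history_auc(self):
        bs = generate_feature_bags(24, dim=8, effect_size=2.0, seed=2)
        cfg = TrainConfig(epochs=4, seed=0)
        params, history = train(bs.bags[:16], bs.bag_labels[:16], cfg,
                                bs.bags[16:], bs.bag_labels[16:])
        from wsimil.model import predict_proba
        from sklearn.metrics import roc_auc_score
        auc = roc_auc_score(bs.bag_labels[16:],
                            predict_proba(bs.bags[16:], params))
        assert auc == pytest.approx(max(h["val_auc"] for h in history), abs=1e-9)

    def test_single_class_labels_rejected(self):
        bs = generate_feature_bags(10, dim=8, seed=3)
        pos = [b for b, y in zip(bs.bags, bs.bag_labels) if y == 1]
        with pytest.raises(ValueError, match="single class"):
            train(pos, [1] * len(pos), TrainConfig(epochs=1),
                  bs.bags, bs.bag_labels)

    def test_gamma_initialized_to_one(self):
        assert ModelParams.initialize(8).gamma == 1.0

    def test_determinism(self):
        bs = generate_feature_bags(16, dim=8, seed=4)
        cfg = TrainConfig(epochs=2, seed=9)
        p1, h1 = train(bs.bags[:12], bs.bag_labels[:12], cfg,
                       bs.bags[12:], bs.bag_labels[12:])
        p2, h2 = train(bs.bags[:12], bs.bag_labels[:12], cfg,
                       bs.bags[12:], bs.bag_labels[12:])
        np.testing.assert_array_equal(p1.W1, p2.W1)
        assert h1 == h2


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        p = _params(dim=8, seed=5)
        p.gamma = 1.7
        save_checkpoint(p, tmp_path / "m", {"task": "demo"})
        back = load_checkpoint(tmp_path / "m")
        assert back.gamma == pytest.approx(1.7)
        np.testing.assert_array_equal(back.W1, p.W1)
        np.testing.assert_array_equal(back.Wout, p.Wout)
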