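import math

import numpy as np
import pytest

from dusqa.layers import GRULayer
from dusqa.network import (
    AttentionParams,
    GRUParams,
    ModelConfig,
    NetworkVariant,
    attention_pool,
    build_model,
    gru_step,
    load_checkpoint,
    predict_window,
    save_checkpoint,
)


def _zero_gru_params(in_dim, hidden):
    z = lambda *s: np.zeros(s)
    return GRUParams(
        W_z=z(in_dim, hidden), W_r=z(in_dim, hidden), W_h=z(in_dim, hidden),
        U_z=z(hidden, hidden), U_r=z(hidden, hidden), U_h=z(hidden, hidden),
        b_z=z(hidden), b_r=z(hidden), b_h=z(hidden),
    )


def _random_gru_params(rng, in_dim, hidden):
    u = lambda *s: rng.uniform(-1, 1, size=s)
    return GRUParams(
        W_z=u(in_dim, hidden), W_r=u(in_dim, hidden), W_h=u(in_dim, hidden),
        U_z=u(hidden, hidden), U_r=u(hidden, hidden), U_h=u(hidden, hidden),
        b_z=u(hidden), b_r=u(hidden), b_h=u(hidden),
    )


def scalar_gru_step(x, h_prev, p):
    """Element-by-element evaluation of the gate equations in pure Python."""
    in_dim, hidden = p.W_z.shape
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h_new = []
    for j in range(hidden):
        z_pre = p.b_z[j] + sum(p.W_z[i, j] * x[i] for i in range(in_dim))
        z_pre += sum(p.U_z[k, j] * h_prev[k] for k in range(hidden))
        r_row = []
        for jj in range(hidden):
            r_pre = p.b_r[jj] + sum(p.W_r[i, jj] * x[i] for i in range(in_dim))
            r_pre += sum(p.U_r[k, jj] * h_prev[k] for k in range(hidden))
            r_row.append(sig(r_pre))
        h_pre = p.b_h[j] + sum(p.W_h[i, j] * x[i] for i in range(in_dim))
        h_pre += sum(p.U_h[k, j] * r_row[k] * h_prev[k] for k in range(hidden))
        z = sig(z_pre)
        h_new.append((1 - z) * h_prev[j] + z * math.tanh(h_pre))
    return np.array(h_new)


def scalar_attention(h_seq, p):
    T, d = h_seq.shape
    scores = []
    for t in range(T):
        ut = [
            math.tanh(p.b[j] + sum(p.W[i, j] * h_seq[t, i] for i in range(d)))
            for j in range(d)
        ]
        scores.append(sum(ut[j] * p.u[j] for j in range(d)))
    mx = max(scores)
    exps = [math.exp(s - mx) for s in scores]
    alpha = [e / sum(exps) for e in exps]
    v = [sum(alpha[t] * h_seq[t, i] for t in range(T)) for i in range(d)]
    return np.array(v), np.array(alpha)


class TestGruStep:
    def test_zero_parameters_halve_hidden_state(self):
        """With all weights zero, z = r = 1/2 and h~ = 0, so h = h_prev / 2."""
        p = _zero_gru_params(3, 4)
        h_prev = np.array([1.0, -2.0, 0.5, 4.0])
        assert np.allclose(gru_step(np.ones(3), h_prev, p), 0.5 * h_prev)

    def test_zero_state_zero_params_stays_zero(self):
        p = _zero_gru_params(3, 4)
        assert np.allclose(gru_step(np.ones(3), np.zeros(4), p), 0.0)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(100)
        for _ in range(20):
            p = _random_gru_params(rng, 3, 2)
            x, h = rng.uniform(-1, 1, 3), rng.uniform(-1, 1, 2)
            assert np.allclose(gru_step(x, h, p), scalar_gru_step(x, h, p), atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gru_step(np.zeros(5), np.zeros(4), _zero_gru_params(3, 4))


class TestAttentionPool:
    def test_singleton_sequence(self):
        rng = np.random.default_rng(0)
        p = AttentionParams(
            W=rng.uniform(-1, 1, (4, 4)), b=rng.uniform(-1, 1, 4), u=rng.uniform(-1, 1, 4)
        )
        h = rng.uniform(-1, 1, (1, 4))
        v, alpha = attention_pool(h, p)
        assert np.allclose(alpha, [1.0])
        assert np.allclose(v, h[0])

    def test_identical_states_give_uniform_weights(self):
        rng = np.random.default_rng(1)
        p = AttentionParams(
            W=rng.uniform(-1, 1, (3, 3)), b=np.zeros(3), u=rng.uniform(-1, 1, 3)
        )
        h = np.tile(rng.uniform(-1, 1, 3), (6, 1))
        v, alpha = attention_pool(h, p)
        assert np.allclose(alpha, 1 / 6)
        assert np.allclose(v, h[0])

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = AttentionParams(
                W=rng.uniform(-1, 1, (2, 2)), b=rng.uniform(-1, 1, 2), u=rng.uniform(-1, 1, 2)
            )
            h = rng.uniform(-1, 1, (3, 2))
            v, alpha = attention_pool(h, p)
            ev, ea = scalar_attention(h, p)
            assert np.allclose(v, ev, atol=1e-9)
            assert np.allclose(alpha, ea, atol=1e-9)
            assert alpha.sum() == pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        p = AttentionParams(W=np.eye(2), b=np.zeros(2), u=np.ones(2))
        with pytest.raises(ValueError):
            attention_pool(np.zeros((0, 2)), p)


class TestBuildModel:
    def test_conv_stack_shape_propagation(self):
        """(250, 40) -> 125 timesteps x 640 features under the default pools."""
        cfg = ModelConfig(seed=3)
        model = build_model(cfg)
        x = np.random.default_rng(0).random((1, 250, 40, 1))
        out = x
        for layer in model.layers:
            out = layer.forward(out, train=False)
            if type(layer).__name__ == "FlattenTime":
                assert out.shape == (1, 125, 640)
        assert out.shape == (1, 5)

    def test_default_parameter_count_matches_hand_derivation(self):
        # conv: 9*1*32+32 + 9*32*64+64 + 9*64*128+128; BN: 2*(32+64+128)
        # GRU: 3*((640+50)*50+50); dense 50*50+50; attention 50*50+50+50; head 50*5+5
        expected = (
            (9 * 1 * 32 + 32) + (9 * 32 * 64 + 64) + (9 * 64 * 128 + 128)
            + 2 * (32 + 64 + 128)
            + 3 * ((640 + 50) * 50 + 50)
            + (50 * 50 + 50)
            + (50 * 50 + 50 + 50)
            + (50 * 5 + 5)
        )
        assert build_model(ModelConfig(seed=0)).n_parameters() == expected

    @pytest.mark.parametrize("variant", list(NetworkVariant))
    def test_softmax_output_valid_probabilities(self, variant):
        cfg = ModelConfig(conv_filters=(4, 8, 16), variant=variant, seed=5)
        model = build_model(cfg)
        x = np.random.default_rng(1).random((3, 250, 40))
        p = model.predict_proba(x)
        assert p.shape == (3, 5)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_builds_reproducible(self):
        a = build_model(ModelConfig(conv_filters=(4, 8, 16), seed=7))
        b = build_model(ModelConfig(conv_filters=(4, 8, 16), seed=7))
        c = build_model(ModelConfig(conv_filters=(4, 8, 16), seed=8))
        for la, lb in zip(a.layers, b.layers):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k])
        diff = any(
            not np.array_equal(la.params[k], lc.params[k])
            for la, lc in zip(a.layers, c.layers)
            for k in la.params
        )
        assert diff

    def test_batched_gru_layer_agrees_with_single_steps(self):
        rng = np.random.default_rng(4)
        layer = GRULayer(6, 5, rng)
        x = rng.uniform(-1, 1, (2, 7, 6))
        out = layer.forward(x, train=False)
        p = GRUParams(**layer.params)
        for b in range(2):
            h = np.zeros(5)
            for t in range(7):
                h = gru_step(x[b, t], h, p)
                assert np.allclose(out[b, t], h, atol=1e-12)


class TestPredictWindow:
    def test_inference_is_deterministic(self):
        model = build_model(ModelConfig(conv_filters=(4, 8, 16), seed=2))
        sg = np.random.default_rng(0).random((250, 40))
        p1 = predict_window(sg, model)
        p2 = predict_window(sg, model)
        assert np.array_equal(p1, p2)

    def test_wrong_shape_rejected(self):
        model = build_model(ModelConfig(conv_filters=(4, 8, 16), seed=2))
        with pytest.raises(ValueError):
            predict_window(np.zeros((100, 40)), model)

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_model(ModelConfig(conv_filters=(4, 8, 16), seed=9))
        sg = np.random.default_rng(5).random((250, 40))
        before = predict_window(sg, model)
        save_checkpoint(tmp_path / "ckpt", model)
        restored = load_checkpoint(tmp_path / "ckpt")
        assert np.array_equal(predict_window(sg, restored), before)
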