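import numpy as np
import pytest

from deeppbs._tensor import Tensor
from deeppbs.losses import detection_focal_loss, weighted_nll
from deeppbs.model import (DeepPBSMonitor, ModelConfig, load_checkpoint,
                           save_checkpoint, select_turning_point)


def tiny_config(**kw):
    base = dict(n_h=3, S=10, n_v=4, n_g=2, p_d=0.1)
    base.update(kw)
    return ModelConfig(**base)


def tiny_model(seed=0, **kw):
    return DeepPBSMonitor(tiny_config(**kw), seed=seed)


def rand_inputs(cfg, B=2, seed=0):
    rng = np.random.default_rng(seed)
    return (rng.normal(size=(B, cfg.S, cfg.n_v)),
            rng.normal(size=(B, cfg.n_g)))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestLinearProjection:
    def test_zero_parameters_give_zero_outputs(self):
        m = tiny_model()
        for k in ("proj.W_x", "proj.b_x", "proj.W_g", "proj.b_g"):
            m.params[k].data[:] = 0.0
        X, G = rand_inputs(m.config)
        H_X, H_g = m.linear_projection(Tensor(X), Tensor(G))
        assert not H_X.data.any() and not H_g.data.any()

    def test_relu_clips_negative_projection(self):
        m = tiny_model(n_v=1, n_h=1, n_g=1)
        m.params["proj.W_x"].data[:] = 1.0
        m.params["proj.b_x"].data[:] = 0.0
        X = np.full((1, m.config.S, 1), -2.0)
        H_X, _ = m.linear_projection(Tensor(X), Tensor(np.zeros((1, 1))))
        assert not H_X.data.any()

    def test_global_embedding_tiled_identically_across_steps(self):
        m = tiny_model()
        X, G = rand_inputs(m.config)
        _, H_g = m.linear_projection(Tensor(X), Tensor(G))
        np.testing.assert_array_equal(
            H_g.data, np.repeat(H_g.data[:, :1, :], m.config.S, axis=1))


class TestHighway:
    def test_gate_near_zero_passes_input_through(self):
        m = tiny_model()
        m.params["highway0.b_g"].data[:] = -30.0
        m.params["highway0.W_g"].data[:] = 0.0
        H = Tensor(np.random.default_rng(0).normal(size=(1, 10, 3)))
        out = m.highway_forward(H)
        np.testing.assert_allclose(out.data, H.data, atol=1e-6)

    def test_gate_near_one_outputs_transform(self):
        m = tiny_model()
        m.params["highway0.b_g"].data[:] = 30.0
        m.params["highway0.W_g"].data[:] = 0.0
        rng = np.random.default_rng(0)
        H = Tensor(rng.normal(size=(1, 10, 3)))
        t = np.maximum(H.data @ m.params["highway0.W_t"].data
                       + m.params["highway0.b_t"].data, 0.0)
        np.testing.assert_allclose(m.highway_forward(H).data, t, atol=1e-6)

    def test_scalar_instance_hand_computed(self):
        # n_h=1, S=1: H=1, W_g=0, b_g=0 -> g=0.5; W_t=1, b_t=0 -> t=1;
        # output = 0.5*1 + 0.5*1 = 1
        m = tiny_model(n_h=1, n_v=1, n_g=1)
        m.params["highway0.W_g"].data[:] = 0.0
        m.params["highway0.b_g"].data[:] = 0.0
        m.params["highway0.W_t"].data[:] = 1.0
        m.params["highway0.b_t"].data[:] = 0.0
        out = m.highway_forward(Tensor(np.ones((1, 1, 1))))
        assert out.data.item() == pytest.approx(1.0)


class TestEmbeddingLSTM:
    def test_mixture_weights_rows_sum_to_one_via_identical_layers(self):
        # with all LSTM weights zero each residual layer is the identity,
        # so the mixture (a convex combination of equal points) returns H
        m = tiny_model()
        for i in range(3):
            for part in ("w_ih", "w_hh", "b"):
                m.params[f"embed{i}.{part}"].data[:] = 0.0
        H = Tensor(np.random.default_rng(1).normal(size=(2, 10, 3)))
        out = m.embedding_lstm(H)
        np.testing.assert_allclose(out.data, H.data, atol=1e-12)

    def test_output_shape_preserved(self):
        m = tiny_model()
        X, G = rand_inputs(m.config)
        H_X, _ = m.linear_projection(Tensor(X), Tensor(G))
        assert m.embedding_lstm(H_X).shape == (2, 10, 3)


class TestGate:
    def test_saturated_gate_returns_signal_branch(self):
        m = tiny_model()
        m.params["gate.b_m"].data[:] = 30.0
        m.params["gate.W_m"].data[:] = 0.0
        rng = np.random.default_rng(2)
        L = Tensor(rng.normal(size=(1, 10, 3)))
        Hg = Tensor(rng.normal(size=(1, 10, 3)))
        np.testing.assert_allclose(m.gate_forward(L, Hg).data, L.data,
                                   atol=1e-6)

    def test_equal_inputs_pass_through_for_any_gate(self):
        m = tiny_model(seed=7)
        L = Tensor(np.random.default_rng(3).normal(size=(2, 10, 3)))
        np.testing.assert_allclose(m.gate_forward(L, L).data, L.data,
                                   atol=1e-12)

    def test_output_bounded_by_inputs_elementwise(self):
        m = tiny_model(seed=5)
        rng = np.random.default_rng(4)
        L = Tensor(rng.normal(size=(2, 10, 3)))
        Hg = Tensor(rng.normal(size=(2, 10, 3)))
        out = m.gate_forward(L, Hg).data
        lo = np.minimum(L.data, Hg.data)
        hi = np.maximum(L.data, Hg.data)
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()


class TestModelingLSTM:
    def test_zero_input_zero_parameters_gives_zero(self):
        m = tiny_model()
        for part in ("w_ih", "w_hh", "b"):
            m.params[f"modeling.{part}"].data[:] = 0.0
        out = m.modeling_lstm(Tensor(np.zeros((1, 10, 3))))
        assert not out.data.any()

    def test_matches_hand_stepped_recurrence(self):
        # length-3 sequence, n_h=1: step the standard gated recurrence by
        # hand and add the residual
        m = tiny_model(n_h=1, n_v=1, n_g=1)
        wi = m.params["modeling.w_ih"].data
        wh = m.params["modeling.w_hh"].data
        b = m.params["modeling.b"].data
        x = np.array([0.5, -1.0, 2.0]).reshape(1, 3, 1)
        h_prev = np.zeros(1)
        c_prev = np.zeros(1)
        expected = []
        for t in range(3):
            z = x[0, t] @ wi + h_prev @ wh + b
            i, f = _expit(z[:1]), _expit(z[1:2])
            g, o = np.tanh(z[2:3]), _expit(z[3:4])
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            expected.append(h + x[0, t])
            h_prev, c_prev = h, c
        out = m.modeling_lstm(Tensor(x))
        np.testing.assert_allclose(out.data[0], np.array(expected), atol=1e-12)


class TestDetector:
    def test_distribution_normalized(self):
        m = tiny_model()
        M = Tensor(np.random.default_rng(0).normal(size=(2, 10, 3)))
        TP, _ = m.detector_forward(M)
        np.testing.assert_allclose(TP.data.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_output_head_gives_uniform_distribution(self):
        m = tiny_model()
        m.params["det.W_tp"].data[:] = 0.0
        m.params["det.b_tp"].data[:] = 0.0
        M = Tensor(np.random.default_rng(0).normal(size=(1, 10, 3)))
        TP, _ = m.detector_forward(M)
        np.testing.assert_allclose(TP.data, 0.1, atol=1e-12)

    @pytest.mark.parametrize("S", [7, 16, 33])
    def test_length_preserved_for_any_sequence_length(self, S):
        m = tiny_model(S=S)
        M = Tensor(np.random.default_rng(0).normal(size=(1, S, 3)))
        TP, _ = m.detector_forward(M)
        assert TP.shape == (1, S)

    def test_sequence_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            tiny_config(S=5)


class TestSelectTurningPoint:
    def test_high_confidence_step_chosen_directly(self):
        p = np.full(960, 0.1 / 959)
        p[412] = 0.9
        assert select_turning_point(p) == 412

    def test_uniform_distribution_has_no_turning_point(self):
        p = np.full(960, 1.0 / 960)
        assert select_turning_point(p) == 959

    def test_tied_candidates_resolve_to_latest(self):
        p = np.full(960, 0.4 / 958)
        p[100] = 0.3
        p[200] = 0.3
        assert select_turning_point(p) == 200

    def test_candidate_below_4_over_length_rejected(self):
        p = np.full(100, 1.0)
        p /= p.sum()  # uniform: 0.01 < 4/100
        assert select_turning_point(p) == 99

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            select_turning_point(np.array([]))


class TestVerifier:
    def test_rows_normalized(self):
        m = tiny_model()
        M = Tensor(np.random.default_rng(0).normal(size=(2, 10, 3)))
        P, Pv = m.verifier_forward(M, np.array([3, 7]))
        np.testing.assert_allclose(P.data.sum(-1), 1.0, atol=1e-9)
        np.testing.assert_allclose(Pv.data.sum(-1), 1.0, atol=1e-9)

    def test_equal_corrections_cancel(self):
        # identical before/after heads and sequence transforms make the
        # verifier correction vanish: P_verified == P
        m = tiny_model()
        m.params["ver.W_w"].data[:] = m.params["ver.W_nw"].data
        m.params["ver.b_w"].data[:] = m.params["ver.b_nw"].data
        for part in ("w_ih", "w_hh", "b"):
            m.params[f"ver.after.{part}"].data[:] = \
                m.params[f"ver.before.{part}"].data
        M = Tensor(np.random.default_rng(1).normal(size=(2, 10, 3)))
        P, Pv = m.verifier_forward(M, np.array([4, 0]))
        np.testing.assert_allclose(Pv.data, P.data, atol=1e-12)

    def test_tp_zero_uses_after_head_everywhere(self):
        m = tiny_model()
        M = Tensor(np.random.default_rng(2).normal(size=(1, 10, 3)))
        P, _ = m.verifier_forward(M, 0)
        logits = M.data @ m.params["ver.W_w"].data + m.params["ver.b_w"].data
        e = np.exp(logits - logits.max(-1, keepdims=True))
        np.testing.assert_allclose(P.data, e / e.sum(-1, keepdims=True),
                                   atol=1e-9)

    def test_out_of_range_turning_point_rejected(self):
        m = tiny_model()
        M = Tensor(np.zeros((1, 10, 3)))
        with pytest.raises(ValueError, match="range"):
            m.verifier_forward(M, 10)


class TestFullForward:
    def test_evaluation_mode_is_deterministic(self):
        m = tiny_model(seed=3)
        X, G = rand_inputs(m.config)
        a = m.forward(X, G)
        b = m.forward(X, G)
        np.testing.assert_array_equal(a.TP.data, b.TP.data)
        np.testing.assert_array_equal(a.P_verified.data, b.P_verified.data)
        np.testing.assert_array_equal(a.tp, b.tp)

    def test_smoke_end_to_end_invariants(self):
        m = tiny_model(seed=4)
        X, G = rand_inputs(m.config, B=3)
        out = m.forward(X, G)
        np.testing.assert_allclose(out.TP.data.sum(1), 1.0, atol=1e-6)
        np.testing.assert_allclose(out.P.data.sum(-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(out.P_verified.data.sum(-1), 1.0, atol=1e-6)
        assert ((out.tp >= 0) & (out.tp <= m.config.S - 1)).all()
        assert set(out.intermediates) >= {"H_X", "H_g", "L_X_bar", "M",
                                          "M_bar", "F"}

    def test_training_mode_turning_point_is_argmax(self):
        m = tiny_model(seed=5)
        X, G = rand_inputs(m.config)
        out = m.forward(X, G, training=True, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.tp, np.argmax(out.TP.data, axis=1))

    def test_gradient_reaches_every_parameter_group(self):
        m = tiny_model(seed=6)
        X, G = rand_inputs(m.config, B=1)
        out = m.forward(X, G, training=True, rng=np.random.default_rng(1))
        S = m.config.S
        labels = np.zeros(S, dtype=int)
        labels[4:] = 1
        loss = detection_focal_loss(out.TP[0], 4, S) \
            + weighted_nll(out.P.reshape((S, 2)), labels, np.ones(S)) \
            + weighted_nll(out.P_verified.reshape((S, 2)), labels, np.ones(S))
        loss.backward()
        for k, t in m.params.items():
            assert t.grad is not None, f"no gradient for {k}"
            assert np.all(np.isfinite(t.grad)), f"non-finite gradient for {k}"
            assert np.any(t.grad != 0.0), f"dead parameter group {k}"


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path):
        m = tiny_model(seed=8)
        X, G = rand_inputs(m.config)
        before = m.forward(X, G)
        save_checkpoint(m, tmp_path / "ck.npz",
                        ema={k: v * 0.5 for k, v in
                             m.parameter_arrays().items()})
        again = load_checkpoint(tmp_path / "ck.npz")
        after = again.forward(X, G)
        np.testing.assert_array_equal(before.P_verified.data,
                                      after.P_verified.data)
        ema_model = load_checkpoint(tmp_path / "ck.npz", use_ema=True)
        np.testing.assert_allclose(ema_model.params["proj.W_x"].data,
                                   0.5 * m.params["proj.W_x"].data)
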