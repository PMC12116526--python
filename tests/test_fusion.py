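"""Fusion math: encoders, softmax weighting, attention blocks, toy training."""

import numpy as np
import pytest

from agrifuse.fusion import (
    EncoderParams,
    cross_modal_attention,
    cross_modal_fuse,
    encode_and_project,
    fused_zone_matrix,
    modality_weights,
    softmax,
    spatial_attention,
    temporal_aggregate,
    train_toy_detector,
)


def _identity_params(d, modalities=("a", "b")):
    p = EncoderParams.init_random({m: d for m in modalities}, d=d, d_k=d, seed=0)
    for m in modalities:
        p.E[m] = np.eye(d)
        p.P[m] = np.eye(d)
    return p


class TestEncode:
    def test_identity_encoder_reproduces_reshaped_input(self, rng):
        p = _identity_params(3)
        X = rng.standard_normal((2, 2, 3))
        tokens, shapes = encode_and_project({"a": X, "b": rng.standard_normal((4, 3))}, p)
        assert np.array_equal(tokens["a"], X.reshape(4, 3))
        assert shapes["a"] == (2, 2) and shapes["b"] is None

    def test_zero_observation_gives_zero_tokens(self):
        p = EncoderParams.init_random({"a": 5}, d=4, seed=1)
        tokens, _ = encode_and_project({"a": np.zeros((3, 5))}, p)
        assert np.all(tokens["a"] == 0.0)

    def test_all_modalities_map_to_shared_dimension(self, rng):
        dims = {"sat": 4, "uav": 3, "ground": 4, "weather": 8}
        p = EncoderParams.init_random(dims, d=6, seed=2)
        raw = {m: rng.standard_normal((5, d_in)) for m, d_in in dims.items()}
        tokens, _ = encode_and_project(raw, p)
        assert all(T.shape[1] == 6 for T in tokens.values())

    def test_shape_mismatch_names_modality(self, rng):
        p = EncoderParams.init_random({"uav": 3}, d=4, seed=0)
        with pytest.raises(ValueError, match="uav"):
            encode_and_project({"uav": rng.standard_normal((2, 5))}, p)


class TestModalityWeights:
    def test_equal_scores_give_uniform_weights(self):
        F = [np.ones((2, 3))] * 4
        W = [np.ones((3, 1))] * 4
        assert modality_weights(F, W) == pytest.approx([0.25] * 4)

    def test_closed_form_softmax(self):
        F = [np.array([[np.log(2.0)]]), np.array([[0.0]])]
        W = [np.eye(1), np.eye(1)]
        assert modality_weights(F, W) == pytest.approx([2 / 3, 1 / 3])

    def test_score_shift_invariance(self, rng):
        F = [rng.standard_normal((3, 2)) for _ in range(3)]
        W = [rng.standard_normal((2, 1)) for _ in range(3)]
        w0 = modality_weights(F, W)
        shifted = [f + 0 for f in F]
        # adding the same constant score to every modality: emulate by
        # softmax shift-invariance on the raw scores
        scores = np.array([float(np.mean(f @ w)) for f, w in zip(F, W)])
        assert softmax(scores + 7.3) == pytest.approx(w0)

    def test_empty_modality_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            modality_weights([], [])


class TestSpatialAttention:
    def test_constant_scores_give_uniform_map(self):
        F = np.ones((3, 4, 2))
        A, F_att = spatial_attention(F, np.zeros(2))
        assert A == pytest.approx(np.full((3, 4), 1 / 12))
        assert F_att == pytest.approx(F / 12)

    def test_saturated_softmax_selects_one_location(self):
        F = np.zeros((2, 2, 1))
        F[1, 1, 0] = 50.0
        A, F_att = spatial_attention(F, np.ones(1))
        assert A[1, 1] == pytest.approx(1.0, abs=1e-9)
        assert F_att[1, 1, 0] == pytest.approx(50.0, rel=1e-6)

    def test_attention_map_normalized(self, rng):
        for _ in range(100):
            F = rng.standard_normal((3, 5, 4))
            A, _ = spatial_attention(F, rng.standard_normal(4))
            assert A.sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_spatial_input_rejected(self, rng):
        with pytest.raises(ValueError, match="H x W"):
            spatial_attention(rng.standard_normal((3, 4)), np.zeros(4))


class TestTemporal:
    def test_recurrent_zero_weights_collapse_to_zero(self, rng):
        p = EncoderParams.init_random({"a": 4}, d=4, seed=0)
        p.W_h = np.zeros((4, 4))
        p.U_h = np.zeros((4, 4))
        p.b_h = np.zeros(4)
        out = temporal_aggregate(rng.standard_normal((6, 4)), p, mode="recurrent")
        assert np.all(out == 0.0)

    def test_single_token_transformer_is_value_projection(self, rng):
        p = EncoderParams.init_random({"a": 4}, d=4, d_k=3, seed=1)
        x = rng.standard_normal((1, 4))
        out = temporal_aggregate(x, p, mode="transformer", positions=False)
        assert out == pytest.approx(x[0] @ p.W_v)

    def test_transformer_position_sensitivity(self, rng):
        # permuting the non-final tokens changes the output only when
        # position encodings are enabled
        p = EncoderParams.init_random({"a": 4}, d=4, d_k=4, seed=2)
        X = rng.standard_normal((5, 4))
        Xp = X.copy()
        Xp[[0, 1, 2, 3]] = X[[2, 0, 3, 1]]
        with_pos = temporal_aggregate(X, p), temporal_aggregate(Xp, p)
        without = (
            temporal_aggregate(X, p, positions=False),
            temporal_aggregate(Xp, p, positions=False),
        )
        assert not np.allclose(with_pos[0], with_pos[1])
        assert without[0] == pytest.approx(without[1])

    def test_empty_sequence_rejected(self):
        p = EncoderParams.init_random({"a": 4}, d=4, seed=0)
        with pytest.raises(ValueError, match="nonempty"):
            temporal_aggregate(np.zeros((0, 4)), p)


class TestCrossModal:
    def test_attention_rows_are_convex_weights(self, rng):
        p = EncoderParams.init_random({"a": 4, "b": 4}, d=4, d_k=3, seed=0)
        C, _ = cross_modal_attention(rng.standard_normal((6, 4)), rng.standard_normal((5, 4)), p)
        assert C.shape == (6, 5)
        assert C.sum(axis=1) == pytest.approx(np.ones(6), abs=1e-9)
        assert np.all(C >= 0)

    def test_single_key_attention_returns_value(self, rng):
        p = EncoderParams.init_random({"a": 3, "b": 3}, d=3, d_k=3, seed=0)
        p.W_q = np.eye(3)
        p.W_k = np.eye(3)
        p.W_v = np.eye(3)
        tok = rng.standard_normal((1, 3))
        C, F12 = cross_modal_attention(tok, tok, p)
        assert C == pytest.approx(np.array([[1.0]]))
        assert F12 == pytest.approx(tok)

    def test_matches_bruteforce_double_loop(self, rng):
        # independent O(n^2) oracle for softmax(Q K^T / sqrt(d_k)) V
        p = EncoderParams.init_random({"a": 5, "b": 5}, d=5, d_k=4, seed=3)
        F1, F2 = rng.standard_normal((7, 5)), rng.standard_normal((8, 5))
        C, F12 = cross_modal_attention(F1, F2, p)
        Q, K, V = F1 @ p.W_q, F2 @ p.W_k, F2 @ p.W_v
        for i in range(7):
            logits = np.array([Q[i] @ K[j] / np.sqrt(4) for j in range(8)])
            e = np.exp(logits - logits.max())
            row = e / e.sum()
            assert np.max(np.abs(C[i] - row)) < 1e-10
            assert np.max(np.abs(F12[i] - row @ V)) < 1e-10

    def test_key_permutation_permutes_attention_columns(self, rng):
        p = EncoderParams.init_random({"a": 4, "b": 4}, d=4, d_k=3, seed=1)
        F1, F2 = rng.standard_normal((3, 4)), rng.standard_normal((6, 4))
        perm = rng.permutation(6)
        C, F12 = cross_modal_attention(F1, F2, p)
        Cp, F12p = cross_modal_attention(F1, F2[perm], p)
        assert Cp == pytest.approx(C[:, perm], abs=1e-12)
        assert F12p == pytest.approx(F12, abs=1e-12)

    def test_residual_contract_exact(self, rng):
        p = EncoderParams.init_random({"a": 4, "b": 4, "c": 4}, d=4, d_k=3, seed=2)
        toks = {m: rng.standard_normal((n, 4)) for m, n in zip("abc", (3, 5, 2))}
        rep = cross_modal_fuse(toks, p)
        expected = rep.F_fused + sum(rep.pooled.values())
        assert np.array_equal(rep.F_final, expected)

    def test_single_modality_rejected(self, rng):
        p = EncoderParams.init_random({"a": 4}, d=4, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            cross_modal_fuse({"a": rng.standard_normal((3, 4))}, p)

    def test_global_attention_rows_normalized(self, rng):
        p = EncoderParams.init_random({"a": 4, "b": 4}, d=4, d_k=3, seed=4)
        toks = {"a": rng.standard_normal((4, 4)), "b": rng.standard_normal((6, 4))}
        rep = cross_modal_fuse(toks, p)
        for c in rep.C_global.values():
            assert c.sum() == pytest.approx(1.0, abs=1e-9)


class TestToyTraining:
    def test_zero_learning_rate_is_noop(self, noiseless_scenario):
        model, _ = train_toy_detector(noiseless_scenario, epochs=5, lr=0.0, seed=0, n_samples=10)
        assert np.all(model["head_w"] == 0.0) and model["head_b"] == 0.0
        assert np.all(model["theta"] == 0.0)

    def test_same_seed_reproduces_training(self, noiseless_scenario):
        m1, r1 = train_toy_detector(noiseless_scenario, epochs=20, lr=0.5, seed=3, n_samples=20)
        m2, r2 = train_toy_detector(noiseless_scenario, epochs=20, lr=0.5, seed=3, n_samples=20)
        assert np.array_equal(m1["head_w"], m2["head_w"])
        assert r1.metrics == r2.metrics

    def test_divergence_raises_with_guidance(self, noiseless_scenario):
        with pytest.raises(ValueError, match="learning rate"):
            train_toy_detector(noiseless_scenario, epochs=400, lr=1e30, seed=0, n_samples=10)

    def test_fused_matrix_uses_softmax_weights(self, rng):
        p = EncoderParams.init_random({"sat": 3, "uav": 3}, d=4, seed=0)
        feats = {"sat": rng.standard_normal((5, 3)), "uav": rng.standard_normal((5, 3))}
        Z = fused_zone_matrix(feats, p, theta=np.array([50.0, 0.0]))
        only_sat = feats["sat"] @ p.E["sat"] @ p.P["sat"]
        assert Z == pytest.approx(only_sat, rel=1e-6)
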