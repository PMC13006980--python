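"""Forward model: projection, masked gating, fusion, encoder, hazard heads."""

import numpy as np
import pytest

import gatedsurv as gs
from gatedsurv._autodiff import Tensor
from gatedsurv.fusion import (
    ModelConfig,
    Params,
    cancer_hazards,
    forward,
    fuse,
    gate_logits,
    gate_weights,
    init_params,
    mask_logits,
    predict,
    project_modality,
    shared_encode,
    survival_curve,
    zero_substitute,
)
from conftest import make_batch


def scipy_softmax(x):
    from scipy.special import softmax

    return softmax(x, axis=-1)


class TestProjection:
    def test_zero_input_zero_bias_gives_zero(self, tiny_config):
        arrays = init_params(tiny_config, np.random.default_rng(0))
        arrays["b_rna"][:] = 0.0
        p = Params(arrays)
        z = project_modality(np.zeros((3, 256)), p, "rna", tiny_config)
        np.testing.assert_array_equal(z.data, np.zeros((3, 32)))

    def test_zero_weights_positive_bias_gives_constant_rows(self, tiny_config, rng):
        arrays = init_params(tiny_config, np.random.default_rng(0))
        arrays["W_txt"][:] = 0.0
        arrays["b_txt"][:] = 0.7
        p = Params(arrays)
        z = project_modality(rng.standard_normal((4, 768)), p, "txt", tiny_config)
        np.testing.assert_allclose(z.data, np.full((4, 32), 0.7))

    def test_eval_mode_matches_manual_relu_matmul(self, tiny_config, tiny_params, rng):
        x = rng.standard_normal((5, 2048))
        z = project_modality(x, tiny_params, "img", tiny_config, training=False)
        w = tiny_params["W_img"].data
        b = tiny_params["b_img"].data
        manual = np.maximum(x @ w.T + b, 0.0)
        np.testing.assert_allclose(z.data, manual, atol=1e-12)

    def test_dimension_mismatch_errors(self, tiny_config, tiny_params, rng):
        with pytest.raises(ValueError, match="width"):
            project_modality(rng.standard_normal((2, 100)), tiny_params, "rna", tiny_config)

    def test_dropout_only_in_training_mode(self, tiny_config, tiny_params, rng):
        x = rng.standard_normal((64, 256))
        z_eval = project_modality(x, tiny_params, "rna", tiny_config).data
        z_train = project_modality(
            x, tiny_params, "rna", tiny_config, training=True,
            rng=np.random.default_rng(0),
        ).data
        assert (z_train == 0).mean() > (z_eval == 0).mean()  # dropout zeros more


class TestMaskingAndGating:
    def test_zero_substitution_follows_mask_patterns(self, tiny_config, tiny_params, rng):
        mask = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 1], [1, 0, 0]])
        batch = make_batch(rng, b=4, config=tiny_config, mask=mask)
        out = forward(batch, tiny_params, tiny_config)
        for col, name in ((1, "z_rna"), (2, "z_txt")):
            z = out[name].data
            absent = mask[:, col] == 0
            assert np.all(z[absent] == 0.0)
            assert np.any(z[~absent] != 0.0)

    def test_image_cannot_be_marked_absent(self, rng):
        with pytest.raises(ValueError, match="image modality"):
            make_batch(rng, b=2, mask=np.array([[0, 1, 1], [1, 1, 1]]))

    def test_gate_logits_match_manual_concat_matmul(self, tiny_params, rng):
        z = [Tensor(rng.standard_normal((4, 32))) for _ in range(3)]
        logits = gate_logits(*z, tiny_params)
        manual = np.hstack([t.data for t in z]) @ tiny_params["W_gate"].data.T
        np.testing.assert_allclose(logits.data, manual, atol=1e-12)

    def test_selector_gate_copies_coordinates(self, tiny_params, rng):
        arrays = {k: v.data.copy() for k, v in tiny_params.tensors.items()}
        arrays["W_gate"][:] = 0.0
        arrays["W_gate"][0, 3] = 1.0  # logit 0 = z_img[:, 3]
        arrays["W_gate"][1, 32 + 5] = 1.0
        arrays["W_gate"][2, 64 + 7] = 1.0
        p = Params(arrays)
        z = [Tensor(rng.standard_normal((3, 32))) for _ in range(3)]
        logits = gate_logits(*z, p).data
        np.testing.assert_allclose(logits[:, 0], z[0].data[:, 3])
        np.testing.assert_allclose(logits[:, 1], z[1].data[:, 5])
        np.testing.assert_allclose(logits[:, 2], z[2].data[:, 7])

    def test_mask_logits_is_additive_penalty(self):
        logits = np.zeros((1, 3))
        masked = mask_logits(logits, np.array([[1, 0, 1]])).data
        np.testing.assert_array_equal(masked, [[0.0, -1e9, 0.0]])
        untouched = mask_logits(np.arange(3.0)[None], np.ones((1, 3), int)).data
        np.testing.assert_array_equal(untouched, np.arange(3.0)[None])

    def test_mask_logits_rejects_non_binary_mask(self):
        with pytest.raises(ValueError, match="binary"):
            mask_logits(np.zeros((1, 3)), np.array([[1, 0.5, 1]]))

    def test_fully_masked_row_puts_all_weight_on_image(self, rng):
        logits = rng.standard_normal((10, 3)) * 5
        g = gate_weights(mask_logits(logits, np.tile([1, 0, 0], (10, 1)))).data
        np.testing.assert_allclose(g[:, 0], 1.0, atol=1e-12)
        assert np.all(g[:, 1:] < 1e-12)

    def test_gate_weights_uniform_and_saturated_cases(self):
        np.testing.assert_allclose(
            gate_weights(np.zeros((1, 3))).data, [[1 / 3] * 3], atol=1e-15
        )
        g = gate_weights(np.array([[0.0, -1e9, -1e9]])).data
        np.testing.assert_allclose(g, [[1.0, 0.0, 0.0]], atol=1e-12)

    def test_gate_weights_match_scipy_softmax(self, rng):
        logits = rng.standard_normal((6, 3)) * 3
        np.testing.assert_allclose(
            gate_weights(logits).data, scipy_softmax(logits), atol=1e-12
        )

    def test_masked_softmax_equals_restricted_softmax(self, rng):
        """Gate of penalised logits == softmax over available modalities only."""
        for _ in range(200):
            logits = rng.standard_normal((1, 3)) * 10
            mask = np.array([[1, rng.integers(0, 2), rng.integers(0, 2)]])
            g = gate_weights(mask_logits(logits, mask)).data[0]
            avail = mask[0].astype(bool)
            restricted = np.zeros(3)
            restricted[avail] = scipy_softmax(logits[0, avail])
            np.testing.assert_allclose(g, restricted, atol=1e-9)
            assert abs(g.sum() - 1.0) < 1e-6
            assert np.all(g[~avail] < 1e-12)
            assert g[0] > 0


class TestFuseEncodeHeads:
    def test_degenerate_gate_selects_image(self, rng):
        z = [Tensor(rng.standard_normal((4, 32))) for _ in range(3)]
        g = Tensor(np.tile([1.0, 0.0, 0.0], (4, 1)))
        np.testing.assert_array_equal(fuse(g, *z).data, z[0].data)

    def test_equal_weights_on_equal_embeddings_is_identity(self, rng):
        z = Tensor(rng.standard_normal((3, 32)))
        g = Tensor(np.full((3, 3), 1 / 3))
        np.testing.assert_allclose(fuse(g, z, z, z).data, z.data, atol=1e-12)

    def test_fuse_matches_weighted_sum_loop(self, rng):
        zs = [rng.standard_normal((5, 32)) for _ in range(3)]
        g = rng.dirichlet(np.ones(3), size=5)
        out = fuse(Tensor(g), *[Tensor(z) for z in zs]).data
        manual = np.zeros((5, 32))
        for i in range(5):
            for m in range(3):
                manual[i] += g[i, m] * zs[m][i]
        np.testing.assert_allclose(out, manual, atol=1e-12)

    def test_fuse_rejects_unnormalised_weights(self, rng):
        z = [Tensor(rng.standard_normal((2, 32))) for _ in range(3)]
        with pytest.raises(ValueError, match="sum to 1"):
            fuse(Tensor(np.full((2, 3), 0.5)), *z)

    def test_identity_initialised_encoder_is_residual_identity(self, tiny_config, rng):
        arrays = init_params(tiny_config, np.random.default_rng(0))
        for layer in range(tiny_config.encoder_layers):
            for name in ("Wo", "bo", "W2", "b2"):
                arrays[f"enc{layer}_{name}"][:] = 0.0
        p = Params(arrays)
        x = Tensor(rng.standard_normal((4, 1, 32)))
        h = shared_encode(x, p, tiny_config)
        np.testing.assert_allclose(h.data, x.data[:, 0, :], atol=1e-12)

    def test_encoder_matches_independent_single_token_forward(self, rng):
        """Brute-force reimplementation of one pre-norm block, length-1 token."""
        config = ModelConfig(C=2, encoder_layers=1)
        p = Params(init_params(config, np.random.default_rng(9)))
        x = rng.standard_normal((3, 1, 32))

        def ln(v, g, b, eps=1e-5):
            mu = v.mean(-1, keepdims=True)
            var = ((v - mu) ** 2).mean(-1, keepdims=True)
            return (v - mu) / np.sqrt(var + eps) * g + b

        a = {k: t.data for k, t in p.tensors.items()}
        v = x[:, 0, :]
        xn = ln(v, a["enc0_ln1_g"], a["enc0_ln1_b"])
        # with one token, attention weights are exactly 1 -> context = V
        ctx = xn @ a["enc0_Wv"].T + a["enc0_bv"]
        v = v + ctx @ a["enc0_Wo"].T + a["enc0_bo"]
        xn2 = ln(v, a["enc0_ln2_g"], a["enc0_ln2_b"])
        ff = np.maximum(xn2 @ a["enc0_W1"].T + a["enc0_b1"], 0.0)
        want = v + ff @ a["enc0_W2"].T + a["enc0_b2"]

        got = shared_encode(Tensor(x), p, config).data
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_hazards_are_half_for_zero_head(self, tiny_config, rng):
        arrays = init_params(tiny_config, np.random.default_rng(0))
        arrays["head1_W"][:] = 0.0
        arrays["head1_b"][:] = 0.0
        p = Params(arrays)
        h = cancer_hazards(Tensor(rng.standard_normal((3, 32))), np.array([1, 1, 1]), p, tiny_config)
        np.testing.assert_allclose(h.data, 0.5)

    def test_per_row_head_dispatch_via_saturated_biases(self, tiny_config, rng):
        arrays = init_params(tiny_config, np.random.default_rng(0))
        arrays["head0_W"][:] = 0.0
        arrays["head0_b"][:] = 10.0
        arrays["head2_W"][:] = 0.0
        arrays["head2_b"][:] = -10.0
        p = Params(arrays)
        h = cancer_hazards(Tensor(rng.standard_normal((2, 32))), np.array([0, 2]), p, tiny_config).data
        assert np.all(h[0] > 0.99)
        assert np.all(h[1] < 0.01)

    def test_hazards_match_per_row_matvec(self, tiny_config, tiny_params, rng):
        h_in = rng.standard_normal((5, 32))
        ids = rng.integers(0, 3, 5)
        got = cancer_hazards(Tensor(h_in), ids, tiny_params, tiny_config).data
        for i in range(5):
            w = tiny_params[f"head{ids[i]}_W"].data
            b = tiny_params[f"head{ids[i]}_b"].data
            want = 1.0 / (1.0 + np.exp(-(w @ h_in[i] + b)))
            np.testing.assert_allclose(got[i], want, atol=1e-12)

    def test_unknown_cancer_id_errors(self, tiny_config, tiny_params, rng):
        with pytest.raises(ValueError, match="cancer index"):
            cancer_hazards(Tensor(rng.standard_normal((1, 32))), np.array([7]), tiny_params, tiny_config)


class TestSurvivalCurve:
    def test_zero_hazards_give_flat_curve(self):
        np.testing.assert_array_equal(survival_curve(np.zeros(4)), np.ones(4))

    def test_half_hazards_give_powers_of_half(self):
        np.testing.assert_allclose(
            survival_curve(np.full(4, 0.5)), [0.5, 0.25, 0.125, 0.0625]
        )

    def test_matches_cumulative_product_loop(self, rng):
        h = rng.random((20, 4))
        s = survival_curve(h)
        for i in range(20):
            acc = 1.0
            for t in range(4):
                acc *= 1 - h[i, t]
                assert s[i, t] == pytest.approx(acc, abs=1e-14)

    def test_rejects_out_of_range_hazards(self):
        with pytest.raises(ValueError):
            survival_curve(np.array([0.2, 1.3, 0.1, 0.0]))


class TestForward:
    def test_image_only_batch_follows_image_pathway(self, tiny_config, tiny_params, rng):
        batch = make_batch(rng, b=3, config=tiny_config, mask=np.tile([1, 0, 0], (3, 1)))
        out = forward(batch, tiny_params, tiny_config)
        np.testing.assert_allclose(out["gate"].data[:, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(out["z_fused"].data, out["z_img"].data, atol=1e-9)

    def test_predictions_ignore_rna_txt_weights_when_all_absent(self, tiny_config, rng):
        batch = make_batch(rng, b=4, config=tiny_config, mask=np.tile([1, 0, 0], (4, 1)))
        arrays = init_params(tiny_config, np.random.default_rng(1))
        base = forward(batch, Params(arrays), tiny_config)["hazards"].data
        arrays2 = {k: v.copy() for k, v in arrays.items()}
        arrays2["W_rna"] = np.random.default_rng(2).standard_normal(arrays["W_rna"].shape)
        arrays2["W_txt"] += 3.0
        again = forward(batch, Params(arrays2), tiny_config)["hazards"].data
        np.testing.assert_array_equal(base, again)

    def test_eval_forward_is_byte_stable(self, tiny_config, tiny_params, rng):
        batch = make_batch(rng, b=8, config=tiny_config)
        a = forward(batch, tiny_params, tiny_config)["hazards"].data
        b = forward(batch, tiny_params, tiny_config)["hazards"].data
        assert a.tobytes() == b.tobytes()

    def test_predict_exposes_gate_and_monotone_survival(self, tiny_config, tiny_params, rng):
        batch = make_batch(rng, b=6, config=tiny_config)
        pred = predict(batch, tiny_params, tiny_config)
        assert pred.gate.shape == (6, 3)
        assert np.all(np.diff(pred.survival, axis=1) <= 1e-12)
        assert np.all((pred.hazards > 0) & (pred.hazards < 1))
        assert np.all(np.isfinite(pred.risk))

    def test_early_fusion_foil_shares_encoder_and_heads(self, rng):
        config = ModelConfig(C=3, fusion="early")
        arrays = init_params(config, np.random.default_rng(3))
        assert "W_fuse" in arrays and "W_gate" in arrays
        batch = make_batch(rng, b=4, config=config)
        out = forward(batch, Params(arrays), config)
        assert np.all(np.isnan(out["gate"].data))  # foil has no gate weights
        assert out["hazards"].data.shape == (4, config.T)


def test_config_invariants():
    with pytest.raises(ValueError):
        ModelConfig(T=1)
    with pytest.raises(ValueError):
        ModelConfig(penalty=-10.0)
    with pytest.raises(ValueError):
        ModelConfig(fusion="late")
    roundtrip = ModelConfig.from_json(ModelConfig(C=4).to_json())
    assert roundtrip.C == 4
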