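"""Cross-modal attention fusion, the prediction head, and the composed model."""

import numpy as np
import pytest

from cmapfusion.autograd import Tensor
from cmapfusion.config import preset
from cmapfusion.errors import ConfigurationError, ShapeError
from cmapfusion.fusion import (
    CrossModalAttention,
    PredictHead,
    cross_modal_attention,
    fuse_residual_norm,
    predict_head,
)
from cmapfusion.model import AblationToggle, CMAPFusionModel


def _softmax(z, axis=-1):
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class TestCrossModalAttention:
    def test_vector_mode_softmax_over_single_key_is_identity(self, rng):
        d = 6
        wq, wk, wv = (rng.normal(size=(d, d)) for _ in range(3))
        fi, fl = rng.normal(size=d), rng.normal(size=d)
        np.testing.assert_array_equal(cross_modal_attention(fi, fl, wq, wk, wv), wv @ fl)

    def test_token_mode_identical_tokens_average_to_common_value(self, rng):
        d, m = 8, 4
        fi = rng.normal(size=d)
        fl_token = rng.normal(size=d // m)
        fl = np.tile(fl_token, m)
        eye = np.eye(d)
        out = cross_modal_attention(fi, fl, rng.normal(size=(d, d)), eye, eye, tokens=m)
        # identical keys give uniform attention; values are identical tokens
        np.testing.assert_allclose(out, fl, atol=1e-12)

    def test_token_mode_matches_hand_computed_attention(self, rng):
        d, m = 4, 2
        wq, wk, wv = (rng.normal(size=(d, d)) for _ in range(3))
        fi, fl = rng.normal(size=d), rng.normal(size=d)
        q = (wq @ fi).reshape(m, 2)
        k = (wk @ fl).reshape(m, 2)
        v = (wv @ fl).reshape(m, 2)
        expected = (_softmax(q @ k.T / np.sqrt(2.0)) @ v).reshape(d)
        np.testing.assert_allclose(
            cross_modal_attention(fi, fl, wq, wk, wv, tokens=m), expected, atol=1e-12
        )

    def test_module_matches_reference_op(self, rng):
        for tokens in (1, 4):
            mod = CrossModalAttention(8, rng, tokens=tokens)
            fi, fl = rng.normal(size=(3, 8)), rng.normal(size=(3, 8))
            out = mod(Tensor(fi), Tensor(fl)).data
            for i in range(3):
                ref = cross_modal_attention(
                    fi[i], fl[i], mod.w_q.data, mod.w_k.data, mod.w_v.data, tokens=tokens
                )
                np.testing.assert_allclose(out[i], ref, atol=1e-12)

    def test_indivisible_token_count_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            CrossModalAttention(6, rng, tokens=4)


class TestFuseResidualNorm:
    def test_zero_sum_input_stays_zero_under_eps_norm(self):
        x = np.array([1.0, -2.0, 3.0, 0.5])
        out = fuse_residual_norm(-x, x)
        np.testing.assert_allclose(out, np.zeros(4), atol=1e-12)

    def test_layer_norm_contract_mean_zero_unit_variance(self, rng):
        out = fuse_residual_norm(rng.normal(size=8), rng.normal(size=8))
        assert out.mean() == pytest.approx(0.0, abs=1e-5)
        assert out.var() == pytest.approx(1.0, abs=1e-4)

    def test_hand_normalisation_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = fuse_residual_norm(np.zeros(4), x)
        ref = (x - 2.5) / np.sqrt(x.var() + 1e-5)
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            fuse_residual_norm(np.zeros(3), np.zeros(4))


class TestPredictHead:
    def test_zero_weights_give_uniform_distribution(self):
        out = predict_head(np.ones(4), np.zeros((4, 2)), np.zeros(2), np.zeros((2, 3)), np.zeros(3))
        np.testing.assert_allclose(out, np.full(3, 1 / 3), atol=1e-12)

    def test_large_logit_saturates(self):
        w_o = np.zeros((2, 3))
        b_o = np.array([50.0, 0.0, 0.0])
        out = predict_head(np.ones(4), np.zeros((4, 2)), np.zeros(2), w_o, b_o)
        assert out[0] > 1 - 1e-9

    def test_matches_hand_relu_softmax_chain(self, rng):
        d, c = 4, 3
        w_b, b_b = rng.normal(size=(d, 2)), rng.normal(size=2)
        w_o, b_o = rng.normal(size=(2, c)), rng.normal(size=c)
        f = rng.normal(size=d)
        refine = np.maximum(f @ w_b + b_b, 0)
        expected = _softmax(refine @ w_o + b_o)
        np.testing.assert_allclose(predict_head(f, w_b, b_b, w_o, b_o), expected, atol=1e-12)

    def test_fewer_than_two_classes_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            PredictHead(8, 1, rng)

    def test_probability_simplex_on_random_inputs(self, rng):
        head = PredictHead(8, 5, rng)
        _, probs = head(Tensor(rng.normal(size=(20, 8)) * 10))
        assert probs.data.min() >= 0
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)


@pytest.fixture(scope="module")
def toy_batch():
    cfg = preset("toy")
    rng = np.random.default_rng(0)
    images = rng.normal(size=(6, 32, 32, 3))
    labs = rng.random((6, 10, 8))
    return cfg, images, labs


class TestComposedModel:
    def test_forward_full_shapes_and_concat_invariant(self, toy_batch):
        cfg, images, labs = toy_batch
        model = CMAPFusionModel(cfg.model, np.random.default_rng(1), cfg.smarttrim, cfg.fusion)
        bundle, state, out = model.forward_full((images, labs))
        d = cfg.model.d
        np.testing.assert_array_equal(bundle.f_cat[:, :d], bundle.f_image)
        np.testing.assert_array_equal(bundle.f_cat[:, d:], bundle.f_lab)
        assert bundle.f_lab.min() >= 0.0
        np.testing.assert_array_equal(state.f_prune, bundle.f_cat * state.mask)
        assert out.probs.shape == (6, cfg.model.n_classes)
        np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_smarttrim_disabled_gate_is_identity(self, toy_batch):
        cfg, images, labs = toy_batch
        model = CMAPFusionModel(
            cfg.model, np.random.default_rng(1), cfg.smarttrim, cfg.fusion,
            toggle=AblationToggle(use_smarttrim=False),
        )
        bundle, state, _ = model.forward_full((images, labs))
        np.testing.assert_array_equal(state.f_prune, bundle.f_cat)
        np.testing.assert_array_equal(state.mask, np.ones_like(bundle.f_cat))

    def test_cmt_disabled_uses_linear_adapter(self, toy_batch):
        cfg, images, labs = toy_batch
        model = CMAPFusionModel(
            cfg.model, np.random.default_rng(1), cfg.smarttrim, cfg.fusion,
            toggle=AblationToggle(use_cmt=False),
        )
        assert model.attention is None and model.adapter is not None
        out = model.forward(images, labs)
        ref = out["f_prune"].data @ model.adapter.weight.data + model.adapter.bias.data
        np.testing.assert_allclose(out["f_fusion"].data, ref, atol=1e-12)

    def test_vector_mode_attention_degeneracy_is_pinned(self, toy_batch):
        cfg, images, labs = toy_batch
        cfg_v = preset("toy")
        cfg_v.fusion.tokens = 1
        model = CMAPFusionModel(cfg_v.model, np.random.default_rng(1), cfg_v.smarttrim, cfg_v.fusion)
        out = model.forward(images, labs)
        fp_l = out["pruning_state"].f_prune_lab
        np.testing.assert_allclose(out["attn"].data, fp_l @ model.attention.w_v.data.T, atol=1e-12)

    def test_residual_sensitivity_to_image_branch(self, toy_batch):
        cfg, images, labs = toy_batch
        model = CMAPFusionModel(cfg.model, np.random.default_rng(1), cfg.smarttrim, cfg.fusion)
        out1 = model.forward(images, labs)
        out2 = model.forward(images + 0.05, labs)
        assert not np.allclose(out1["f_fusion"].data, out2["f_fusion"].data)

    def test_forward_reproducible_bitwise(self, toy_batch):
        cfg, images, labs = toy_batch
        model = CMAPFusionModel(cfg.model, np.random.default_rng(2), cfg.smarttrim, cfg.fusion)
        a = model.forward(images, labs)
        b = model.forward(images, labs)
        np.testing.assert_array_equal(a["probs"].data, b["probs"].data)
        np.testing.assert_array_equal(a["f_fusion"].data, b["f_fusion"].data)
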