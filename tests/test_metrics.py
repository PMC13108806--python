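"""Metric suite and training objective, cross-checked against scikit-learn."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, f1_score, roc_auc_score

from cmapfusion.errors import UndefinedMetricError
from cmapfusion.metrics import (
    LossBreakdown,
    accuracy_from_counts,
    auc_from_scores,
    confusion_matrix,
    count_parameters,
    cross_modal_similarity,
    estimate_flops,
    f1_from_counts,
    feature_sparsity,
    kappa_from_confusion,
    loss_total,
    loss_total_tensor,
    macro_f1,
)
from cmapfusion.autograd import Tensor
from cmapfusion.encoders import LabEncoder
from cmapfusion.nn import Linear


class TestCountMetrics:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,expected",
        [(10, 10, 0, 0, 1.0), (45, 40, 5, 10, 0.85), (0, 0, 3, 7, 0.0)],
    )
    def test_accuracy_from_counts(self, tp, tn, fp, fn, expected):
        assert accuracy_from_counts(tp, tn, fp, fn) == pytest.approx(expected)

    def test_accuracy_rejects_zero_total(self):
        with pytest.raises(ValueError):
            accuracy_from_counts(0, 0, 0, 0)

    @pytest.mark.parametrize(
        "tp,fp,fn,expected", [(8, 2, 2, 0.8), (0, 5, 5, 0.0), (7, 0, 0, 1.0)]
    )
    def test_f1_from_counts(self, tp, fp, fn, expected):
        assert f1_from_counts(tp, fp, fn) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cm,expected",
        [
            ([[50, 0], [0, 50]], 1.0),
            ([[40, 10], [10, 40]], 0.6),
            ([[25, 25], [25, 25]], 0.0),
        ],
    )
    def test_kappa_worked_examples(self, cm, expected):
        assert kappa_from_confusion(np.array(cm)) == pytest.approx(expected)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_from_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_pair_enumeration_example(self):
        # positives {0.8, 0.2}, negatives {0.6, 0.4}: 2 of 4 pairs correct
        assert auc_from_scores([0.8, 0.2, 0.6, 0.4], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_all_ties_give_half(self):
        assert auc_from_scores([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc_from_scores([0.1, 0.2], [1, 1])

    def test_rank_formulation_matches_trapezoidal_roc(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            scores = rng.normal(size=40)  # ties-free with probability 1
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            assert auc_from_scores(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-9
            )


def test_classification_metrics_match_sklearn_on_random_inputs():
    """Accuracy, macro-F1, kappa and macro-OvR AUC agree with the reference
    implementations to 1e-9 over 500 random prediction sets."""
    rng = np.random.default_rng(17)
    for _ in range(500):
        c = int(rng.integers(2, 6))
        n = int(rng.integers(c + 2, 60))
        labels = rng.integers(0, c, size=n)
        preds = rng.integers(0, c, size=n)
        cm = confusion_matrix(labels, preds, c)
        assert np.trace(cm) / cm.sum() == pytest.approx((labels == preds).mean(), abs=1e-12)
        assert macro_f1(cm) == pytest.approx(
            f1_score(labels, preds, average="macro", labels=range(c), zero_division=0),
            abs=1e-9,
        )
        if len(np.unique(labels)) > 1 or len(np.unique(preds)) > 1:
            assert kappa_from_confusion(cm) == pytest.approx(
                cohen_kappa_score(labels, preds, labels=range(c)), abs=1e-9
            )
        assert -1.0 <= kappa_from_confusion(cm) <= 1.0
        if len(np.unique(labels)) > 1:
            scores = rng.random(size=(n, c))
            expected = np.mean(
                [roc_auc_score((labels == k).astype(int), scores[:, k]) for k in np.unique(labels)]
            )
            assert auc_from_scores(scores, labels) == pytest.approx(expected, abs=1e-9)


class TestFeatureQuality:
    def test_sparsity_counting(self):
        assert feature_sparsity(np.zeros(7)) == 100.0
        assert feature_sparsity(np.ones(7)) == 0.0
        v = np.array([1.0, 0, 0, 2.0, 0, 0, 0, 3.0])
        assert feature_sparsity(v) == pytest.approx(62.5)
        with pytest.raises(ValueError):
            feature_sparsity(np.array([]))

    def test_cosine_similarity(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cross_modal_similarity(v, 2 * v) == pytest.approx(1.0)
        assert cross_modal_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cross_modal_similarity([1, 2, 3], [3, 2, 1]) == pytest.approx(10 / 14)
        with pytest.raises(UndefinedMetricError):
            cross_modal_similarity(np.zeros(3), v)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        f = np.array([[1.0, 1.0]])
        lb = loss_total(probs, [0], f, f, np.zeros((1, 4)))
        assert lb.cls == 0.0 and lb.sparse == 0.0
        assert lb.cm == pytest.approx(0.0, abs=1e-12)
        assert lb.total == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_composition(self):
        lb = LossBreakdown(cls=1.0, cm=0.5, sparse=0.4, alpha=0.1, beta=0.05, total=1.0 + 0.1 * 0.5 + 0.05 * 0.4)
        assert lb.total == pytest.approx(1.07)

    def test_orthogonal_embeddings_give_unit_alignment_loss(self):
        probs = np.array([[0.5, 0.5]])
        lb = loss_total(probs, [0], np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]), np.ones((1, 4)))
        assert lb.cm == pytest.approx(1.0)

    def test_zero_probability_clamped_not_inf(self):
        probs = np.array([[0.0, 1.0]])
        f = np.array([[1.0, 0.0]])
        lb = loss_total(probs, [0], f, f, np.ones((1, 2)))
        assert np.isfinite(lb.cls)
        assert lb.cls == pytest.approx(-np.log(1e-12))

    def test_decomposition_recombines_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n, c = 8, 4
            logits = rng.normal(size=(n, c))
            probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
            lb = loss_total(
                probs, rng.integers(0, c, n), rng.normal(size=(n, 6)), rng.random(size=(n, 6)) + 0.01,
                rng.integers(0, 2, (n, 12)).astype(float), alpha=0.1, beta=0.05,
            )
            assert lb.total == lb.cls + 0.1 * lb.cm + 0.05 * lb.sparse  # bit-exact

    def test_tensor_loss_matches_reference(self, rng):
        n, c = 6, 3
        logits = rng.normal(size=(n, c))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = rng.integers(0, c, n)
        fi, fl = rng.normal(size=(n, 5)), rng.random(size=(n, 5)) + 0.01
        mask = rng.random(size=(n, 10))
        _, bd = loss_total_tensor(Tensor(probs), labels, Tensor(fi), Tensor(fl), Tensor(mask))
        ref = loss_total(probs, labels, fi, fl, mask)
        assert bd.cls == pytest.approx(ref.cls, abs=1e-12)
        assert bd.cm == pytest.approx(ref.cm, abs=1e-9)
        assert bd.sparse == pytest.approx(ref.sparse, abs=1e-12)


class TestEfficiency:
    def test_single_linear_parameter_count(self, rng):
        lin = Linear(12, 768, rng)
        assert count_parameters(lin) == 12 * 768 + 768 == 9984

    def test_lab_encoder_parameter_count(self, rng):
        enc = LabEncoder(k=12, d=768, rng=rng)
        assert count_parameters(enc) == (12 * 384 + 384) + (384 * 768 + 768)

    def test_frozen_parameters_excluded(self, rng):
        lin = Linear(4, 4, rng)
        lin.weight.trainable = False
        lin.bias.trainable = False
        assert count_parameters(lin) == 0

    def test_linear_flops_definition(self, rng):
        lin = Linear(10, 20, rng)
        total, breakdown = estimate_flops(lin)
        assert total == 2 * 10 * 20 + 20
        assert estimate_flops(lin, batch=2)[0] == 2 * total

    def test_full_model_flops_equal_per_layer_hand_count(self, toy_config):
        from cmapfusion.model import CMAPFusionModel

        cfg = toy_config.model
        model = CMAPFusionModel(cfg, np.random.default_rng(0), toy_config.smarttrim, toy_config.fusion)
        total, breakdown = estimate_flops(model)
        d, p = cfg.d, cfg.patch
        h, w, c = cfg.image_size
        n_patch = (h // p) * (w // p)
        n_tok = n_patch + 1
        hand = (2 * p * p * c * d + d) * n_patch  # patch embedding
        for _ in range(cfg.depth):  # transformer blocks
            hand += (2 * d * 3 * d + 3 * d) * n_tok + (2 * d * d + d) * n_tok  # qkv + proj
            hand += 2 * (2 * n_tok * n_tok * d)  # QK^T and att@V
            hidden = int(d * cfg.mlp_ratio)
            hand += (2 * d * hidden + hidden) * n_tok + (2 * hidden * d + d) * n_tok
        hand += (2 * cfg.K * d // 2 + d // 2) * cfg.T + (2 * (d // 2) * d + d) * cfg.T  # lab MLP
        hand += 2 * (2 * d) * (2 * d) + 2 * d  # pruning scorer
        m = toy_config.fusion.tokens
        hand += 3 * 2 * d * d + 2 * (2 * m * m * (d // m))  # cross-modal attention
        hand += 2 * d * (d // 2) + d // 2  # bottleneck
        hand += 2 * (d // 2) * cfg.n_classes + cfg.n_classes  # classifier
        assert total == hand, breakdown
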