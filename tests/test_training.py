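"""Masked cross-entropy loss and the base/oracle training loops."""
import numpy as np
import pytest

from saen.bayesian_unet import UNetConfig, predict_probabilities
from saen.training import (TrainConfig, masked_cross_entropy, train_base_model,
                           train_uncertainty_oracle)
from saen.uncertainty import mc_sample


def loop_cross_entropy(probs, labels, masks, eps=1e-7):
    """Independent triple-loop oracle for the mask-gated cross-entropy."""
    n, c, h, w = probs.shape
    total = 0.0
    for b in range(n):
        for i in range(h):
            for j in range(w):
                for cls in range(c):
                    y = 1.0 if labels[b, i, j] == cls else 0.0
                    p = min(max(probs[b, cls, i, j], eps), 1.0)
                    total += masks[b, i, j] * y * np.log(p)
    return -total / (n * h * w)


def _random_inputs(rng, n=2, h=4, w=5, c=2):
    raw = rng.random((n, c, h, w))
    probs = raw / raw.sum(axis=1, keepdims=True)
    labels = rng.integers(0, c, size=(n, h, w))
    masks = (rng.random((n, h, w)) < 0.7).astype(np.uint8)
    return probs, labels, masks


class TestMaskedCrossEntropy:
    def test_all_ones_mask_reduces_to_plain_cross_entropy(self):
        rng = np.random.default_rng(0)
        probs, labels, _ = _random_inputs(rng)
        ones = np.ones(labels.shape, np.uint8)
        assert masked_cross_entropy(probs, labels, ones) == pytest.approx(
            loop_cross_entropy(probs, labels, ones), abs=1e-10)

    def test_all_zero_mask_is_zero_with_warning(self):
        rng = np.random.default_rng(1)
        probs, labels, _ = _random_inputs(rng)
        with pytest.warns(UserWarning, match="zero"):
            assert masked_cross_entropy(probs, labels,
                                        np.zeros(labels.shape, np.uint8)) == 0.0

    def test_hand_computed_three_term_fixture(self):
        # 1 image, 2x2 pixels, mask removes pixel (1,1); three remaining terms
        probs = np.array([[[[0.9, 0.2], [0.6, 0.3]],
                           [[0.1, 0.8], [0.4, 0.7]]]])
        labels = np.array([[[0, 1], [1, 0]]])
        masks = np.array([[[1, 1], [1, 0]]])
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.4)) / 4.0
        assert masked_cross_entropy(probs, labels, masks) == pytest.approx(
            expected, abs=1e-12)

    def test_matches_loop_oracle_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            probs, labels, masks = _random_inputs(rng)
            assert masked_cross_entropy(probs, labels, masks) == pytest.approx(
                loop_cross_entropy(probs, labels, masks), abs=1e-10)

    def test_batch_permutation_invariance_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        probs, labels, masks = _random_inputs(rng, n=4)
        loss = masked_cross_entropy(probs, labels, masks)
        assert loss >= 0.0
        perm = rng.permutation(4)
        assert masked_cross_entropy(probs[perm], labels[perm],
                                    masks[perm]) == pytest.approx(loss, abs=1e-12)

    def test_masking_removes_exactly_the_excluded_terms(self):
        rng = np.random.default_rng(4)
        probs, labels, masks = _random_inputs(rng)
        full = masked_cross_entropy(probs, labels, np.ones_like(masks))
        part = masked_cross_entropy(probs, labels, masks)
        excluded = loop_cross_entropy(probs, labels, 1 - masks)
        assert part + excluded == pytest.approx(full, abs=1e-10)

    def test_masked_count_normalization_option(self):
        rng = np.random.default_rng(5)
        probs, labels, masks = _random_inputs(rng)
        n, _, h, w = probs.shape
        by_all = masked_cross_entropy(probs, labels, masks)
        by_mask = masked_cross_entropy(probs, labels, masks,
                                       normalize_by_mask_count=True)
        assert by_mask == pytest.approx(by_all * n * h * w / masks.sum(), abs=1e-10)

    def test_shape_and_binary_validation(self):
        rng = np.random.default_rng(6)
        probs, labels, masks = _random_inputs(rng)
        with pytest.raises(ValueError, match="shape"):
            masked_cross_entropy(probs, labels[:, :2], masks)
        with pytest.raises(ValueError, match="binary"):
            masked_cross_entropy(probs, labels, masks * 2)


class TestTrainBaseModel:
    def test_zero_epochs_returns_initialized_model(self, small_records, tiny_unet_cfg):
        cfg = TrainConfig(epochs=0, seed=5)
        from saen.bayesian_unet import build_model

        model = train_base_model(small_records, None, tiny_unet_cfg, cfg, 0.7)
        fresh = build_model(tiny_unet_cfg, seed=5)
        for a, b in zip(model.net.parameters(), fresh.net.parameters()):
            assert np.array_equal(a.value, b.value)
        assert model.fingerprint["lambda"] == 0.7

    def test_training_decreases_loss_across_seeds(self, small_records, tiny_unet_cfg):
        drops = []
        for seed in (0, 1, 2):
            cfg = TrainConfig(epochs=2, crops_per_image=8, patch_shape=(16, 16),
                              seed=seed)
            model = train_base_model(small_records, None, tiny_unet_cfg, cfg, 1.0)
            curve = model.fingerprint["loss_curve"]
            drops.append(curve[-1] < curve[0])
        assert np.mean(drops) > 0.5

    def test_reproducible_for_fixed_seed(self, small_records, tiny_unet_cfg,
                                         tiny_train_cfg):
        a = train_base_model(small_records, None, tiny_unet_cfg, tiny_train_cfg, 1.0)
        b = train_base_model(small_records, None, tiny_unet_cfg, tiny_train_cfg, 1.0)
        for pa, pb in zip(a.net.parameters(), b.net.parameters()):
            assert np.allclose(pa.value, pb.value, atol=1e-6)

    def test_missing_mask_names_the_record(self, small_records, tiny_unet_cfg,
                                           tiny_train_cfg):
        masks = [np.ones_like(r.label) for r in small_records]
        masks[3] = None
        with pytest.raises(ValueError, match=small_records[3].subject_id):
            train_base_model(small_records, masks, tiny_unet_cfg, tiny_train_cfg, 0.5)

    def test_mask_shape_mismatch_rejected(self, small_records, tiny_unet_cfg,
                                          tiny_train_cfg):
        masks = [np.ones_like(r.label) for r in small_records]
        masks[0] = np.ones((4, 4), np.uint8)
        with pytest.raises(ValueError, match="mask shape"):
            train_base_model(small_records, masks, tiny_unet_cfg, tiny_train_cfg, 0.5)


class TestTrainOracle:
    def test_requires_inference_time_dropout(self, small_records, tiny_unet_cfg,
                                             tiny_train_cfg):
        with pytest.raises(ValueError, match="dropout"):
            train_uncertainty_oracle(small_records, tiny_unet_cfg, tiny_train_cfg)
        train_only = UNetConfig(**{**tiny_unet_cfg.__dict__, "dropout_rate": 0.5,
                                   "dropout_mode": "train_only"})
        with pytest.raises(ValueError, match="train_and_inference"):
            train_uncertainty_oracle(small_records, train_only, tiny_train_cfg)

    def test_oracle_contract(self, trained_tiny_oracle):
        assert trained_tiny_oracle.config.dropout_mode == "train_and_inference"
        assert trained_tiny_oracle.fingerprint["lambda"] == 1.0

    def test_oracle_uncertainty_is_nondegenerate(self, trained_tiny_oracle,
                                                 small_records):
        from saen.uncertainty import normalize_uncertainty, probability_variation

        stack = mc_sample(trained_tiny_oracle, small_records[0].image, T=10, seed=0)
        u = normalize_uncertainty(probability_variation(stack))
        assert u.values.max() > u.values.min()
        assert u.values.max() == 1.0
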