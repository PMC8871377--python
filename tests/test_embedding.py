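"""Hypersphere head, constrained loss, and training behaviour of the embedding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octanomaly import ImageSet, SynthConfig, generate_dataset
from octanomaly.embedding import (
    BackboneSpec,
    TrainConfig,
    ZeroFeatureError,
    extract_features,
    l2_norm_scale,
    l2_softmax_loss,
    train,
)
from oracles import softmax_loss_by_hand


class TestL2NormScale:
    def test_fixed_point(self):
        np.testing.assert_allclose(l2_norm_scale(np.array([3.0, 4.0]), 5.0), [3.0, 4.0])

    def test_axis_vector_alpha5(self):
        np.testing.assert_allclose(l2_norm_scale(np.array([1.0, 0.0, 0.0]), 5.0), [5.0, 0.0, 0.0])

    def test_symmetry(self):
        np.testing.assert_allclose(
            l2_norm_scale(np.array([1.0, 1.0]), 2.0), [np.sqrt(2), np.sqrt(2)]
        )

    def test_zero_vector_is_explicit_error(self):
        with pytest.raises(ZeroFeatureError):
            l2_norm_scale(np.zeros(4), 5.0)

    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            l2_norm_scale(np.ones(3), 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        vec=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        c=st.floats(1e-3, 1e3),
        alpha=st.floats(0.1, 20),
    )
    def test_scale_equivariance(self, vec, c, alpha):
        """Multiplying the raw feature by any c > 0 leaves the on-sphere feature unchanged."""
        v = np.array(vec)
        if np.linalg.norm(v) < 1e-6:
            return
        np.testing.assert_allclose(
            l2_norm_scale(c * v, alpha), l2_norm_scale(v, alpha), rtol=1e-9, atol=1e-9
        )


class TestL2SoftmaxLoss:
    def test_uniform_logits_give_log_C(self):
        feats = l2_norm_scale(np.random.default_rng(0).standard_normal((6, 4)), 5.0)
        loss = l2_softmax_loss(feats, [0, 1, 0, 1, 0, 1], np.zeros((4, 2)), np.zeros(2), 5.0)
        assert loss == pytest.approx(np.log(2.0), abs=1e-12)

    def test_single_sample_closed_form(self):
        # logits (1, 0) for the true class: loss = log(1 + e^-1)
        f = np.array([[2.0, 0.0]])  # norm 2, alpha 2
        W = np.array([[0.5, 0.0], [0.0, 1.0]])
        loss = l2_softmax_loss(f, [0], W, np.zeros(2), alpha=2.0)
        assert loss == pytest.approx(np.log(1 + np.exp(-1.0)), abs=1e-12)

    def test_matches_hand_rolled_softmax(self):
        # frozen small case: M=3, d=2, C=2 on the alpha=2 circle
        feats = np.array([[2.0, 0.0], [0.0, 2.0], [np.sqrt(2), np.sqrt(2)]])
        labels = [0, 1, 1]
        W = [[0.3, -0.2], [-0.1, 0.4]]
        b = [0.05, -0.05]
        expected = softmax_loss_by_hand(feats.tolist(), labels, W, b)
        got = l2_softmax_loss(feats, labels, np.array(W), np.array(b), alpha=2.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_norm_violation_is_contract_error(self):
        feats = np.array([[3.0, 0.0], [0.0, 2.0]])  # first row off the alpha=2 sphere
        with pytest.raises(ValueError, match="norm"):
            l2_softmax_loss(feats, [0, 1], np.zeros((2, 2)), np.zeros(2), alpha=2.0)

    def test_bad_labels_rejected(self):
        feats = np.array([[2.0, 0.0]])
        with pytest.raises(ValueError):
            l2_softmax_loss(feats, [5], np.zeros((2, 2)), np.zeros(2), alpha=2.0)


@pytest.fixture(scope="module")
def tiny_train_set():
    cfg = SynthConfig(height=64, width=64, n_layers=4, speckle_sd=0.02,
                      drusen_amplitude=9.0, drusen_width=11.0, fluid_depth=15.0,
                      fluid_width=30.0, tilt_jitter=2.0, seed=7)
    return generate_dataset(cfg, (40, 20, 20), seed=13)


class TestTraining:
    def test_zero_epochs_returns_initialized_model_empty_history(self, tiny_train_set):
        model, history, _ = train(
            tiny_train_set, TrainConfig(epochs=0, input_size=(64, 64, 3), seed=1)
        )
        assert history == []
        assert np.all(model.W == 0.0) and np.all(model.b == 0.0)

    def test_initial_loss_is_log2_for_zero_init_head(self, tiny_train_set):
        _, history, _ = train(
            tiny_train_set, TrainConfig(epochs=1, input_size=(64, 64, 3), seed=1)
        )
        assert history[0]["epoch"] == 0
        assert history[0]["train_loss"] == pytest.approx(np.log(2.0), abs=1e-9)

    def test_loss_decreases_and_validation_accuracy_high_on_easy_set(self, tiny_train_set):
        _, history, _ = train(
            tiny_train_set, TrainConfig(epochs=5, input_size=(64, 64, 3), seed=3)
        )
        assert history[-1]["train_loss"] < history[0]["train_loss"]
        assert history[-1]["val_acc"] >= 0.95

    def test_split_is_seeded_and_stratified(self, tiny_train_set):
        _, _, (tr1, va1) = train(tiny_train_set, TrainConfig(epochs=0, seed=9))
        _, _, (tr2, va2) = train(tiny_train_set, TrainConfig(epochs=0, seed=9))
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(va1, va2)
        y = np.array([im.binary_label.value for im in tiny_train_set])
        frac_tr = np.mean(y[tr1] == "AMD")
        frac_all = np.mean(y == "AMD")
        assert abs(frac_tr - frac_all) < 0.05

    def test_single_class_input_rejected(self, tiny_train_set):
        normals = tiny_train_set.subset(
            [i for i, im in enumerate(tiny_train_set) if im.binary_label.value == "NORMAL"]
        )
        with pytest.raises(ValueError):
            train(normals, TrainConfig(epochs=1))


class TestFeatureExtraction:
    def test_all_norms_equal_alpha_for_fresh_and_trained_models(self, tiny_train_set):
        fresh, _, _ = train(tiny_train_set, TrainConfig(epochs=0, seed=2))
        trained, _, _ = train(
            tiny_train_set, TrainConfig(epochs=2, input_size=(64, 64, 3), seed=2)
        )
        for model in (fresh, trained):
            feats = extract_features(model, tiny_train_set)
            norms = np.linalg.norm(feats, axis=1)
            np.testing.assert_allclose(norms, 5.0, rtol=1e-4)

    def test_duplicate_images_give_identical_rows(self, tiny_train_set):
        model, _, _ = train(tiny_train_set, TrainConfig(epochs=1, seed=4))
        pair = ImageSet([tiny_train_set[0], tiny_train_set[0]])
        feats = extract_features(model, pair)
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_feature_equals_norm_scale_of_backbone_output(self, tiny_train_set):
        model, _, _ = train(tiny_train_set, TrainConfig(epochs=1, seed=4))
        px = tiny_train_set[0].pixels[None]
        raw = model.backbone.forward(px)
        np.testing.assert_allclose(model.features(px), l2_norm_scale(raw, 5.0), rtol=1e-12)

    def test_empty_imageset_gives_zero_row_matrix(self, tiny_train_set):
        model, _, _ = train(tiny_train_set, TrainConfig(epochs=0, seed=2))
        feats = extract_features(model, ImageSet([]))
        assert feats.shape == (0, model.feature_dim)


class TestBackboneSpec:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            BackboneSpec(kind="vgg16")

    def test_tiny_cnn_has_no_pretrained_weights(self):
        with pytest.raises(ValueError):
            BackboneSpec(kind="tiny_cnn", pretrained=True)
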