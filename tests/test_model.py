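"""Training recipe contracts: backprop, early stopping, ensemble, Grad-CAM,
Hyperband bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import ngtlife as ng
from ngtlife.errors import ConfigurationError
from ngtlife.model import resize_images
from ngtlife.nn import SmallCNN

from conftest import toy_quadrant_images


class TestBackprop:
    def test_analytic_gradients_match_numeric(self):
        """Finite-difference check across conv, dense and pooling layers."""
        net = SmallCNN(8, (3, 4), dense_units=32, dropout_rate=0.0, n_classes=3,
                       seed=0, dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 8, 8))
        y = np.zeros((2, 3))
        y[0, 1] = y[1, 2] = 1.0
        net.loss_and_grads(x, y)
        eps = 1e-6
        for layer in net.layers:
            for name, p in layer.params.items():
                flat_idx = np.unravel_index([0, p.size // 2, p.size - 1], p.shape)
                for idx in zip(*flat_idx):
                    g = layer.grads[name][idx]
                    p[idx] += eps
                    lp = net.loss(x, y)
                    p[idx] -= 2 * eps
                    lm = net.loss(x, y)
                    p[idx] += eps
                    num = (lp - lm) / (2 * eps)
                    assert g == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestTrainClassifier:
    def test_separable_toy_reaches_perfect_training_accuracy(self, toy_model):
        x, y = toy_quadrant_images(200, seed=0)
        acc = (np.array(["a", "b"])[toy_model.predict_proba(x).argmax(1)] == y).mean()
        assert acc == 1.0
        assert len(toy_model.history) <= 30

    def test_early_stopping_fires_after_patience_epochs(self):
        # zero learning rate freezes the network: validation loss can never
        # improve after epoch 1, so training must stop at 1 + patience
        x, y = toy_quadrant_images(40, seed=2)
        xv, yv = toy_quadrant_images(20, seed=3)
        cfg = ng.ClassifierConfig(input_side=16, conv_widths=(4,), dense_units=32,
                                  dropout_rate=0.0, learning_rate=0.0,
                                  patience=3, max_epochs=20, seed=0)
        m = ng.train_classifier(x, y, xv, yv, cfg, classes=("a", "b"))
        assert len(m.history) == 1 + cfg.patience

    def test_restored_weights_match_best_epoch(self):
        x, y = toy_quadrant_images(120, seed=4)
        xv, yv = toy_quadrant_images(40, seed=5)
        cfg = ng.ClassifierConfig(input_side=16, conv_widths=(4,), dense_units=32,
                                  dropout_rate=0.0, max_epochs=8, patience=2, seed=1)
        m = ng.train_classifier(x, y, xv, yv, cfg, classes=("a", "b"))
        probs = m.predict_proba(xv)
        onehot = np.array([[1.0, 0.0] if t == "a" else [0.0, 1.0] for t in yv])
        realized = float(-(onehot * np.log(probs + 1e-12)).sum() / len(yv))
        assert realized == pytest.approx(m.history["val_loss"].min(), abs=1e-6)

    def test_deterministic_loss_history(self):
        x, y = toy_quadrant_images(60, seed=6)
        xv, yv = toy_quadrant_images(20, seed=7)
        cfg = ng.ClassifierConfig(input_side=16, conv_widths=(4,), dense_units=32,
                                  max_epochs=3, seed=9)
        h1 = ng.train_classifier(x, y, xv, yv, cfg, classes=("a", "b")).history
        h2 = ng.train_classifier(x, y, xv, yv, cfg, classes=("a", "b")).history
        pd.testing.assert_frame_equal(h1, h2)

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            ng.train_classifier(np.zeros((0, 8, 8)), [], np.zeros((1, 8, 8)), ["a"])

    def test_single_class_warns_but_trains(self):
        x, _ = toy_quadrant_images(30, seed=8)
        xv, yv = toy_quadrant_images(10, seed=9)
        cfg = ng.ClassifierConfig(input_side=16, conv_widths=(4,), dense_units=32,
                                  max_epochs=2, seed=0)
        with pytest.warns(UserWarning):
            ng.train_classifier(x, ["a"] * 30, xv, yv, cfg, classes=("a", "b"))

    def test_inference_is_augmentation_free(self, toy_model):
        x, _ = toy_quadrant_images(10, seed=10)
        assert np.array_equal(toy_model.predict_proba(x), toy_model.predict_proba(x))

    def test_config_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            ng.ClassifierConfig(dense_units=16).validate()
        with pytest.raises(ConfigurationError):
            ng.ClassifierConfig(dropout_rate=0.5).validate()
        with pytest.raises(ConfigurationError):
            ng.ClassifierConfig(patience=0).validate()

    def test_save_load_roundtrip(self, toy_model, tmp_path):
        path = tmp_path / "model.npz"
        toy_model.save(path)
        loaded = ng.TrainedClassifier.load(path)
        x, _ = toy_quadrant_images(8, seed=11)
        assert np.allclose(loaded.predict_proba(x), toy_model.predict_proba(x))
        assert loaded.classes == toy_model.classes


class TestInference:
    def test_probability_rows_sum_to_one(self, toy_model):
        x, _ = toy_quadrant_images(20, seed=12)
        p = toy_model.predict_proba(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_images_identical_embeddings(self, toy_model):
        x, _ = toy_quadrant_images(4, seed=13)
        dup = np.concatenate([x, x[:1]])
        emb = toy_model.embed(dup)
        assert np.array_equal(emb[0], emb[-1])
        assert emb.shape[1] == toy_model.embed_dim

    def test_argmax_feeds_confusion_contract(self, toy_model):
        x, y = toy_quadrant_images(40, seed=14)
        p = toy_model.predict_proba(x)
        cm = ng.confusion(y, p, toy_model.classes)
        manual = np.array(toy_model.classes)[p.argmax(axis=1)]
        for i, cls_t in enumerate(toy_model.classes):
            for j, cls_p in enumerate(toy_model.classes):
                assert cm.counts[i, j] == np.sum((y == cls_t) & (manual == cls_p))

    def test_resize_ignores_aspect_ratio(self):
        rect = np.random.default_rng(0).normal(size=(1, 30, 60)).astype(np.float32)
        out = resize_images(rect, 32)
        assert out.shape == (1, 32, 32)


class _StubModel:
    def __init__(self, row, classes=("satisfactory", "malpositioned", "bronchial")):
        self.row = np.asarray(row, dtype=float)
        self.classes = tuple(classes)

    def predict_proba(self, images):
        return np.tile(self.row, (len(images), 1))


class TestEnsemble:
    def test_identical_constituents_idempotent(self, toy_model):
        x, _ = toy_quadrant_images(10, seed=15)
        single = toy_model.predict_proba(x)
        assert np.allclose(ng.ensemble_proba([toy_model, toy_model], x), single)

    def test_probability_averaging_arithmetic(self):
        out = ng.ensemble_proba([_StubModel([1, 0, 0]), _StubModel([0, 1, 0])],
                                np.zeros((3, 4, 4)))
        assert np.allclose(out, [0.5, 0.5, 0.0])

    def test_empty_model_list_raises(self):
        with pytest.raises(ValueError):
            ng.ensemble_proba([], np.zeros((1, 4, 4)))

    def test_mismatched_class_spaces_raise(self):
        with pytest.raises(ValueError):
            ng.ensemble_proba([_StubModel([1, 0, 0]),
                               _StubModel([1, 0, 0], classes=("a", "b", "c"))],
                              np.zeros((1, 4, 4)))

    def test_multi_model_embeddings_concatenate(self, toy_model):
        x, _ = toy_quadrant_images(5, seed=16)
        both = ng.extract_embeddings([toy_model, toy_model], x)
        assert both.shape == (5, 2 * toy_model.embed_dim)


class TestGradCam:
    def test_map_nonnegative_and_input_shaped(self, toy_model):
        x, _ = toy_quadrant_images(1, seed=17)
        sal = ng.grad_cam(toy_model, x[0], "b")
        assert sal.map.shape == x[0].shape
        assert (sal.map >= 0).all()

    def test_unknown_class_raises(self, toy_model):
        with pytest.raises(ValueError):
            ng.grad_cam(toy_model, np.zeros((32, 32)), "c")

    def test_detached_class_score_yields_zero_map(self, toy_model):
        import copy

        frozen = copy.deepcopy(toy_model)
        final_dense = frozen._net.layers[-1]
        final_dense.params["W"][:, 1] = 0.0  # class 'b' logit no longer depends on features
        final_dense.params["b"][1] = 0.0
        x, _ = toy_quadrant_images(1, seed=18)
        sal = ng.grad_cam(frozen, x[0], "b")
        assert np.allclose(sal.map, 0.0)

    def test_salient_region_matches_planted_signal(self, toy_model):
        # class 'b' is defined by the bright top-left quadrant; its saliency
        # must concentrate there on confidently classified images
        x, y = toy_quadrant_images(40, seed=19)
        probs = toy_model.predict_proba(x)
        b_mask = (y == "b") & (probs.argmax(1) == 1)
        hits = 0
        for img in x[b_mask]:
            sal = ng.grad_cam(toy_model, img, "b").map
            inside = sal[:16, :16].mean()
            outside = (sal.sum() - sal[:16, :16].sum()) / (32 * 32 - 256)
            hits += inside > outside
        assert hits / b_mask.sum() >= 0.8


class TestHyperband:
    def test_bracket_bookkeeping_r9_eta3(self):
        brackets = ng.hyperband_brackets(9, 3)
        assert brackets[0] == [(9, 1), (3, 3), (1, 9)]
        # later brackets shrink in rounds and start at higher budgets
        assert brackets[-1][0][1] == 9

    def test_budget_below_one_epoch_raises(self):
        with pytest.raises(ValueError):
            ng.hyperband_brackets(0)

    def test_singleton_space_returned_unchanged(self):
        x, y = toy_quadrant_images(40, seed=20, side=16)
        xv, yv = toy_quadrant_images(16, seed=21, side=16)
        base = ng.ClassifierConfig(input_side=16, conv_widths=(4,), dense_units=32,
                                   dropout_rate=0.0, seed=0)
        res = ng.tune_hyperband({"dense_units": [64]}, x, y, xv, yv, base_config=base,
                                budget_epochs=1, seed=0, classes=("a", "b"))
        assert res.best_config.dense_units == 64
        assert len(res.trials) >= 1

    def test_divergent_configuration_never_wins(self):
        x, y = toy_quadrant_images(60, seed=22, side=16)
        xv, yv = toy_quadrant_images(30, seed=23, side=16)
        base = ng.ClassifierConfig(input_side=16, conv_widths=(4,), dense_units=32,
                                   dropout_rate=0.0, seed=0)
        res = ng.tune_hyperband({"learning_rate": [1e-3, 10.0]}, x, y, xv, yv,
                                base_config=base, budget_epochs=3, seed=1,
                                classes=("a", "b"))
        assert res.best_config.learning_rate == pytest.approx(1e-3)
        # the ledger logged both candidates
        assert set(res.trials["learning_rate"]) == {1e-3, 10.0}
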