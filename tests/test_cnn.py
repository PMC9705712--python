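"""Numpy CNN: architecture, parameter counts, gradients, training behavior.

Heavier training runs live in the acceptance suite; the unit tests here
use reduced input sizes so the whole file stays fast.
"""

import numpy as np
import pytest

from seedtax import cnn
from seedtax import harness as har


TINY = cnn.ArchitectureSpec(conv_filters=(4, 8), dense_widths=(16, 8),
                            dropout_rates=(0.0, 0.0), output_classes=12,
                            input_size=32)


def _tiny_separable(n_per_class=6, n_classes=12, seed=0):
    """32x32 images where a bright block's position encodes the class."""
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    x = rng.random((n, 32, 32)).astype(np.float32) * 0.2
    y = np.repeat(np.arange(n_classes), n_per_class)
    for i, cls in enumerate(y):
        r, c = divmod(int(cls), 4)
        x[i, 10 * r: 10 * r + 8, 8 * c: 8 * c + 8] += 0.7
    return np.clip(x, 0, 1), y


class TestArchitecture:
    def test_default_output_width_and_spatial_size(self):
        spec = cnn.ArchitectureSpec()
        net = cnn.build_network(spec)
        assert spec.spatial_after_conv == 8  # 128 / 2**4
        out = net.forward(np.zeros((2, 128, 128), np.float32))
        assert out.shape == (2, 12)

    def test_parameter_count_matches_closed_form(self):
        spec = cnn.ArchitectureSpec()
        net = cnn.build_network(spec)
        k = spec.conv_kernel
        total, ch = 0, 1
        for f in spec.conv_filters:
            total += k * k * ch * f + f   # conv weights + bias
            total += 2 * f                # batch-norm gamma + beta
            ch = f
        d = spec.spatial_after_conv**2 * ch
        for w in spec.dense_widths:
            total += d * w + w
            d = w
        total += d * spec.output_classes + spec.output_classes
        assert cnn.count_parameters(net) == total

    def test_single_dense_layer_parameter_count(self):
        layer = cnn.Dense(10, 5, np.random.default_rng(0))
        assert sum(p[0].size for p in layer.params) == 55

    def test_dropping_a_conv_stage_reduces_count(self):
        full = cnn.count_parameters(cnn.build_network(cnn.ArchitectureSpec()))
        reduced = cnn.count_parameters(cnn.build_network(
            cnn.ArchitectureSpec(conv_filters=(16, 32, 64), input_size=128)))
        assert reduced < full

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            cnn.ArchitectureSpec(input_size=100)  # not divisible by 2**4
        with pytest.raises(ValueError):
            cnn.ArchitectureSpec(dense_widths=(0, 8))


class TestGradients:
    def test_backprop_matches_numerical_gradients(self):
        spec = cnn.ArchitectureSpec(conv_filters=(2, 3), dense_widths=(4, 5),
                                    dropout_rates=(0.0, 0.0),
                                    output_classes=3, input_size=8)
        net = cnn.build_network(spec, rng_seed=0)
        for layer in net.layers:  # freeze BN running stats for repeatability
            if isinstance(layer, cnn.BatchNorm):
                layer.momentum = 1.0
        rng = np.random.default_rng(1)
        x = rng.random((5, 8, 8, 1)).astype(np.float32)
        y = cnn.one_hot(np.array([0, 1, 2, 0, 1]), 3)
        logits = net.forward(x, train=True)
        _, dl = cnn._loss_and_dlogits(logits, y, "categorical")
        net.zero_grads()
        net.backward(dl)
        eps = 1e-3
        checked = 0
        for p_index, (value, grad) in enumerate(net.params):
            flat, gflat = value.ravel(), grad.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size),
                                replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = cnn._loss_and_dlogits(net.forward(x, True), y,
                                              "categorical")
                flat[i] = orig - eps
                lm, _ = cnn._loss_and_dlogits(net.forward(x, True), y,
                                              "categorical")
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                if abs(numeric) < 1e-4:  # conv bias before BN: exact zero grad
                    continue
                assert gflat[i] == pytest.approx(numeric, rel=0.05, abs=1e-4)
                checked += 1
        assert checked > 20

    def test_binary_loss_gradient_direction(self):
        # both losses must pull logits toward the one-hot target
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(4, 3)).astype(np.float32)
        y = cnn.one_hot(np.array([0, 1, 2, 0]), 3)
        for loss in ("categorical", "binary"):
            _, d = cnn._loss_and_dlogits(logits, y, loss)
            assert ((d * y).sum(axis=1) < 0).all()  # push target logit up


class TestTraining:
    def test_overfits_tiny_separable_set(self):
        x, y = _tiny_separable(n_per_class=2)
        net = cnn.build_network(TINY, rng_seed=0)
        cfg = cnn.TrainConfig(learning_rate=3e-3, max_epochs=60, patience=60,
                              batch_size=12, rng_seed=1)
        model = cnn.train(net, x, cnn.one_hot(y, 12), cfg)
        acc, _ = cnn.evaluate(model, x, y)
        assert acc == 1.0

    def test_loss_trends_down_early(self):
        x, y = _tiny_separable(n_per_class=4)
        net = cnn.build_network(TINY, rng_seed=0)
        cfg = cnn.TrainConfig(learning_rate=1e-3, max_epochs=10, patience=10,
                              batch_size=16, rng_seed=2)
        model = cnn.train(net, x, cnn.one_hot(y, 12), cfg)
        losses = [h["loss"] for h in model.history]
        assert np.isfinite(losses).all()
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_same_seed_reproduces_final_loss(self):
        x, y = _tiny_separable(n_per_class=2)
        finals = []
        for _ in range(2):
            net = cnn.build_network(TINY, rng_seed=3)
            cfg = cnn.TrainConfig(learning_rate=1e-3, max_epochs=5, patience=5,
                                  batch_size=8, rng_seed=4)
            model = cnn.train(net, x, cnn.one_hot(y, 12), cfg)
            finals.append(model.history[-1]["loss"])
        assert finals[0] == finals[1]

    def test_label_width_mismatch_rejected(self):
        x, y = _tiny_separable(n_per_class=2)
        net = cnn.build_network(TINY)
        with pytest.raises(ValueError):
            cnn.train(net, x, cnn.one_hot(y % 5, 5),
                      cnn.TrainConfig(max_epochs=1))

    def test_early_stopping_on_plateau(self):
        x, y = _tiny_separable(n_per_class=2)
        net = cnn.build_network(TINY, rng_seed=0)
        cfg = cnn.TrainConfig(learning_rate=1e-9, max_epochs=500, patience=3,
                              min_delta=1e-3, batch_size=8, rng_seed=0)
        model = cnn.train(net, x, cnn.one_hot(y, 12), cfg)
        assert model.stop_reason == "early-stop"
        assert len(model.history) < 30


class TestSplitAndEvaluate:
    def test_study_size_split(self):
        split = cnn.make_cnn_split(1299, rng_seed=0)
        assert len(split.train_idx) == 974
        assert len(split.test_idx) == 325

    def test_round_split(self):
        split = cnn.make_cnn_split(100, rng_seed=1)
        assert len(split.train_idx) == 75 and len(split.test_idx) == 25

    def test_deterministic_and_exhaustive(self):
        s1 = cnn.make_cnn_split(50, rng_seed=2)
        s2 = cnn.make_cnn_split(50, rng_seed=2)
        assert np.array_equal(s1.train_idx, s2.train_idx)
        assert len(np.union1d(s1.train_idx, s1.test_idx)) == 50

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            cnn.make_cnn_split(3, rng_seed=0)

    def test_probability_outputs_normalized(self):
        net = cnn.build_network(TINY, rng_seed=1)
        x = np.random.default_rng(0).random((10, 32, 32)).astype(np.float32)
        proba = net.predict_proba(x)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-5)
        assert (proba >= 0).all()

    def test_confusion_counts_sum_to_test_size(self):
        net = cnn.build_network(TINY, rng_seed=1)
        x, y = _tiny_separable(n_per_class=3)
        acc, cm = cnn.evaluate(net, x, y)
        assert cm.sum() == len(y)
        assert acc == pytest.approx(np.trace(cm) / cm.sum())


class TestRepetitions:
    def test_summary_consistency_with_harness(self):
        x, y = _tiny_separable(n_per_class=4)
        cfg = cnn.TrainConfig(learning_rate=3e-3, max_epochs=8, patience=8,
                              batch_size=16, rng_seed=0)
        results = cnn.run_cnn_repetitions(x, y, n_rep=2, config=cfg, spec=TINY)
        assert len(results) == 2
        summary = har.summarize_accuracy(results, method="cnn")
        accs = 100 * np.array([r.accuracy for r in results])
        assert summary.min <= summary.median <= summary.max
        assert summary.mean == pytest.approx(accs.mean())
        for r in results:
            assert r.confusion.sum() == 12  # ceil(0.25 * 48)
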