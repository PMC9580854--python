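"""CNN builders, shape oracle, training protocol, evaluation."""

import numpy as np
import pytest

from genimg import (
    ConfigurationError,
    DataError,
    Hyperparams,
    build_1dcnn,
    build_2dcnn,
    evaluate_accuracy,
    output_shapes,
    train,
)
from genimg import models
from genimg import nn


class TestShapeOracle:
    def test_reference_2d_chain(self):
        assert output_shapes(build_2dcnn(24)) == [
            (22, 22, 32),
            (11, 11, 32),
            (9, 9, 64),
            (4, 4, 64),
            (1024,),
            (10,),
            (2,),
        ]

    def test_reference_1d_chain(self):
        assert output_shapes(build_1dcnn(603)) == [
            (601, 32),
            (300, 32),
            (298, 64),
            (149, 64),
            (9536,),
            (10,),
            (2,),
        ]

    def test_too_small_image_names_failing_layer(self):
        with pytest.raises(ConfigurationError, match="conv"):
            build_2dcnn(7)
        with pytest.raises(ConfigurationError):
            build_1dcnn(1)

    def test_oracle_matches_backend_shapes(self):
        rng = np.random.default_rng(0)
        cases = [("2d", int(m)) for m in rng.integers(10, 40, 10)] + [
            ("1d", int(L)) for L in rng.integers(12, 400, 10)
        ]
        for kind, dim in cases:
            spec = build_2dcnn(dim) if kind == "2d" else build_1dcnn(dim)
            net = models.build_network(spec, seed=1)
            x = (
                rng.random((2, dim, dim, 1)).astype(np.float32)
                if kind == "2d"
                else rng.random((2, 1, dim, 1)).astype(np.float32)
            )
            got = []
            h = x
            for layer in net.layers:
                h = layer.forward(h)
                if isinstance(layer, nn.Dropout):
                    continue
                shape = h.shape[1:]
                if kind == "1d" and len(shape) == 3:
                    shape = (shape[1], shape[2])
                got.append(tuple(int(s) for s in shape))
            assert got == output_shapes(spec)

    def test_dense_parameter_count_for_m24(self):
        net = models.build_network(build_2dcnn(24), seed=0)
        dense10 = [l for l in net.layers if isinstance(l, nn.Dense)][0]
        assert dense10.w.size + dense10.b.size == 1024 * 10 + 10

    def test_both_models_end_in_dense_10_head(self):
        for spec in (build_2dcnn(24), build_1dcnn(603)):
            dense_sizes = [d[1] for d in spec.layers if d[0] == "dense"]
            assert dense_sizes == [10, 2]

    def test_degenerate_1xn_equivalence(self):
        # the 1-D net is the height-1 2-D net, so its parameter count equals
        # the closed-form arithmetic of a 2-D net on a 1 x N image
        L = 203
        net = models.build_network(build_1dcnn(L), seed=0)
        shapes = output_shapes(build_1dcnn(L))
        flat = shapes[4][0]
        expect = (3 * 1 * 32 + 32) + (3 * 32 * 64 + 64) + (flat * 10 + 10) + (10 * 2 + 2)
        assert net.n_params() == expect


class TestTraining:
    def _toy(self, n=120, m=12, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        x = rng.random((n, m, m)).astype(np.float32) * 0.2
        x[np.arange(n), 3, 3] = y  # deterministic label patch
        x[np.arange(n), 3, 4] = y
        return x, y

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        # 20 images whose label is written into one patch: the model must
        # fit them perfectly within 50 epochs (accuracy evaluated without
        # dropout noise on the training inputs)
        x, y = self._toy(n=20)
        hp = Hyperparams(epochs=50, batch_size=5, seed=1, validation_fraction=0.0)
        rep = train(build_2dcnn(12), hp, x, y)
        assert evaluate_accuracy(rep.weights, rep.spec, x, y) == 1.0

    def test_shuffled_labels_stay_at_chance(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.random((n, 30)).astype(np.float32)
        y = rng.integers(0, 2, n)  # labels independent of inputs
        hp = Hyperparams(epochs=6, batch_size=100, seed=3, validation_fraction=0.3)
        rep = train(
            build_1dcnn(30), hp, x[:1500], y[:1500],
            test_inputs=x[1500:], test_labels=y[1500:],
        )
        assert abs(rep.test_accuracy - 0.5) < 0.1

    def test_deterministic_history(self):
        x, y = self._toy(n=60)
        hp = Hyperparams(epochs=5, batch_size=20, seed=11)
        a = train(build_2dcnn(12), hp, x, y)
        b = train(build_2dcnn(12), hp, x, y)
        assert a.history["train_acc"] == b.history["train_acc"]
        assert a.history["val_acc"] == b.history["val_acc"]
        assert all(np.array_equal(u, v) for u, v in zip(a.weights, b.weights))

    def test_history_length_equals_epochs(self):
        x, y = self._toy(n=40)
        hp = Hyperparams(epochs=7, batch_size=10, seed=0)
        rep = train(build_2dcnn(12), hp, x, y)
        assert len(rep.history["train_acc"]) == 7
        assert rep.history["epoch"] == list(range(1, 8))

    def test_single_class_rejected(self):
        x, _ = self._toy(n=30)
        with pytest.raises(DataError):
            train(build_2dcnn(12), Hyperparams(epochs=1), x, np.zeros(30, dtype=int))

    def test_unscaled_inputs_rejected(self):
        x, y = self._toy(n=20)
        with pytest.raises(DataError):
            train(build_2dcnn(12), Hyperparams(epochs=1), x * 3.0, y)

    def test_gradients_match_directional_derivative(self):
        # analytic gradients against a finite-difference directional check
        rng = np.random.default_rng(0)
        net = models.build_network(build_1dcnn(16, dropout=0.0), seed=2)
        x = rng.random((32, 1, 16, 1)).astype(np.float32)
        y = np.zeros((32, 2), dtype=np.float32)
        y[np.arange(32), rng.integers(0, 2, 32)] = 1

        def loss():
            p = nn.softmax(net._logits(x)).astype(np.float64)
            return float(-np.mean(np.sum(y * np.log(p + 1e-15), axis=1)))

        l0 = loss()
        net.train_batch(x, y, rng)
        grads = [((l, n), getattr(l, "d" + n).copy()) for l, n in net.param_refs()]
        gn = sum((g**2).sum() for _, g in grads)
        t = 1e-4
        for (layer, name), g in grads:
            setattr(layer, name, getattr(layer, name) - (t * g).astype(np.float32))
        assert (l0 - loss()) / (t * gn) == pytest.approx(1.0, abs=0.02)

    def test_softmax_outputs_sum_to_one(self):
        net = models.build_network(build_2dcnn(12), seed=5)
        x = np.random.default_rng(1).random((7, 12, 12, 1)).astype(np.float32)
        p = net.predict_proba(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()


class TestEvaluate:
    def test_perfect_and_constant_predictors(self):
        spec = build_1dcnn(20, dropout=0.0)
        rng = np.random.default_rng(0)
        x = rng.random((40, 20)).astype(np.float32)
        y = np.repeat([0, 1], 20)
        net = models.build_network(spec, seed=1)
        weights = net.get_weights()
        # constant predictor: zero out the head -> argmax always class 0
        weights_const = [w.copy() for w in weights]
        weights_const[-2][:] = 0
        weights_const[-1][:] = [1.0, 0.0]
        acc = evaluate_accuracy(weights_const, spec, x, y)
        assert acc == 0.5  # balanced labels, constant class-0 prediction

    def test_manual_tally_on_four_samples(self):
        spec = build_1dcnn(12, dropout=0.0)
        net = models.build_network(spec, seed=3)
        x = np.random.default_rng(2).random((4, 12)).astype(np.float32)
        y = np.array([0, 1, 0, 1])
        pred = net.predict_proba(x[:, None, :, None]).argmax(axis=1)
        expect = float(np.mean(pred == y))
        assert evaluate_accuracy(net.get_weights(), spec, x, y) == expect

    def test_shape_mismatch_rejected(self):
        spec = build_1dcnn(12)
        net = models.build_network(spec, seed=0)
        with pytest.raises(DataError):
            evaluate_accuracy(net.get_weights(), spec, np.zeros((2, 9)), [0, 1])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        x = rng.random((30, 12)).astype(np.float32)
        y = rng.integers(0, 2, 30)
        y[:15] = 0
        y[15:] = 1
        hp = Hyperparams(epochs=2, batch_size=10, seed=4)
        rep = train(build_1dcnn(12), hp, x, y)
        path = tmp_path / "m.npz"
        models.save_report(rep, path)
        back = models.load_report(path)
        assert back.fingerprint == rep.fingerprint
        assert back.history == rep.history
        assert all(np.array_equal(a, b) for a, b in zip(back.weights, rep.weights))
        assert evaluate_accuracy(back.weights, back.spec, x, y) == evaluate_accuracy(
            rep.weights, rep.spec, x, y
        )
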