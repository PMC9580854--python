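"""Experiment orchestration, similarity trace, saliency, filter gallery."""

import numpy as np
import pytest

from genimg import (
    DataError,
    ExperimentConfig,
    Hyperparams,
    SimConfig,
    build_1dcnn,
    build_2dcnn,
    classification_region_map,
    evaluate_accuracy,
    filter_gallery,
    penultimate_cosine_trace,
    run_iterations,
    train,
)
from genimg import models
from genimg.experiment import _cosine
from genimg.models import TrainReport


@pytest.fixture(scope="module")
def tiny_results():
    cfg = ExperimentConfig(
        sim=SimConfig(n_samples=400, n_snps=250, n_causal=3, heritability=0.8, seed=5),
        thresholds=(1.0, 1e-4),
        encodings=("E1",),
        models=("2d", "1d"),
        n_iterations=2,
        base_seed=2,
        hyperparams=Hyperparams(epochs=2, seed=0),
    )
    return cfg, run_iterations(cfg)


class TestRunIterations:
    def test_summary_means_match_per_iteration_rows(self, tiny_results):
        _, res = tiny_results
        for _, row in res.summary.iterrows():
            sub = res.per_iteration[
                (res.per_iteration["threshold"] == row["threshold"])
                & (res.per_iteration["encoding"] == row["encoding"])
                & (res.per_iteration["model"] == row["model"])
            ]
            assert row["n_runs"] == len(sub)
            assert row["test_acc"] == pytest.approx(sub["test_acc"].mean())
            assert row["train_acc"] == pytest.approx(sub["train_acc"].mean())

    def test_each_cell_has_requested_iterations(self, tiny_results):
        cfg, res = tiny_results
        ok_cells = res.summary[["threshold", "encoding", "model"]].values
        for thr, enc, model in ok_cells:
            sub = res.per_iteration[
                (res.per_iteration["threshold"] == thr)
                & (res.per_iteration["encoding"] == enc)
                & (res.per_iteration["model"] == model)
            ]
            assert sorted(sub["iteration"]) == list(range(cfg.n_iterations))

    def test_failures_recorded_not_raised(self):
        # a threshold below any attainable p-value must yield recorded
        # failures, not an exception
        cfg = ExperimentConfig(
            sim=SimConfig(n_samples=120, n_snps=64, n_causal=2, heritability=0.6, seed=8),
            thresholds=(1e-300,),
            encodings=("E1",),
            models=("2d",),
            n_iterations=1,
            hyperparams=Hyperparams(epochs=1, seed=0),
        )
        res = run_iterations(cfg)
        assert len(res.per_iteration) == 0
        assert len(res.failures) == 1
        assert "threshold" in res.failures.iloc[0]["reason"]

    def test_evaluation_invariant_to_test_row_permutation(self):
        # accuracy is a per-sample mean: permuting the held-out rows cannot
        # change any reported cell
        rng = np.random.default_rng(0)
        x = rng.random((40, 20)).astype(np.float32)
        y = rng.integers(0, 2, 40)
        spec = build_1dcnn(20, dropout=0.0)
        w = models.build_network(spec, seed=1).get_weights()
        perm = rng.permutation(40)
        assert evaluate_accuracy(w, spec, x, y) == evaluate_accuracy(
            w, spec, x[perm], y[perm]
        )


class TestCosineTrace:
    def test_cosine_identities(self):
        a = np.array([1.0, 2.0, 3.0])
        assert _cosine(a, a) == pytest.approx(1.0)
        assert _cosine(a, -a) == pytest.approx(-1.0)
        assert _cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert _cosine(a, np.zeros(3)) == 0.0

    def test_head_weight_shape_and_trace_length(self):
        rng = np.random.default_rng(1)
        x1 = rng.random((60, 20)).astype(np.float32)
        y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
        hp = Hyperparams(epochs=3, batch_size=20, seed=2)
        frozen = train(build_1dcnn(20), hp, x1, y)
        assert models.head_weight(frozen).shape == (10, 2)

        x2 = rng.random((60, 12, 12)).astype(np.float32)
        trace = penultimate_cosine_trace(frozen, build_2dcnn(12), hp, x2, y)
        assert trace.values.shape == (3,)
        assert (np.abs(trace.values) <= 1.0).all()

    def test_identical_heads_give_similarity_one(self):
        rng = np.random.default_rng(3)
        x = rng.random((40, 20)).astype(np.float32)
        y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        hp = Hyperparams(epochs=2, batch_size=20, seed=5)
        rep = train(build_1dcnn(20), hp, x, y)
        w = models.head_weight(rep).ravel()
        assert _cosine(w, w.copy()) == pytest.approx(1.0)


class TestSaliency:
    def _handmade_report(self, m=12):
        """Weights routing exactly one bright pixel to the class-1 logit."""
        spec = build_2dcnn(m, dropout=0.0)
        net = models.build_network(spec, seed=0)
        weights = [np.zeros_like(w) for w in net.get_weights()]
        weights[0][1, 1, 0, 0] = 1.0  # conv1 filter 0: center tap
        weights[2][1, 1, 0, 0] = 1.0  # conv2 filter 0: center tap, channel 0
        weights[4][:, 0] = 1.0  # dense(10): sum features into unit 0
        weights[6][0, 1] = 1.0  # head: unit 0 -> class-1 logit
        return TrainReport(
            spec=spec, training_accuracy=1.0, validation_accuracy=None,
            test_accuracy=None, history={}, weights=weights, seed=0,
            fingerprint=spec.fingerprint,
        )

    def test_single_pixel_toy_model_peaks_at_that_pixel(self):
        report = self._handmade_report()
        img = np.zeros((12, 12), dtype=np.float32)
        img[5, 5] = 1.0
        sal = classification_region_map(report, img)
        assert sal.shape == (12, 12)
        assert sal[5, 5] == 1.0
        assert sal.argmax() == 5 * 12 + 5

    def test_values_in_unit_interval(self, tiny_results):
        _, res = tiny_results
        # train a real (tiny) model and check the map range
        rng = np.random.default_rng(0)
        x = rng.random((30, 12, 12)).astype(np.float32)
        y = np.r_[np.zeros(15, dtype=int), np.ones(15, dtype=int)]
        rep = train(build_2dcnn(12), Hyperparams(epochs=2, batch_size=10, seed=1), x, y)
        sal = classification_region_map(rep, x[0])
        assert sal.min() >= 0.0 and sal.max() <= 1.0

    def test_constant_model_yields_all_zero_map(self):
        report = self._handmade_report()
        for w in report.weights:
            w[:] = 0
        sal = classification_region_map(report, np.zeros((12, 12), dtype=np.float32))
        assert not sal.any()

    def test_wrong_image_shape_rejected(self):
        report = self._handmade_report()
        with pytest.raises(DataError):
            classification_region_map(report, np.zeros((9, 9), dtype=np.float32))


class TestFilterGallery:
    def _report(self):
        rng = np.random.default_rng(2)
        x = rng.random((20, 12, 12)).astype(np.float32)
        y = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        return train(build_2dcnn(12), Hyperparams(epochs=1, batch_size=10, seed=3), x, y)

    def test_grid_holds_32_three_by_three_tiles(self):
        rep = self._report()
        grid = filter_gallery(rep, tiles_per_row=8, pad=1)
        # 4 rows x 8 cols of 3x3 tiles with 1-px separators
        assert grid.shape == (4 * 4 - 1, 8 * 4 - 1)
        assert grid.dtype == np.uint8

    def test_normalization_spans_full_range(self):
        rep = self._report()
        grid = filter_gallery(rep)
        assert grid.max() == 255

    def test_deterministic_given_weights(self):
        rep = self._report()
        assert np.array_equal(filter_gallery(rep), filter_gallery(rep))
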