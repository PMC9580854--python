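"""End-to-end repeated-iteration experiments and model inspection.

``run_iterations`` drives the full pipeline — simulate (or reuse) a cohort,
stratified 80/20 split, Fisher GWAS on the training side only, p-value
preselection, image/sequence encoding, CNN training — over several
iterations, re-drawing the split, the liability noise and the weight
initialization from ``base_seed + iteration`` while keeping the genetic
architecture (causal SNPs and effects) fixed. Results are reported as
per-cell means over iterations plus the per-iteration raw rows.

Also here: the per-epoch cosine-similarity trace between the two models'
dense(10)->dense(2) weight blocks, gradient saliency maps ("classification
region" visualization) and first-layer filter galleries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image

from . import imaging, models
from .association import gwas_scan, select_snps
from .datatypes import GenotypeDataset, SimConfig
from .errors import DataError, GenimgError
from .io import stratified_split
from .simulate import binarize_phenotype, simulate_cohort, simulate_phenotype
from .models import Hyperparams, TrainReport

__all__ = [
    "ExperimentConfig",
    "ResultsTable",
    "SimilarityTrace",
    "run_iterations",
    "penultimate_cosine_trace",
    "classification_region_map",
    "filter_gallery",
]

#: the four operating points used throughout the results tables
DEFAULT_THRESHOLDS = (1.0, 5.05915e-10, 5.05915e-30, 5.05915e-50)

Cell = Tuple[float, str, str]  # (threshold, encoding or "seq", model)


@dataclass
class ExperimentConfig:
    """Grid and protocol of a repeated-iteration experiment.

    ``cells`` restricts the (threshold, encoding, model) grid to an explicit
    subset; if None, the full product of ``thresholds`` x ``encodings`` (2-D
    models) plus ``thresholds`` ("seq") for the 1-D model is run.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Tuple[float, ...] = DEFAULT_THRESHOLDS
    encodings: Tuple[str, ...] = ("E1", "E2")
    models: Tuple[str, ...] = ("2d", "1d")
    n_iterations: int = 5
    base_seed: int = 0
    train_fraction: float = 0.8
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    cells: Optional[Sequence[Cell]] = None

    def __post_init__(self):
        if self.n_iterations < 1:
            raise DataError("n_iterations must be >= 1")
        if not self.thresholds:
            raise DataError("thresholds must be non-empty")

    def grid(self) -> List[Cell]:
        if self.cells is not None:
            return [tuple(c) for c in self.cells]
        out: List[Cell] = []
        for t in self.thresholds:
            if "2d" in self.models:
                out.extend((t, e, "2d") for e in self.encodings)
            if "1d" in self.models:
                out.append((t, "seq", "1d"))
        return out


@dataclass
class ResultsTable:
    """Iteration-averaged accuracies per (threshold, encoding, model) cell."""

    summary: pd.DataFrame
    per_iteration: pd.DataFrame
    failures: pd.DataFrame

    def cell(self, threshold: float, encoding: str, model: str) -> pd.Series:
        s = self.summary
        row = s[
            np.isclose(s["threshold"], threshold)
            & (s["encoding"] == encoding)
            & (s["model"] == model)
        ]
        if len(row) != 1:
            raise KeyError((threshold, encoding, model))
        return row.iloc[0]


@dataclass
class SimilarityTrace:
    """Per-epoch cosine similarity of the two models' output-head weights."""

    values: np.ndarray
    epochs: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.epochs,):
            raise DataError("trace length must equal the number of epochs")


def _prepare_cell_inputs(
    cell: Cell, train_sel: GenotypeDataset, test_sel: GenotypeDataset
):
    """Encode a selected SNP set for one cell; returns (x_train, x_test, spec_builder_arg)."""
    _, encoding, model = cell
    if model == "1d":
        xtr = imaging.to_network_input(imaging.flatten_for_1d(train_sel))
        xte = imaging.to_network_input(imaging.flatten_for_1d(test_sel))
        return xtr, xte, xtr.shape[1]
    stack_tr = imaging.encode(train_sel, encoding)
    stack_te = imaging.encode(test_sel, encoding)
    return (
        imaging.to_network_input(stack_tr),
        imaging.to_network_input(stack_te),
        stack_tr.side,
    )


def run_iterations(
    config: ExperimentConfig,
    dataset: Optional[GenotypeDataset] = None,
    jsonl_path: Optional[Union[str, Path]] = None,
) -> ResultsTable:
    """Run the full pipeline for every grid cell over repeated iterations.

    If ``dataset`` is given it is used as the cohort and only the split and
    model seeds are re-drawn per iteration; otherwise the cohort genotypes
    and genetic architecture come from ``config.sim`` and the liability
    noise is additionally re-drawn per iteration (so case/control labels,
    and hence the surviving SNP count, vary between iterations as they do
    between full re-runs of the pipeline).

    A failing cell (e.g. no SNP survives, or the image is too small for the
    conv stack) is recorded in ``failures`` with its reason and skipped.
    """
    rows: List[dict] = []
    failures: List[dict] = []
    base_cohort = dataset if dataset is not None else simulate_cohort(config.sim)

    for it in range(config.n_iterations):
        seed_i = config.base_seed + it
        cohort = base_cohort
        if dataset is None and config.sim.heritability < 1.0:
            liab, causal = simulate_phenotype(
                base_cohort,
                config.sim.n_causal,
                config.sim.heritability,
                seed=config.sim.seed,
                noise_seed=seed_i,
            )
            cohort = base_cohort.replace(
                phenotype=binarize_phenotype(liab),
                liability=liab,
                causal_index=causal,
            )
        split = stratified_split(cohort, config.train_fraction, seed=seed_i)
        assoc = gwas_scan(split.train)
        for threshold in sorted({c[0] for c in config.grid()}, reverse=True):
            cells_here = [c for c in config.grid() if c[0] == threshold]
            try:
                train_sel = select_snps(assoc, split.train, threshold)
                test_sel = select_snps(assoc, split.test, threshold)
            except GenimgError as e:
                for cell in cells_here:
                    failures.append(
                        {"iteration": it, "threshold": threshold,
                         "encoding": cell[1], "model": cell[2], "reason": str(e)}
                    )
                continue
            n_sel = train_sel.n_snps
            for cell in cells_here:
                _, encoding, model = cell
                try:
                    xtr, xte, dim = _prepare_cell_inputs(cell, train_sel, test_sel)
                    spec = (
                        models.build_1dcnn(dim, dropout=config.hyperparams.dropout)
                        if model == "1d"
                        else models.build_2dcnn(dim, dropout=config.hyperparams.dropout)
                    )
                    hp = replace(config.hyperparams, seed=seed_i)
                    report = models.train(
                        spec, hp, xtr, split.train.phenotype,
                        test_inputs=xte, test_labels=split.test.phenotype,
                    )
                except GenimgError as e:
                    failures.append(
                        {"iteration": it, "threshold": threshold,
                         "encoding": encoding, "model": model, "reason": str(e)}
                    )
                    continue
                row = {
                    "iteration": it,
                    "threshold": threshold,
                    "encoding": encoding,
                    "model": model,
                    "n_snps_selected": n_sel,
                    "train_acc": report.training_accuracy,
                    "val_acc": report.validation_accuracy,
                    "test_acc": report.test_accuracy,
                    "seed": seed_i,
                }
                rows.append(row)
                if jsonl_path is not None:
                    import json

                    with open(jsonl_path, "a") as fh:
                        fh.write(json.dumps(row) + "\n")

    per_it = pd.DataFrame(rows)
    if len(per_it):
        summary = (
            per_it.groupby(["threshold", "encoding", "model"], as_index=False)
            .agg(
                train_acc=("train_acc", "mean"),
                val_acc=("val_acc", "mean"),
                test_acc=("test_acc", "mean"),
                test_acc_std=("test_acc", "std"),
                n_snps_selected=("n_snps_selected", "mean"),
                n_runs=("iteration", "count"),
            )
            .sort_values("threshold", ascending=False, kind="stable")
            .reset_index(drop=True)
        )
    else:
        summary = pd.DataFrame(
            columns=["threshold", "encoding", "model", "train_acc", "val_acc",
                     "test_acc", "test_acc_std", "n_snps_selected", "n_runs"]
        )
    return ResultsTable(
        summary=summary,
        per_iteration=per_it,
        failures=pd.DataFrame(
            failures, columns=["iteration", "threshold", "encoding", "model", "reason"]
        ),
    )


def penultimate_cosine_trace(
    frozen_1d: TrainReport,
    spec_2d: models.CNNSpec,
    hyperparams: Hyperparams,
    inputs: np.ndarray,
    labels: np.ndarray,
) -> SimilarityTrace:
    """Cosine similarity between output-head weight blocks, per 2-D epoch.

    The 1-D model is already trained and frozen; the 2-D model is trained
    from scratch and after every epoch the flattened dense(10)->dense(2)
    weight matrices (biases excluded) are compared.
    """
    w1 = models.head_weight(frozen_1d).ravel().astype(np.float64)
    head_2d_shape = None
    for desc in spec_2d.layers:
        if desc[0] == "dense":
            head_2d_shape = desc[1]
    values: List[float] = []

    def cb(net, epoch):
        w2 = models.head_weight(net.get_weights()).ravel().astype(np.float64)
        if w2.shape != w1.shape:
            raise DataError(
                f"head shape mismatch: 1d {w1.shape} vs 2d {w2.shape}"
            )
        values.append(_cosine(w1, w2))

    models.train(spec_2d, hyperparams, inputs, labels, epoch_callback=cb)
    return SimilarityTrace(values=np.array(values), epochs=hyperparams.epochs)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def classification_region_map(
    report: TrainReport,
    image: np.ndarray,
    out_png: Optional[Union[str, Path]] = None,
) -> np.ndarray:
    """Gradient saliency of the predicted class, min-max scaled to [0, 1].

    ``image`` is a single M x M network-input image (already in [0, 1]).
    The map is |d logit_pred / d pixel|; a constant-output model yields an
    all-zero map rather than 0/0.
    """
    if report.weights is None or not len(report.weights):
        raise DataError("model has no trained weights")
    spec = report.spec
    net = models.build_network(spec, seed=0)
    net.set_weights(report.weights)
    x = np.asarray(image, dtype=np.float32)
    if spec.dimensionality == 2:
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:
            x = x[None, ...]
        if x.shape[1:3] != spec.input_shape[:2]:
            raise DataError(
                f"image shape {x.shape[1:3]} does not match model input "
                f"{spec.input_shape[:2]}"
            )
    else:
        x = x.reshape(1, 1, -1, 1)
        if x.shape[2] != spec.input_shape[0]:
            raise DataError("sequence length does not match model input")
    pred = int(net.predict_proba(x).argmax(axis=1)[0])
    grad = net.input_gradient(x, pred)
    sal = np.abs(grad[0, ..., 0])
    if spec.dimensionality == 1:
        sal = sal[0]
    lo, hi = sal.min(), sal.max()
    sal = np.zeros_like(sal) if hi == lo else (sal - lo) / (hi - lo)
    if out_png is not None:
        Image.fromarray((sal * 255).astype(np.uint8), mode="L").save(out_png)
    return sal


def filter_gallery(
    report: TrainReport,
    out_png: Optional[Union[str, Path]] = None,
    tiles_per_row: int = 8,
    pad: int = 1,
) -> np.ndarray:
    """First-layer kernels as grayscale tiles (each scaled min->0, max->255).

    Returns the assembled uint8 grid; deterministic given the weights.
    """
    w = report.weights[0]  # (kh, kw, 1, F)
    if w.ndim != 4:
        raise DataError("first weight tensor is not a conv kernel")
    kh, kw, _, f = w.shape
    tiles = []
    for k in range(f):
        t = w[:, :, 0, k].astype(np.float64)
        lo, hi = t.min(), t.max()
        t = np.zeros_like(t) if hi == lo else (t - lo) / (hi - lo)
        tiles.append((t * 255).astype(np.uint8))
    rows = int(np.ceil(f / tiles_per_row))
    grid = np.zeros(
        (rows * (kh + pad) - pad, tiles_per_row * (kw + pad) - pad), dtype=np.uint8
    )
    for k, t in enumerate(tiles):
        r, c = divmod(k, tiles_per_row)
        grid[r * (kh + pad) : r * (kh + pad) + kh,
             c * (kw + pad) : c * (kw + pad) + kw] = t
    if out_png is not None:
        Image.fromarray(grid, mode="L").save(out_png)
    return grid
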