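"""The two classifier architectures and their training protocol.

The 2-D model is the fixed stack

    conv(32, 3x3) -> maxpool(2x2) -> conv(64, 3x3) -> maxpool(2x2)
    -> flatten -> dense(10, relu) -> dropout(0.3) -> dense(2) -> softmax

on an M x M x 1 genotype image; the 1-D counterpart mirrors it with
kernel/pool sizes 3 and 2 on a length-L dosage sequence, so the two differ
only in dimensionality (a 2-D net on 1 x N input with 1 x 3 kernels has
exactly the same parameter count as the 1-D net on length N).

Training follows one protocol for every model: batches of 100, Adam at
1e-3, binary cross-entropy on the 2-way softmax, a 30% stratified
validation split (the last-listed fraction of each class), a fixed number
of epochs with no early stopping, and accuracy as the metric. Training
accuracy is the running mean over the epoch's batches; validation accuracy
is evaluated at each epoch end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .errors import ConfigurationError, DataError

__all__ = [
    "CNNSpec",
    "Hyperparams",
    "TrainReport",
    "build_2dcnn",
    "build_1dcnn",
    "build_network",
    "output_shapes",
    "train",
    "evaluate_accuracy",
    "head_weight",
    "save_report",
    "load_report",
]

LayerDesc = Tuple


@dataclass(frozen=True)
class CNNSpec:
    """Declarative layer list; ``dimensionality`` is 1 or 2."""

    dimensionality: int
    layers: Tuple[LayerDesc, ...]
    input_shape: Tuple[int, ...]

    @property
    def fingerprint(self) -> str:
        return f"{self.dimensionality}d|{self.input_shape}|" + ";".join(
            ",".join(str(p) for p in l) for l in self.layers
        )


@dataclass
class Hyperparams:
    """The shared training protocol (see module docstring)."""

    batch_size: int = 100
    epochs: int = 50
    validation_fraction: float = 0.3
    learning_rate: float = 0.001
    dropout: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ConfigurationError("validation_fraction must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be positive")


@dataclass
class TrainReport:
    """Final accuracies, per-epoch history and the trained weights."""

    spec: CNNSpec
    training_accuracy: float
    validation_accuracy: Optional[float]
    test_accuracy: Optional[float]
    history: dict
    weights: List[np.ndarray]
    seed: int
    fingerprint: str


def _spec_layers(dropout: float) -> Tuple[LayerDesc, ...]:
    return (
        ("conv", 32, 3),
        ("maxpool", 2),
        ("conv", 64, 3),
        ("maxpool", 2),
        ("flatten",),
        ("dense", 10),
        ("dropout", dropout),
        ("dense", 2),
        ("softmax",),
    )


def build_2dcnn(m: int, dropout: float = 0.3, global_average: bool = False) -> CNNSpec:
    """Spec for the 2-D classifier on an M x M x 1 image (M >= 10).

    ``global_average`` swaps the flatten for global average pooling (an
    off-by-default variant); the canonical stack flattens.
    """
    layers = _spec_layers(dropout)
    if global_average:
        layers = tuple(("gap",) if l == ("flatten",) else l for l in layers)
    spec = CNNSpec(dimensionality=2, layers=layers, input_shape=(m, m, 1))
    output_shapes(spec)  # raises naming the failing layer if M is too small
    return spec


def build_1dcnn(length: int, dropout: float = 0.3, global_average: bool = False) -> CNNSpec:
    """Spec for the mirrored 1-D classifier on a length-L sequence (L >= 12)."""
    layers = _spec_layers(dropout)
    if global_average:
        layers = tuple(("gap",) if l == ("flatten",) else l for l in layers)
    spec = CNNSpec(dimensionality=1, layers=layers, input_shape=(length, 1))
    output_shapes(spec)
    return spec


def output_shapes(spec: CNNSpec) -> List[Tuple[int, ...]]:
    """Closed-form per-layer output shapes (no ML backend involved).

    Valid convolution: extent -> extent - k + 1; pooling: floor(extent / p).
    Raises :class:`ConfigurationError` naming the first failing layer.
    """
    if spec.dimensionality == 2:
        shape = spec.input_shape
    else:
        shape = (1, spec.input_shape[0], spec.input_shape[1])
    shapes: List[Tuple[int, ...]] = []
    for desc in spec.layers:
        kind = desc[0]
        if kind == "conv":
            _, f, k = desc
            kh = 1 if spec.dimensionality == 1 else k
            shape = (shape[0] - kh + 1, shape[1] - k + 1, f)
            if min(shape[:2]) < 1:
                raise ConfigurationError(
                    f"layer conv({f},{k}) has non-positive output extent "
                    f"for input {spec.input_shape}"
                )
        elif kind == "maxpool":
            p = desc[1]
            ph = 1 if spec.dimensionality == 1 else p
            shape = (shape[0] // ph, shape[1] // p, shape[2])
            if min(shape[:2]) < 1:
                raise ConfigurationError(
                    f"layer maxpool({p}) has non-positive output extent "
                    f"for input {spec.input_shape}"
                )
        elif kind in ("flatten", "gap"):
            shape = (
                (int(np.prod(shape)),) if kind == "flatten" else (shape[2],)
            )
        elif kind == "dense":
            shape = (desc[1],)
        elif kind in ("dropout", "softmax"):
            pass
        else:
            raise ConfigurationError(f"unknown layer kind {kind!r}")
        if kind not in ("dropout", "softmax"):
            if spec.dimensionality == 1 and len(shape) == 3:
                shapes.append((shape[1], shape[2]))
            else:
                shapes.append(shape)
    return shapes


def build_network(spec: CNNSpec, seed: int = 0) -> nn.Network:
    """Instantiate and initialize the backing network for a spec."""
    two_d = spec.dimensionality == 2
    layers: List[nn._Layer] = []
    for desc in spec.layers:
        kind = desc[0]
        if kind == "conv":
            _, f, k = desc
            layers.append(nn.Conv2D(f, (k, k) if two_d else (1, k), relu=True))
        elif kind == "maxpool":
            p = desc[1]
            layers.append(nn.MaxPool2D((p, p) if two_d else (1, p)))
        elif kind == "flatten":
            layers.append(nn.Flatten())
        elif kind == "gap":
            layers.append(nn.GlobalAveragePool2D())
        elif kind == "dense":
            u = desc[1]
            # dense(10) carries the stated ReLU; the 2-logit head does not
            layers.append(nn.Dense(u, relu=(u != 2)))
        elif kind == "dropout":
            layers.append(nn.Dropout(desc[1]))
        elif kind == "softmax":
            pass  # applied by the Network head
        else:
            raise ConfigurationError(f"unknown layer kind {kind!r}")
    if two_d:
        input_shape = spec.input_shape
    else:
        input_shape = (1, spec.input_shape[0], spec.input_shape[1])
    return nn.Network(layers, input_shape).build(seed=seed)


def _prepare_xy(spec: CNNSpec, x: np.ndarray, y: np.ndarray):
    x = np.asarray(x, dtype=np.float32)
    if x.size and (x.min() < -1e-6 or x.max() > 1 + 1e-6):
        raise DataError("network inputs must be scaled to [0, 1]")
    if spec.dimensionality == 2:
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:] != spec.input_shape:
            raise DataError(f"input shape {x.shape[1:]} != spec {spec.input_shape}")
    else:
        if x.ndim == 2:
            x = x[:, None, :, None]
        elif x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2] != spec.input_shape[0]:
            raise DataError(
                f"sequence length {x.shape[2]} != spec {spec.input_shape[0]}"
            )
    y = np.asarray(y)
    if y.ndim == 1:
        labels = y.astype(np.int64)
        onehot = np.zeros((len(y), 2), dtype=np.float32)
        onehot[np.arange(len(y)), labels] = 1.0
    else:
        onehot = y.astype(np.float32)
        labels = onehot.argmax(axis=1)
    if len(x) != len(onehot):
        raise DataError("inputs and labels differ in length")
    return x, onehot, labels


def _stratified_tail_split(labels: np.ndarray, fraction: float):
    """Validation = the last-listed ``fraction`` of each class."""
    val = np.zeros(len(labels), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_val = int(np.floor(idx.size * fraction + 0.5))
        if n_val:
            val[idx[-n_val:]] = True
    return ~val, val


def train(
    spec: CNNSpec,
    hyperparams: Hyperparams,
    inputs: np.ndarray,
    labels: np.ndarray,
    test_inputs: Optional[np.ndarray] = None,
    test_labels: Optional[np.ndarray] = None,
    epoch_callback: Optional[Callable[[nn.Network, int], None]] = None,
) -> TrainReport:
    """Train a spec'd model under the shared protocol; fully seeded.

    ``inputs`` must already be scaled to [0, 1]; ``labels`` may be 0/1
    integers or one-hot rows. Runs exactly ``hyperparams.epochs`` epochs.
    """
    hp = hyperparams
    x, onehot, lab = _prepare_xy(spec, inputs, labels)
    if len(np.unique(lab)) < 2:
        raise DataError("training set must contain both classes")
    fit_mask, val_mask = _stratified_tail_split(lab, hp.validation_fraction)
    x_fit, y_fit = x[fit_mask], onehot[fit_mask]
    x_val, y_val = x[val_mask], lab[val_mask]
    if len(x_fit) == 0:
        raise DataError("validation split leaves no training samples")

    net = build_network(spec, seed=hp.seed)
    opt = nn.Adam(net, lr=hp.learning_rate)
    shuffle_rng = np.random.default_rng([hp.seed, 707])
    dropout_rng = np.random.default_rng([hp.seed, 808])

    hist = {"epoch": [], "train_acc": [], "val_acc": [], "loss": []}
    n = len(x_fit)
    for epoch in range(hp.epochs):
        order = shuffle_rng.permutation(n)
        seen = correct = 0
        loss_sum = 0.0
        for s in range(0, n, hp.batch_size):
            sel = order[s : s + hp.batch_size]
            loss, acc = net.train_batch(x_fit[sel], y_fit[sel], dropout_rng)
            opt.step()
            seen += len(sel)
            correct += acc * len(sel)
            loss_sum += loss * len(sel)
        train_acc = correct / seen
        if len(x_val):
            val_pred = net.predict_proba(x_val).argmax(axis=1)
            val_acc = float(np.mean(val_pred == y_val))
        else:
            val_acc = float("nan")
        hist["epoch"].append(epoch + 1)
        hist["train_acc"].append(float(train_acc))
        hist["val_acc"].append(val_acc)
        hist["loss"].append(loss_sum / seen)
        if epoch_callback is not None:
            epoch_callback(net, epoch)

    weights = net.get_weights()
    test_acc = None
    if test_inputs is not None and test_labels is not None:
        test_acc = evaluate_accuracy(weights, spec, test_inputs, test_labels)
    return TrainReport(
        spec=spec,
        training_accuracy=float(hist["train_acc"][-1]),
        validation_accuracy=None if not len(x_val) else float(hist["val_acc"][-1]),
        test_accuracy=test_acc,
        history=hist,
        weights=weights,
        seed=hp.seed,
        fingerprint=spec.fingerprint,
    )


def evaluate_accuracy(
    weights: Sequence[np.ndarray],
    spec: CNNSpec,
    inputs: np.ndarray,
    labels: np.ndarray,
) -> float:
    """Fraction of argmax-softmax predictions matching the labels."""
    x, _, lab = _prepare_xy(spec, inputs, labels)
    net = build_network(spec, seed=0)
    net.set_weights(list(weights))
    pred = net.predict_proba(x).argmax(axis=1)
    return float(np.mean(pred == lab))


def head_weight(report_or_weights) -> np.ndarray:
    """The dense(10) -> dense(2) weight matrix (bias excluded).

    This is the only weight tensor with identical shape in the 1-D and 2-D
    models, hence the block compared across models.
    """
    weights = (
        report_or_weights.weights
        if isinstance(report_or_weights, TrainReport)
        else list(report_or_weights)
    )
    w = weights[-2]  # final dense W (its bias is weights[-1])
    if w.ndim != 2 or w.shape[1] != 2:
        raise DataError(f"unexpected head shape {w.shape}; expected (*, 2)")
    return w


def save_report(report: TrainReport, path: Union[str, Path]) -> None:
    """Persist weights + history + metadata as a single .npz checkpoint."""
    meta = {
        "dimensionality": report.spec.dimensionality,
        "layers": report.spec.layers,
        "input_shape": report.spec.input_shape,
        "training_accuracy": report.training_accuracy,
        "validation_accuracy": report.validation_accuracy,
        "test_accuracy": report.test_accuracy,
        "seed": report.seed,
        "fingerprint": report.fingerprint,
        "history": report.history,
    }
    arrays = {f"w{k}": w for k, w in enumerate(report.weights)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_report(path: Union[str, Path]) -> TrainReport:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        weights = [z[f"w{k}"] for k in range(len(z.files) - 1)]
    spec = CNNSpec(
        dimensionality=meta["dimensionality"],
        layers=tuple(tuple(l) for l in meta["layers"]),
        input_shape=tuple(meta["input_shape"]),
    )
    return TrainReport(
        spec=spec,
        training_accuracy=meta["training_accuracy"],
        validation_accuracy=meta["validation_accuracy"],
        test_accuracy=meta["test_accuracy"],
        history=meta["history"],
        weights=weights,
        seed=meta["seed"],
        fingerprint=meta["fingerprint"],
    )
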