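"""Minimal deterministic CNN engine in NumPy.

Implements exactly what the classifier stacks need: valid 2-D convolution
(stride 1), max pooling (stride = pool size), flatten, dense, inverted
dropout, a softmax head with (binary) cross-entropy, and Adam. One-dim
convolution is the height-1 special case of the 2-D path, so both model
families share a single code path.

Everything is float32 and driven by explicit ``numpy.random.Generator``
instances, so a fixed seed reproduces training bit for bit on any machine
with the same BLAS reduction order (single-threaded runs are exact).
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, DataError

__all__ = ["Network", "Adam", "glorot_uniform", "softmax"]


def glorot_uniform(
    rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int, fan_out: int
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Layer:
    params: List[str] = []

    def init(self, rng: np.random.Generator, in_shape: Tuple[int, ...]) -> Tuple[int, ...]:
        raise NotImplementedError

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2D(_Layer):
    """Valid convolution, stride 1, optional ReLU. Weight: (kh, kw, cin, f)."""

    params = ["w", "b"]

    def __init__(self, filters: int, kernel: Tuple[int, int], relu: bool = True):
        self.filters = filters
        self.kernel = tuple(kernel)
        self.relu = relu

    def init(self, rng, in_shape):
        h, w, c = in_shape
        kh, kw = self.kernel
        ho, wo = h - kh + 1, w - kw + 1
        if ho < 1 or wo < 1:
            raise ConfigurationError(
                f"conv({self.filters}, {self.kernel}) on input {in_shape}: "
                "non-positive output extent"
            )
        self.w = glorot_uniform(
            rng, (kh, kw, c, self.filters), kh * kw * c, kh * kw * self.filters
        )
        self.b = np.zeros(self.filters, dtype=np.float32)
        self.in_shape = in_shape
        return (ho, wo, self.filters)

    def _wmat(self):
        kh, kw, c, f = self.w.shape
        return self.w.reshape(kh * kw * c, f)

    def _im2col(self, x):
        # column layout (kh, kw, C) matches w.reshape(kh*kw*C, F)
        kh, kw = self.kernel
        c = self.in_shape[2]
        b_ = x.shape[0]
        ho = self.in_shape[0] - kh + 1
        wo = self.in_shape[1] - kw + 1
        cols = np.empty((b_, ho, wo, kh * kw * c), dtype=np.float32)
        k = 0
        for i in range(kh):
            for j in range(kw):
                cols[..., k * c : (k + 1) * c] = x[:, i : i + ho, j : j + wo, :]
                k += 1
        return cols

    def forward(self, x, training=False, rng=None):
        cols = self._im2col(x)
        out = cols.reshape(-1, cols.shape[-1]) @ self._wmat()
        out = out.reshape(cols.shape[:3] + (self.filters,)) + self.b
        if training:
            self._cols = cols
        if self.relu:
            mask = out > 0
            out *= mask
            if training:
                self._mask = mask
        return out

    def backward(self, dy):
        if self.relu:
            dy = dy * self._mask
        kh, kw = self.kernel
        c = self.in_shape[2]
        b_, ho, wo, f = dy.shape
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        dy2 = dy.reshape(-1, f)
        self.dw = (cols2.T @ dy2).reshape(kh, kw, c, f)
        self.db = dy2.sum(axis=0)
        dcols = (dy2 @ self._wmat().T).reshape(b_, ho, wo, kh * kw * c)
        dx = np.zeros((b_,) + self.in_shape, dtype=np.float32)
        k = 0
        for i in range(kh):
            for j in range(kw):
                dx[:, i : i + ho, j : j + wo, :] += dcols[..., k * c : (k + 1) * c]
                k += 1
        self._cols = None
        return dx


class MaxPool2D(_Layer):
    """Max pooling, stride = pool size; trailing remainder rows/cols dropped."""

    def __init__(self, pool: Tuple[int, int]):
        self.pool = tuple(pool)

    def init(self, rng, in_shape):
        h, w, c = in_shape
        ph, pw = self.pool
        ho, wo = h // ph, w // pw
        if ho < 1 or wo < 1:
            raise ConfigurationError(
                f"maxpool{self.pool} on input {in_shape}: non-positive output extent"
            )
        self.in_shape = in_shape
        self.out_shape = (ho, wo, c)
        return self.out_shape

    def _windows(self, x):
        ph, pw = self.pool
        ho, wo, _ = self.out_shape
        return [
            x[:, i : i + ho * ph : ph, j : j + wo * pw : pw, :]
            for i in range(ph)
            for j in range(pw)
        ]

    def forward(self, x, training=False, rng=None):
        out = None
        for w in self._windows(x):
            out = w.copy() if out is None else np.maximum(out, w, out=out)
        if training:
            self._x = x
            self._out = out
        return out

    def backward(self, dy):
        # route each gradient to the first window position attaining the max
        dx = np.zeros((dy.shape[0],) + self.in_shape, dtype=np.float32)
        taken = np.zeros(dy.shape, dtype=bool)
        ph, pw = self.pool
        ho, wo, _ = self.out_shape
        for i in range(ph):
            for j in range(pw):
                w = self._x[:, i : i + ho * ph : ph, j : j + wo * pw : pw, :]
                hit = (w == self._out) & ~taken
                taken |= hit
                dx[:, i : i + ho * ph : ph, j : j + wo * pw : pw, :] += dy * hit
        self._x = self._out = None
        return dx


class GlobalAveragePool2D(_Layer):
    """Mean over the spatial axes (off-by-default alternative to Flatten)."""

    def init(self, rng, in_shape):
        self.in_shape = in_shape
        return (in_shape[2],)

    def forward(self, x, training=False, rng=None):
        self._b = x.shape[0]
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        h, w, c = self.in_shape
        return np.broadcast_to(
            dy[:, None, None, :] / (h * w), (self._b, h, w, c)
        ).astype(np.float32)


class Flatten(_Layer):
    def init(self, rng, in_shape):
        self.in_shape = in_shape
        return (int(np.prod(in_shape)),)

    def forward(self, x, training=False, rng=None):
        self._b = x.shape[0]
        return x.reshape(self._b, -1)

    def backward(self, dy):
        return dy.reshape((self._b,) + self.in_shape)


class Dense(_Layer):
    params = ["w", "b"]

    def __init__(self, units: int, relu: bool = False):
        self.units = units
        self.relu = relu

    def init(self, rng, in_shape):
        (k,) = in_shape
        self.w = glorot_uniform(rng, (k, self.units), k, self.units)
        self.b = np.zeros(self.units, dtype=np.float32)
        return (self.units,)

    def forward(self, x, training=False, rng=None):
        out = x @ self.w + self.b
        if training:
            self._x = x
        if self.relu:
            mask = out > 0
            out *= mask
            if training:
                self._mask = mask
        return out

    def backward(self, dy):
        if self.relu:
            dy = dy * self._mask
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


class Dropout(_Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ConfigurationError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def init(self, rng, in_shape):
        return in_shape

    def forward(self, x, training=False, rng=None):
        # rng=None (e.g. a gradient probe of a trained net) means no dropout
        if not training or self.rate == 0.0 or rng is None:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if not hasattr(self, "_mask") or self._mask is None:
            return dy
        dy = dy * self._mask
        self._mask = None
        return dy


class Network:
    """An ordered layer stack ending in a 2-way softmax head."""

    def __init__(self, layers: Sequence[_Layer], input_shape: Tuple[int, ...]):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)
        self.built = False

    def build(self, seed: int = 0) -> "Network":
        rng = np.random.default_rng([seed, 606])
        shape = self.input_shape
        self.shapes = [shape]
        for layer in self.layers:
            shape = layer.init(rng, shape)
            self.shapes.append(shape)
        if shape != (2,):
            raise ConfigurationError(f"network head must output 2 logits, got {shape}")
        self.built = True
        return self

    # -- parameter access ---------------------------------------------------
    def get_weights(self) -> List[np.ndarray]:
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append(getattr(layer, name).copy())
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        weights = list(weights)
        k = 0
        for layer in self.layers:
            for name in layer.params:
                cur = getattr(layer, name)
                if cur.shape != weights[k].shape:
                    raise DataError(
                        f"weight {k} shape mismatch: {cur.shape} vs {weights[k].shape}"
                    )
                setattr(layer, name, weights[k].astype(np.float32))
                k += 1
        if k != len(weights):
            raise DataError("wrong number of weight arrays")

    def param_refs(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_params(self) -> int:
        return sum(getattr(l, n).size for l, n in self.param_refs())

    # -- forward / backward -------------------------------------------------
    def _logits(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        if not self.built:
            raise DataError("network not built")
        x = np.asarray(x, dtype=np.float32)
        outs = [
            softmax(self._logits(x[s : s + batch_size]))
            for s in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def train_batch(self, x, y_onehot, rng) -> Tuple[float, float]:
        """One forward/backward pass; returns (loss, accuracy). Gradients are
        left on the layers for the optimizer to consume."""
        logits = self._logits(x, training=True, rng=rng)
        probs = softmax(logits)
        eps = 1e-12
        # 2-way softmax + one-hot binary cross-entropy == categorical CE
        loss = float(-np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1)))
        acc = float(np.mean(probs.argmax(axis=1) == y_onehot.argmax(axis=1)))
        dy = (probs - y_onehot) / len(x)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return loss, acc

    def input_gradient(self, x: np.ndarray, class_idx: int) -> np.ndarray:
        """Gradient of the given class logit with respect to the input."""
        if not self.built:
            raise DataError("network not built")
        x = np.asarray(x, dtype=np.float32)
        logits = self._logits(x, training=True, rng=None)
        dy = np.zeros_like(logits)
        dy[:, class_idx] = 1.0
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with the usual framework defaults (lr 1e-3, b1 .9, b2 .999)."""

    def __init__(self, net: Network, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.refs = list(net.param_refs())
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, n)) for l, n in self.refs]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in self.refs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, (layer, name) in enumerate(self.refs):
            g = getattr(layer, "d" + name)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.lr * (self.m[k] / b1t)
                      / (np.sqrt(self.v[k] / b2t) + self.eps))
            setattr(layer, name, getattr(layer, name) - update.astype(np.float32))
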