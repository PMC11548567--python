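"""Minimal NumPy neural-network engine for 1D convolutional classifiers.

Implements exactly the layer set the architecture needs — valid stride-1
conv1d, non-overlapping max-pooling, inverted dropout, flatten, dense — with
manual backpropagation and an Adam optimizer.  Convolutions are evaluated as
batched tensor contractions over sliding windows (``numpy.lib.stride_tricks``),
which keeps a full forward/backward pass of the 1.6M-parameter reference
network tractable on one CPU.

All computation is float32 and fully deterministic given the seed used to
initialize weights and drive dropout/shuffling.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from lungsound.arch import ArchSpec

_F32 = np.float32


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> read-only view (B, L-k+1, k, C) of sliding windows."""
    return sliding_window_view(x, k, axis=1).transpose(0, 1, 3, 2)


class Conv1D:
    """Valid, stride-1 1D convolution (cross-correlation) with bias and ReLU."""

    def __init__(self, kernel: int, in_ch: int, filters: int, relu: bool, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kernel * in_ch))  # He init for ReLU stacks
        self.w = (rng.standard_normal((kernel, in_ch, filters)) * scale).astype(_F32)
        self.b = np.zeros(filters, dtype=_F32)
        self.relu = relu
        self.kernel = kernel

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        out = np.tensordot(_windows(x, self.kernel), self.w, axes=([2, 3], [0, 1]))
        out += self.b
        if self.relu:
            self._mask = out > 0
            out *= self._mask
        return out

    def backward(self, g: np.ndarray):
        if self.relu:
            g = g * self._mask
        cols = _windows(self._x, self.kernel)  # (B, Lout, k, Cin)
        self.dw = np.tensordot(cols, g, axes=([0, 1], [0, 1]))  # (k, Cin, Cout)
        self.db = g.sum(axis=(0, 1))
        # dx: full correlation of the upstream gradient with the flipped kernel
        k = self.kernel
        gpad = np.pad(g, ((0, 0), (k - 1, k - 1), (0, 0)))
        wflip = self.w[::-1].transpose(0, 2, 1)  # (k, Cout, Cin)
        return np.tensordot(_windows(gpad, k), wflip, axes=([2, 3], [0, 1]))


class MaxPool1D:
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, c = x.shape
        lout = length // self.pool
        self._in_shape = x.shape
        blocks = x[:, : lout * self.pool].reshape(b, lout, self.pool, c)
        self._argmax = blocks.argmax(axis=2)
        return blocks.max(axis=2)

    def backward(self, g: np.ndarray):
        b, lout, c = g.shape
        blocks = np.zeros((b, lout, self.pool, c), dtype=_F32)
        bi, li, ci = np.ogrid[:b, :lout, :c]
        blocks[bi, li, self._argmax, ci] = g
        dx = np.zeros(self._in_shape, dtype=_F32)
        dx[:, : lout * self.pool] = blocks.reshape(b, lout * self.pool, c)
        return dx


class Dropout:
    """Inverted dropout: active only in training mode, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F32) / _F32(keep)
        return x * self._mask

    def backward(self, g: np.ndarray):
        return g if self._mask is None else g * self._mask


class Flatten:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray):
        return g.reshape(self._shape)


class Dense:
    """Fully connected layer; optional ReLU (the softmax head stays linear —
    the softmax is folded into the loss)."""

    def __init__(self, in_units: int, units: int, relu: bool, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_units)
        self.w = (rng.standard_normal((in_units, units)) * scale).astype(_F32)
        self.b = np.zeros(units, dtype=_F32)
        self.relu = relu

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        out = x @ self.w + self.b
        if self.relu:
            self._mask = out > 0
            out *= self._mask
        return out

    def backward(self, g: np.ndarray):
        if self.relu:
            g = g * self._mask
        self.dw = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


_EPS = 1e-7


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probs, _EPS, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def focal_loss(probs: np.ndarray, onehot: np.ndarray, gamma: float) -> float:
    """Mean over samples of -(1 - p_true)^gamma * log(p_true).

    gamma = 0 recovers categorical cross-entropy; probabilities are clipped at
    a small epsilon so an (impossible under softmax, but representable) zero
    never produces an infinite loss.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p_true = np.clip((probs * onehot).sum(axis=1), _EPS, 1.0)
    return float(np.mean(-((1.0 - p_true) ** gamma) * np.log(p_true)))


def _loss_grad(probs: np.ndarray, onehot: np.ndarray, loss: str, gamma: float) -> np.ndarray:
    """Gradient of the mean loss w.r.t. the pre-softmax logits."""
    n = probs.shape[0]
    if loss == "categorical_crossentropy":
        return (probs - onehot) / n
    # focal: d/dz = [gamma * (1-p)^(g-1) * p * log(p) + (1-p)^g] * (probs - onehot_adjusted)
    p_true = np.clip((probs * onehot).sum(axis=1, keepdims=True), _EPS, 1.0)
    coef = (1.0 - p_true) ** gamma - gamma * (1.0 - p_true) ** np.maximum(gamma - 1.0, 0.0) * (
        p_true * np.log(p_true)
    )
    return coef * (probs - onehot) / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class SGD:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class Network:
    """Sequential network instantiated from an :class:`ArchSpec`.

    Parameter counting sums the sizes of the actually allocated weight arrays,
    independently of the arithmetic in :func:`lungsound.arch.summarize`.
    """

    def __init__(self, arch: ArchSpec, rng: np.random.Generator):
        self.arch = arch
        self.layers: list = []
        length, channels = arch.input_len, arch.input_channels
        flat: int | None = None
        for spec in arch.layers:
            if spec.kind == "conv1d":
                self.layers.append(
                    Conv1D(spec.kernel, channels, spec.filters, spec.activation == "relu", rng)
                )
                length = length - spec.kernel + 1
                channels = spec.filters
            elif spec.kind == "maxpool1d":
                self.layers.append(MaxPool1D(spec.pool))
                length //= spec.pool
            elif spec.kind == "dropout":
                self.layers.append(Dropout(spec.rate, rng))
            elif spec.kind == "flatten":
                self.layers.append(Flatten())
                flat = length * channels
            elif spec.kind == "dense":
                assert flat is not None, "dense before flatten"
                self.layers.append(Dense(flat, spec.units, spec.activation == "relu", rng))
                flat = spec.units

    @property
    def param_count(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, L) or (B, L, C) waveform batch -> (B, n_classes) probabilities."""
        if x.ndim == 2:
            x = x[:, :, None]
        out = np.ascontiguousarray(x, dtype=_F32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return softmax(out)

    def backward(self, probs, onehot, loss: str, gamma: float) -> list[np.ndarray]:
        g = _loss_grad(probs, onehot, loss, gamma).astype(_F32)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        grads: list[np.ndarray] = []
        for layer in self.layers:
            if isinstance(layer, (Conv1D, Dense)):
                grads.extend([layer.dw, layer.db])
        return grads

    @property
    def trainable_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def reseed_dropout(self, rng: np.random.Generator) -> None:
        """Point every dropout layer at a fresh stream (deterministic MC eval)."""
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.trainable_params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.trainable_params, weights):
            p[...] = w
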