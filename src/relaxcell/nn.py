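"""Minimal NumPy neural-network engine for the spectral-map classifiers.

Implements exactly the pieces the VGG-derived architectures need — 3x3
same-padding convolution (im2col), batch normalization, 2x2 max pooling,
dense layers, ReLU, dropout, a softmax cross-entropy head and the Adamax
optimizer — with explicit forward/backward passes in float32.  Everything
is seeded and CPU-only; there is no autograd, each layer implements its own
gradient.

Data layout is NHWC: images are (batch, height, width, channels).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm",
    "MaxPool2",
    "ReLU",
    "Flatten",
    "Dense",
    "Dropout",
    "SequentialNet",
    "Adamax",
    "softmax",
    "cross_entropy",
]

_F = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy; ``y`` holds integer class indices."""
    n = probs.shape[0]
    return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (configurable) convolution, stride 1, same padding, He init."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = ksize * ksize * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (ksize, ksize, c_in, c_out))
        self.w = w.astype(_F)
        self.b = np.zeros(c_out, dtype=_F)
        self.ksize = ksize
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train):
        k = self.ksize
        p = k // 2
        n, h, wdt, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (n, h, w, c, k, k) -> cols (n*h*w, k*k*c)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wdt, k * k * c)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.w.reshape(k * k * c, -1) + self.b
        return out.reshape(n, h, wdt, -1)

    def backward(self, g):
        k = self.ksize
        n, h, wdt, c = self._xshape
        c_out = g.shape[-1]
        gflat = g.reshape(n * h * wdt, c_out)
        self.grads[0][...] = (self._cols.T @ gflat).reshape(self.w.shape)
        self.grads[1][...] = gflat.sum(axis=0)
        # col2im: scatter-add each kernel tap back onto the padded input grid
        gcols = gflat @ self.w.reshape(k * k * c, c_out).T  # (n*h*w, k*k*c)
        gcols = gcols.reshape(n, h, wdt, k, k, c)
        p = k // 2
        gx = np.zeros((n, h + 2 * p, wdt + 2 * p, c), dtype=g.dtype)
        for a in range(k):
            for b in range(k):
                gx[:, a : a + h, b : b + wdt] += gcols[:, :, :, a, b]
        return gx[:, p : p + h, p : p + wdt]


class BatchNorm(Layer):
    """Per-channel batch normalization (over batch and spatial axes)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels, dtype=_F)
        self.beta = np.zeros(channels, dtype=_F)
        self.run_mean = np.zeros(channels, dtype=_F)
        self.run_var = np.ones(channels, dtype=_F)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean[...] = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var[...] = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._axes = axes
        self._m = np.prod([x.shape[a] for a in axes])
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        axes = self._axes
        self.grads[0][...] = (g * self._xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        m = self._m
        gx = (
            self.gamma
            * self._istd
            / m
            * (m * g - g.sum(axis=axes) - self._xhat * (g * self._xhat).sum(axis=axes))
        )
        return gx.astype(g.dtype)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 needs even spatial dimensions")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        gr = np.where(self._mask, g[:, :, None, :, None, :], 0.0)
        return gr.reshape(n, h, w, c).astype(g.dtype)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, g):
        return np.where(self._mask, g, 0.0).astype(g.dtype)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(_F)
        self.b = np.zeros(d_out, dtype=_F)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return (g @ self.w.T).astype(g.dtype)


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(x.dtype)

    def backward(self, g):
        if self._mask is None:
            return g
        return (g * self._mask).astype(g.dtype)


class SequentialNet:
    """Plain layer stack with a softmax cross-entropy head."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [softmax(self.forward(x[i : i + batch_size].astype(_F), train=False))
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def train_batch(self, x: np.ndarray, y: np.ndarray, opt: "Adamax") -> float:
        """One optimizer step on a batch; returns the batch loss."""
        logits = self.forward(x.astype(_F), train=True)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        n = x.shape[0]
        g = probs.copy()
        g[np.arange(n), y] -= 1.0
        g = (g / n).astype(_F)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        opt.step(self)
        if not np.isfinite(loss):
            raise FloatingPointError("training loss became non-finite")
        return loss

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def layer_counts(self) -> dict:
        from collections import Counter

        return dict(Counter(type(l).__name__ for l in self.layers))


class Adamax:
    """Adamax optimizer (Adam with an infinity-norm second moment)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._state: dict = {}

    def step(self, net: SequentialNet) -> None:
        self.t += 1
        bias = 1.0 - self.beta1**self.t
        for li, layer in enumerate(net.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                key = (li, pi)
                if key not in self._state:
                    self._state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, u = self._state[key]
                m[...] = self.beta1 * m + (1.0 - self.beta1) * g
                u[...] = np.maximum(self.beta2 * u, np.abs(g))
                p -= (self.lr / bias) * m / (u + self.eps)
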