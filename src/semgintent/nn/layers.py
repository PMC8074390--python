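"""Trainable layers with explicit forward/backward passes.

Each layer owns its parameters in ``params`` and accumulates gradients of
the same shapes in ``grads``.  The forward pass caches whatever the backward
pass needs; calling ``backward`` before ``forward`` is an error.
"""
from __future__ import annotations

import numpy as np

from . import functional as F


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    """Base class: parameter/gradient bookkeeping."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def _register(self, **arrays: np.ndarray) -> None:
        for name, arr in arrays.items():
            self.params[name] = arr
            self.grads[name] = np.zeros_like(arr)

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2D(Layer):
    """Valid 2-D cross-correlation, stride 1.  weight: (C_out, C_in, kh, kw)."""

    def __init__(self, in_ch, out_ch, kh, kw, rng, dtype=np.float32):
        super().__init__()
        fan_in = in_ch * kh * kw
        self._register(
            weight=kaiming_uniform(rng, (out_ch, in_ch, kh, kw), fan_in, dtype),
            bias=np.zeros(out_ch, dtype=dtype),
        )

    def forward(self, x):
        out, cols = F.conv2d(x, self.params["weight"], self.params["bias"])
        self._cache = (cols, x.shape)
        return out

    def backward(self, dout):
        cols, x_shape = self._cache
        dx, dw, db = F.conv2d_backward(dout, cols, self.params["weight"], x_shape)
        self.grads["weight"] += dw
        self.grads["bias"] += db
        return dx


class ConvTranspose2D(Layer):
    """Transposed valid convolution, stride 1.  weight: (C_in, C_out, kh, kw)."""

    def __init__(self, in_ch, out_ch, kh, kw, rng, dtype=np.float32):
        super().__init__()
        fan_in = in_ch * kh * kw
        self._register(
            weight=kaiming_uniform(rng, (in_ch, out_ch, kh, kw), fan_in, dtype),
            bias=np.zeros(out_ch, dtype=dtype),
        )

    def forward(self, x):
        out, x_flat = F.conv_transpose2d(x, self.params["weight"], self.params["bias"])
        self._cache = (x_flat, x.shape)
        return out

    def backward(self, dout):
        x_flat, x_shape = self._cache
        dx, dw, db = F.conv_transpose2d_backward(dout, x_flat, self.params["weight"], x_shape)
        self.grads["weight"] += dw
        self.grads["bias"] += db
        return dx


class Dense(Layer):
    """Affine map on the last axis.  weight: (in, out) — rows index inputs."""

    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        super().__init__()
        self._register(
            weight=kaiming_uniform(rng, (n_in, n_out), n_in, dtype),
            bias=np.zeros(n_out, dtype=dtype),
        )

    def forward(self, x):
        self._cache = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, dout):
        x = self._cache
        xf = x.reshape(-1, x.shape[-1])
        df = dout.reshape(-1, dout.shape[-1])
        self.grads["weight"] += xf.T @ df
        self.grads["bias"] += df.sum(axis=0)
        return (df @ self.params["weight"].T).reshape(x.shape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Tanh(Layer):
    def forward(self, x):
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout):
        return dout * (1.0 - self._out**2)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all elements; returns (loss, dpred)."""
    diff = pred - target
    n = diff.size
    return float(np.mean(diff.astype(np.float64) ** 2)), (2.0 / n) * diff


class SGD:
    """Plain stochastic gradient descent with optional global-norm clipping."""

    def __init__(self, layers, lr: float, clip_norm: float | None = None):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.clip_norm = clip_norm

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def _clip_scale(self) -> float:
        if self.clip_norm is None:
            return 1.0
        total = 0.0
        for l in self.layers:
            for g in l.grads.values():
                total += float(np.sum(g.astype(np.float64) ** 2))
        norm = np.sqrt(total)
        if norm > self.clip_norm:
            return self.clip_norm / (norm + 1e-12)
        return 1.0

    def step(self):
        scale = self._clip_scale()
        for l in self.layers:
            for k, p in l.params.items():
                p -= self.lr * scale * l.grads[k]


class Adam(SGD):
    """Adam with bias correction; used for the shortened desk-scale schedules
    where plain SGD cannot cross the ill-conditioned loss surface in the
    available step budget."""

    def __init__(self, layers, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clip_norm: float | None = None):
        super().__init__(layers, lr, clip_norm)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]

    def step(self):
        scale = self._clip_scale()
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for li, l in enumerate(self.layers):
            for k, p in l.params.items():
                g = scale * l.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
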