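"""Minimal convolutional-network machinery on numpy.

Implements exactly the pieces the single-shot detector needs -- 2-D
convolution (im2col + matmul), ReLU, 2x2 max pooling, He initialization,
analytic backpropagation and an Adam optimizer -- with float32 tensors in
NCHW layout.  The scope is deliberately narrow: static feed-forward stacks
whose gradients we derive by hand, which keeps training runs fast and
bit-reproducible on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold k x k patches of an NCHW tensor into a matrix.

    Returns ``(cols, H_out, W_out)`` with cols of shape
    ``(N*H_out*W_out, C*k*k)``.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    shape = (n, c, ho, wo, k, k)
    strides = (
        x.strides[0],
        x.strides[1],
        x.strides[2] * stride,
        x.strides[3] * stride,
        x.strides[2],
        x.strides[3],
    )
    view = np.lib.stride_tricks.as_strided(x, shape, strides)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * k * k), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col`: scatter-add column gradients back."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    dx = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols6 = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                cols6[:, :, :, :, i, j]
            )
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Layer:
    params: dict
    grads: dict

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) convolution with 'same'-style zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = c_in * k * k
        w = rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(c_out, dtype=np.float32)}
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self._cache = None

    def forward(self, x, train=True):
        x = x.astype(np.float32, copy=False)
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        w2 = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = cols @ w2.T + self.params["b"]
        n = x.shape[0]
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (x.shape, cols)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        x_shape, cols = self._cache
        n, c_out, ho, wo = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.grads["W"][...] = (dmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"][...] = dmat.sum(axis=0)
        dcols = dmat @ self.params["W"].reshape(c_out, -1)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class ReLU(Layer):
    def __init__(self):
        self.params, self.grads = {}, {}
        self._mask = None

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class BatchNorm2d(Layer):
    """Per-channel batch normalization for NCHW tensors.

    Training uses batch statistics and keeps exponential running averages
    (momentum 0.9) that inference uses, so a trained network is
    deterministic regardless of batch composition at test time.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.params = {"gamma": np.ones(channels, dtype=np.float32),
                       "beta": np.zeros(channels, dtype=np.float32)}
        self.grads = {"gamma": np.zeros(channels, dtype=np.float32),
                      "beta": np.zeros(channels, dtype=np.float32)}
        self.buffers = {"running_mean": np.zeros(channels, dtype=np.float32),
                        "running_var": np.ones(channels, dtype=np.float32)}
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def forward(self, x, train=True):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if not train:
            mean = self.buffers["running_mean"][None, :, None, None]
            var = self.buffers["running_var"][None, :, None, None]
            return g * (x - mean) / np.sqrt(var + self.eps) + b
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        m = self.momentum
        self.buffers["running_mean"][...] = (
            m * self.buffers["running_mean"] + (1 - m) * mean
        )
        self.buffers["running_var"][...] = (
            m * self.buffers["running_var"] + (1 - m) * var
        )
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return g * xhat + b

    def backward(self, dout):
        xhat, inv_std = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        # standard batchnorm backward over the (N, H, W) axes
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv_std[None, :, None, None] * (
            dxhat - mean_dxhat - xhat * mean_dxhat_xhat
        )


class MaxPool2(Layer):
    """2x2, stride-2 max pooling; truncates odd trailing rows/columns."""

    def __init__(self):
        self.params, self.grads = {}, {}
        self._cache = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : 2 * h2, : 2 * w2]
        xr = x.reshape(n, c, h2, 2, w2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._cache = (x.shape, xr, out)
        return out

    def backward(self, dout):
        x_shape, xr, out = self._cache
        mask = xr == out[:, :, :, None, :, None]
        # distribute evenly across ties to keep the adjoint exact
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dx = mask * (dout[:, :, :, None, :, None] / counts)
        return dx.reshape(x_shape)


@dataclass
class Sequential:
    layers: list[Layer] = field(default_factory=list)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                out.append((f"{i}.{name}", layer.params[name], layer.grads[name]))
        return out

    def buffers(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, value in getattr(layer, "buffers", {}).items():
                out.append((f"{i}.{name}", value))
        return out


class Adam:
    """Adam with the standard bias correction; state keyed by parameter id."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)  # (name, value, grad) triples
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(v) for n, v, _ in self.params}
        self.v = {n: np.zeros_like(v) for n, v, _ in self.params}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for name, value, grad in self.params:
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad * grad
            value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, targets: np.ndarray):
    """Per-row softmax cross-entropy and its gradient w.r.t. logits.

    ``logits``: (N, K); ``targets``: (N,) int class indices.
    Returns (loss_per_row (N,), dlogits (N, K)).
    """
    p = softmax(logits, axis=1)
    n = logits.shape[0]
    idx = np.arange(n)
    loss = -np.log(np.clip(p[idx, targets], 1e-12, None))
    dlogits = p.copy()
    dlogits[idx, targets] -= 1.0
    return loss, dlogits


def smooth_l1_with_grad(pred: np.ndarray, target: np.ndarray):
    """Elementwise smooth-L1 (Huber, delta=1) and gradient w.r.t. pred."""
    d = pred - target
    a = np.abs(d)
    loss = np.where(a < 1.0, 0.5 * d * d, a - 0.5)
    grad = np.where(a < 1.0, d, np.sign(d))
    return loss, grad
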