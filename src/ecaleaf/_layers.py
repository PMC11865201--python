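"""Minimal numpy layer engine used by the classifier network.

Each layer implements ``forward(x, training)`` and ``backward(grad)``;
learnable arrays live in ``layer.params`` with matching ``layer.grads``.
Tensors are NCHW float32.  Convolutions use "same" padding with ceil
division under stride, so a stride-2 stage maps H -> ceil(H/2).
"""

from __future__ import annotations

import numpy as np


def same_pads(size: int, k: int, stride: int) -> tuple[int, int]:
    """Asymmetric (before, after) padding giving output length ceil(size/stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def _pad_nchw(x, pads_h, pads_w):
    return np.pad(x, ((0, 0), (0, 0), pads_h, pads_w))


def _windows(xp, k, stride):
    # (N, C, Hp, Wp) -> (N, C, Ho, Wo, k, k) strided view
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


def kaiming_conv(rng, shape, fan_out):
    return rng.normal(0.0, np.sqrt(2.0 / fan_out), shape).astype(np.float32)


class Conv2d(Layer):
    """Standard convolution; bias optional (backbone convs are bias-free)."""

    def __init__(self, cin, cout, k, stride=1, bias=False, rng=None, init="kaiming"):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        if init == "zeros" or rng is None:
            w = np.zeros((cout, cin, k, k), np.float32)
        else:
            w = kaiming_conv(rng, (cout, cin, k, k), k * k * cout)
        self.w = w
        self.b = np.zeros(cout, np.float32) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None
        self.params = [self.w] + ([self.b] if bias else [])
        self.grads = [self.gw] + ([self.gb] if bias else [])

    def forward(self, x, training=False):
        if self.k == 1 and self.stride == 1:
            self._x = x
            out = np.einsum("oc,nchw->nohw", self.w[:, :, 0, 0], x)
        else:
            ph = same_pads(x.shape[2], self.k, self.stride)
            pw = same_pads(x.shape[3], self.k, self.stride)
            xp = _pad_nchw(x, ph, pw)
            v = _windows(xp, self.k, self.stride)
            self._cache = (xp.shape, ph, pw, x.shape, v)
            out = np.einsum("ocij,nchwij->nohw", self.w, v, optimize=True)
        if self.b is not None:
            out = out + self.b[None, :, None, None]
        return out

    def backward(self, g):
        if self.b is not None:
            self.gb[...] = g.sum(axis=(0, 2, 3))
        if self.k == 1 and self.stride == 1:
            self.gw[...] = np.einsum("nohw,nchw->oc", g, self._x)[:, :, None, None]
            return np.einsum("oc,nohw->nchw", self.w[:, :, 0, 0], g)
        xp_shape, ph, pw, x_shape, v = self._cache
        self.gw[...] = np.einsum("nohw,nchwij->ocij", g, v, optimize=True)
        dxp = np.zeros(xp_shape, np.float32)
        n, _, ho, wo = g.shape
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                t = np.einsum("nohw,oc->nchw", g, self.w[:, :, i, j])
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += t
        h, w = x_shape[2], x_shape[3]
        return dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]


class DepthwiseConv2d(Layer):
    """Per-channel spatial filter; channel count preserved."""

    def __init__(self, channels, k, stride=1, rng=None, init="kaiming"):
        self.c, self.k, self.stride = channels, k, stride
        if init == "zeros" or rng is None:
            w = np.zeros((channels, k, k), np.float32)
        else:
            w = kaiming_conv(rng, (channels, k, k), k * k)
        self.w = w
        self.gw = np.zeros_like(w)
        self.params = [self.w]
        self.grads = [self.gw]

    def forward(self, x, training=False):
        ph = same_pads(x.shape[2], self.k, self.stride)
        pw = same_pads(x.shape[3], self.k, self.stride)
        xp = _pad_nchw(x, ph, pw)
        v = _windows(xp, self.k, self.stride)
        self._cache = (xp.shape, ph, pw, x.shape, v)
        return np.einsum("nchwij,cij->nchw", v, self.w, optimize=True)

    def backward(self, g):
        xp_shape, ph, pw, x_shape, v = self._cache
        self.gw[...] = np.einsum("nchw,nchwij->cij", g, v, optimize=True)
        dxp = np.zeros(xp_shape, np.float32)
        n, _, ho, wo = g.shape
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += (
                    g * self.w[None, :, i, j, None, None]
                )
        h, w = x_shape[2], x_shape[3]
        return dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]


class BatchNorm2d(Layer):
    """Affine batch norm (2 learnable scalars per channel: scale, shift)."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, init="kaiming"):
        self.eps, self.momentum = eps, momentum
        self.gamma = (
            np.zeros(channels, np.float32) if init == "zeros" else np.ones(channels, np.float32)
        )
        self.beta = np.zeros(channels, np.float32)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.ggamma, self.gbeta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, training)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, g):
        xhat, std, training = self._cache
        self.ggamma[...] = (g * xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = g.sum(axis=(0, 2, 3))
        dxhat = g * self.gamma[None, :, None, None]
        if not training:
            return dxhat / std[None, :, None, None]
        n, c, h, w = g.shape
        m = n * h * w
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m) / std[None, :, None, None]


class ReLU6(Layer):
    def forward(self, x, training=False):
        self._mask = (x > 0) & (x < 6.0)
        return np.clip(x, 0.0, 6.0)

    def backward(self, g):
        return g * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate, rng=None):
        self.rate = float(rate)
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, g):
        n, c, h, w = self._shape
        return np.broadcast_to(g / (h * w), self._shape).copy()


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Residual(Layer):
    """Identity skip around an inner stack (stride 1, matching channels only)."""

    def __init__(self, inner: Sequential):
        self.inner = inner

    @property
    def params(self):
        return self.inner.params

    @property
    def grads(self):
        return self.inner.grads

    def forward(self, x, training=False):
        return self.inner.forward(x, training) + x

    def backward(self, g):
        return self.inner.backward(g) + g


class Adam:
    """Standard Adam over a flat (param, grad) list."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits, labels):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
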