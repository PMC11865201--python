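"""Efficient channel attention (ECA).

The gate pools each channel of a feature map to a scalar (global average
pooling), mixes each scalar with its k neighbouring channels through a
single shared k-tap 1-D convolution, squashes the result through a sigmoid,
and rescales the channels by the resulting weights.  Unlike
squeeze-excitation there is no dimensionality-reducing bottleneck: the gate
carries exactly k learnable scalars, where k is chosen adaptively from the
channel count C as the nearest odd integer to log2(C)/gamma + b/gamma
(defaults gamma=2, b=1).
"""

from __future__ import annotations

import numpy as np

from ._layers import Layer


def relu6(x):
    """Clipped rectifier min(max(0, x), 6); elementwise on arrays."""
    return np.clip(x, 0.0, 6.0)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1-D kernel size for an ECA gate over ``channels`` channels.

    Returns the odd integer nearest to log2(C)/gamma + b/gamma; a value that
    lands on an even integer resolves upward (t = floor(log2(C)/gamma +
    b/gamma); k = t if odd else t + 1).  Non-decreasing in C and always odd.
    """
    if channels < 1:
        raise ValueError(f"channel count must be >= 1, got {channels}")
    t = int(np.floor(np.log2(channels) / gamma + b / gamma))
    k = t if t % 2 == 1 else t + 1
    return max(k, 1)

def global_average_pool(fm: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of a (C, H, W) or (N, C, H, W) feature map."""
    fm = np.asarray(fm)
    if fm.ndim == 3:
        if fm.shape[1] * fm.shape[2] == 0:
            raise ValueError("feature map has zero spatial extent")
        return fm.mean(axis=(1, 2))
    if fm.ndim == 4:
        if fm.shape[2] * fm.shape[3] == 0:
            raise ValueError("feature map has zero spatial extent")
        return fm.mean(axis=(2, 3))
    raise ValueError(f"expected 3- or 4-dimensional feature map, got ndim={fm.ndim}")


class EcaGate(Layer):
    """The ECA unit: GAP -> shared k-tap Conv1D across channels -> sigmoid -> rescale.

    The 1-D convolution runs along the channel axis with zero ("same")
    padding of (k-1)/2 so the weight vector has exactly C entries, and
    carries no bias: the gate's learnable parameter count is exactly k.
    """

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0,
                 kernel: np.ndarray | None = None):
        self.channels = channels
        self.k = eca_kernel_size(channels, gamma, b)
        if kernel is None:
            kernel = np.zeros(self.k, np.float32)
        else:
            kernel = np.asarray(kernel, np.float32)
            if kernel.shape != (self.k,):
                raise ValueError(
                    f"kernel must have shape ({self.k},) for C={channels}, "
                    f"got {kernel.shape}"
                )
        self.w = kernel
        self.gw = np.zeros_like(self.w)
        self.params = [self.w]
        self.grads = [self.gw]

    # -- channel weights -------------------------------------------------
    def channel_weights(self, fm: np.ndarray) -> np.ndarray:
        """Attention weights, one per channel, each strictly in (0, 1)."""
        s = global_average_pool(fm)
        single = s.ndim == 1
        if single:
            s = s[None]
        z = self._conv1d(s)
        w = sigmoid(z)
        return w[0] if single else w

    def _conv1d(self, s):
        pad = (self.k - 1) // 2
        sp = np.pad(s, ((0, 0), (pad, pad)))
        v = np.lib.stride_tricks.sliding_window_view(sp, self.k, axis=1)
        return v @ self.w

    # -- layer interface -------------------------------------------------
    def forward(self, x, training=False):
        if x.shape[1] != self.channels:
            raise ValueError(
                f"gate configured for {self.channels} channels, input has {x.shape[1]}"
            )
        s = x.mean(axis=(2, 3))
        z = self._conv1d(s)
        w = sigmoid(z)
        self._cache = (x, s, w)
        return x * w[:, :, None, None]

    def backward(self, g):
        x, s, w = self._cache
        n, c, h, w_sp = x.shape
        dw_chan = (g * x).sum(axis=(2, 3))            # dL/d(omega)
        dz = dw_chan * w * (1.0 - w)                  # through sigmoid
        pad = (self.k - 1) // 2
        sp = np.pad(s, ((0, 0), (pad, pad)))
        v = np.lib.stride_tricks.sliding_window_view(sp, self.k, axis=1)
        self.gw[...] = np.einsum("nc,nck->k", dz, v)
        # scatter dz back through the same-padded 1-D convolution
        dsp = np.zeros_like(sp)
        for j in range(self.k):
            dsp[:, j : j + c] += dz * self.w[j]
        ds = dsp[:, pad : pad + c]
        return g * w[:, :, None, None] + ds[:, :, None, None] / (h * w_sp)


def eca_forward(fm: np.ndarray, gate: EcaGate) -> np.ndarray:
    """Apply an ECA gate to a (C, H, W) or (N, C, H, W) feature map."""
    fm = np.asarray(fm, np.float32)
    single = fm.ndim == 3
    x = fm[None] if single else fm
    if x.shape[1] != gate.channels:
        raise ValueError(
            f"channel mismatch: feature map has {x.shape[1]}, gate expects {gate.channels}"
        )
    out = gate.forward(x)
    return out[0] if single else out
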