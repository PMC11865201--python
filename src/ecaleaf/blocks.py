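"""Inverted-residual building blocks.

Three variants are used by the backbone:

* ``DW_IR``    — depthwise conv (+BN+relu6) -> ECA -> pointwise projection
                 (+BN, no activation); no channel expansion.
* ``DSC_IR``   — pointwise expansion (+BN+relu6) -> depthwise (+BN+relu6)
                 -> pointwise projection (+BN, no activation).
* ``DSC_ECA_IR`` — DSC_IR with an ECA gate after the projection stage,
                 acting on the output channels, before the residual add.

An identity skip wraps the block iff stride == 1 and the channel count is
preserved.  All convolutions are bias-free and followed by batch norm
(2 learnable scalars per channel), so a block's learnable-parameter count
has a closed form (:func:`block_param_count`) that must agree with a direct
enumeration of the built block's tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._layers import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    ReLU6,
    Residual,
    Sequential,
)
from .attention import EcaGate, eca_kernel_size

BLOCK_KINDS = ("DW_IR", "DSC_IR", "DSC_ECA_IR")


@dataclass(frozen=True)
class BlockSpec:
    """One backbone row: block kind, kernel, channel plan, attention flag, stride."""

    kind: str
    kernel: int
    in_channels: int
    expansion_channels: int
    out_channels: int
    stride: int

    def __post_init__(self):
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError(f"kernel must be odd and positive, got {self.kernel}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.kind == "DW_IR" and self.expansion_channels != self.in_channels:
            raise ValueError("DW_IR has no expansion stage: expansion == in_channels")
        if min(self.in_channels, self.expansion_channels, self.out_channels) < 1:
            raise ValueError("channel counts must be positive")

    @property
    def use_eca(self) -> bool:
        return self.kind in ("DW_IR", "DSC_ECA_IR")

    @property
    def has_residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


def build_block(spec: BlockSpec, rng=None, init: str = "kaiming",
                use_eca: bool | None = None):
    """Compose the layer stack for one block; wraps it in a residual when eligible.

    ``use_eca=False`` builds the attention-free ablation of the same row.
    """
    if use_eca is None:
        use_eca = spec.use_eca
    layers = []
    if spec.kind != "DW_IR":
        layers += [
            Conv2d(spec.in_channels, spec.expansion_channels, 1, rng=rng, init=init),
            BatchNorm2d(spec.expansion_channels, init=init),
            ReLU6(),
        ]
    layers += [
        DepthwiseConv2d(spec.expansion_channels, spec.kernel, spec.stride,
                        rng=rng, init=init),
        BatchNorm2d(spec.expansion_channels, init=init),
        ReLU6(),
    ]
    if spec.kind == "DW_IR" and use_eca:
        layers.append(EcaGate(spec.expansion_channels))
    layers += [
        Conv2d(spec.expansion_channels, spec.out_channels, 1, rng=rng, init=init),
        BatchNorm2d(spec.out_channels, init=init),
    ]
    if spec.kind == "DSC_ECA_IR" and use_eca:
        layers.append(EcaGate(spec.out_channels))
    inner = Sequential(layers)
    return Residual(inner) if spec.has_residual else inner


def block_param_count(spec: BlockSpec, use_eca: bool | None = None) -> int:
    """Closed-form learnable-scalar count of :func:`build_block`'s output.

    Conventions: convolutions are bias-free; each is followed by batch norm
    contributing 2 scalars per output channel; an ECA gate contributes its
    adaptive kernel size k at the channel count where it sits.
    """
    if use_eca is None:
        use_eca = spec.use_eca
    total = 0
    if spec.kind != "DW_IR":
        total += spec.in_channels * spec.expansion_channels  # expand PW
        total += 2 * spec.expansion_channels                 # BN
    total += spec.kernel**2 * spec.expansion_channels        # depthwise
    total += 2 * spec.expansion_channels                     # BN
    if spec.kind == "DW_IR" and use_eca:
        total += eca_kernel_size(spec.expansion_channels)
    total += spec.expansion_channels * spec.out_channels     # project PW
    total += 2 * spec.out_channels                           # BN
    if spec.kind == "DSC_ECA_IR" and use_eca:
        total += eca_kernel_size(spec.out_channels)
    return total


def dsc_cost(h: int, w: int, d_in: int, d_out: int, k: int) -> int:
    """Multiply count of a depthwise-separable convolution: h*w*d_in*(k^2 + d_out)."""
    if min(h, w, d_in, d_out, k) < 1:
        raise ValueError("all extents must be positive")
    return h * w * d_in * (k * k + d_out)


def standard_conv_cost(h: int, w: int, d_in: int, d_out: int, k: int) -> int:
    """Multiply count of the equivalent standard convolution: h*w*d_in*d_out*k^2."""
    if min(h, w, d_in, d_out, k) < 1:
        raise ValueError("all extents must be positive")
    return h * w * d_in * d_out * k * k


def enumerate_param_count(block) -> int:
    """Oracle: total size of every learnable tensor in a built layer stack."""
    return int(sum(p.size for p in block.params))
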