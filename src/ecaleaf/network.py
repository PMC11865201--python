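"""The full ultra-lightweight ECA leaf-disease classification network.

Topology: a 3x3 stride-2 stem convolution, thirteen inverted-residual
blocks (one depthwise DW_IR, two attention-free DSC_IR, ten DSC_ECA_IR),
then a head of 1x1 conv 48->288 (+BN+relu6), global average pooling,
1x1 conv 288->512 (+bias, relu6), dropout, and a 1x1 conv 512->num_classes
(+bias) in place of a fully connected classifier.  At the default
448x448x3 input the backbone ends at 7x7x48 and the head at 1x1xnum_classes.

The network spec is the single source of truth for both model construction
and the analytic parameter count: for the 4-class default the full variant
carries 418,181 learnable scalars and the attention-free ablation 418,148
(the eleven ECA gates contribute 3 parameters each, +33 in total).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from ._layers import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    ReLU6,
    Sequential,
    softmax,
)
from .attention import eca_kernel_size
from .blocks import BlockSpec, block_param_count, build_block, enumerate_param_count

VARIANTS = ("full", "no_eca", "no_dropout")

#: The thirteen backbone rows: (kind, kernel, in, expansion, out, stride).
BACKBONE_ROWS: tuple[BlockSpec, ...] = tuple(
    BlockSpec(*row)
    for row in [
        ("DW_IR", 3, 16, 16, 16, 2),
        ("DSC_IR", 3, 16, 72, 24, 2),
        ("DSC_IR", 3, 24, 88, 24, 1),
        ("DSC_ECA_IR", 3, 24, 88, 24, 1),
        ("DSC_ECA_IR", 5, 24, 96, 40, 2),
        ("DSC_ECA_IR", 5, 40, 240, 40, 1),
        ("DSC_ECA_IR", 5, 40, 240, 40, 1),
        ("DSC_ECA_IR", 5, 40, 120, 48, 2),
        ("DSC_ECA_IR", 5, 48, 144, 48, 1),
        ("DSC_ECA_IR", 5, 48, 288, 48, 1),
        ("DSC_ECA_IR", 5, 48, 288, 48, 2),
        ("DSC_ECA_IR", 5, 48, 288, 48, 1),
        ("DSC_ECA_IR", 5, 48, 288, 48, 1),
    ]
)

STEM_OUT = 16
HEAD_MID = 288
HEAD_WIDE = 512


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: stem + backbone rows + head."""

    rows: tuple[BlockSpec, ...] = BACKBONE_ROWS
    num_classes: int = 4
    dropout_rate: float = 0.2
    input_size: int = 448

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")

    def fingerprint(self) -> str:
        """Stable identity string used to validate checkpoints on load."""
        rows = [
            (r.kind, r.kernel, r.in_channels, r.expansion_channels,
             r.out_channels, r.stride)
            for r in self.rows
        ]
        return json.dumps(
            {"rows": rows, "num_classes": self.num_classes,
             "input_size": self.input_size},
            separators=(",", ":"),
        )


class Network:
    """A built classifier: callable forward pass plus training helpers."""

    def __init__(self, spec: NetworkSpec, variant: str, stack: Sequential):
        self.spec = spec
        self.variant = variant
        self.stack = stack

    @property
    def params(self):
        return self.stack.params

    @property
    def grads(self):
        return self.stack.grads

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map a (N, 3, S, S) batch to (N, num_classes) logits."""
        x = np.asarray(x, np.float32)
        s = self.spec.input_size
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != s or x.shape[3] != s:
            raise ValueError(
                f"expected input of shape (N, 3, {s}, {s}), got {tuple(x.shape)}"
            )
        out = self.stack.forward(x, training)
        return out[:, :, 0, 0]

    def backward(self, grad_logits: np.ndarray) -> None:
        self.stack.backward(grad_logits[:, :, None, None])

    def parameter_count(self) -> int:
        return enumerate_param_count(self.stack)

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        """Serialize weights, running BN statistics and the spec fingerprint."""
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        for i, layer in enumerate(_iter_layers(self.stack)):
            if isinstance(layer, BatchNorm2d):
                arrays[f"rm{i}"] = layer.running_mean
                arrays[f"rv{i}"] = layer.running_var
        meta = json.dumps(
            {"fingerprint": self.spec.fingerprint(), "variant": self.variant,
             "dropout_rate": self.spec.dropout_rate}
        )
        np.savez(path, _meta=np.frombuffer(meta.encode(), np.uint8), **arrays)

    @classmethod
    def load(cls, path, spec: NetworkSpec | None = None) -> "Network":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            if spec is None:
                fp = json.loads(meta["fingerprint"])
                spec = NetworkSpec(
                    rows=tuple(BlockSpec(*r) for r in fp["rows"]),
                    num_classes=fp["num_classes"],
                    dropout_rate=meta["dropout_rate"],
                    input_size=fp["input_size"],
                )
            if spec.fingerprint() != meta["fingerprint"]:
                raise ValueError("checkpoint architecture does not match spec")
            net = build_network(spec, meta["variant"])
            for i, p in enumerate(net.params):
                p[...] = data[f"p{i}"]
            for i, layer in enumerate(_iter_layers(net.stack)):
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean[...] = data[f"rm{i}"]
                    layer.running_var[...] = data[f"rv{i}"]
        return net


def _iter_layers(layer):
    from ._layers import Residual

    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    elif isinstance(layer, Residual):
        yield from _iter_layers(layer.inner)
    else:
        yield layer


def build_network(
    spec: NetworkSpec | None = None,
    variant: str = "full",
    seed: int | None = None,
    init: str = "kaiming",
) -> Network:
    """Assemble the classifier for a variant (``full``/``no_eca``/``no_dropout``)."""
    if spec is None:
        spec = NetworkSpec()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    rng = np.random.default_rng(0 if seed is None else seed)
    use_eca = variant != "no_eca"
    layers = [
        Conv2d(3, STEM_OUT, 3, stride=2, rng=rng, init=init),
        BatchNorm2d(STEM_OUT, init=init),
        ReLU6(),
    ]
    for row in spec.rows:
        layers.append(build_block(row, rng=rng, init=init, use_eca=use_eca))
    last = spec.rows[-1].out_channels
    layers += [
        Conv2d(last, HEAD_MID, 1, rng=rng, init=init),
        BatchNorm2d(HEAD_MID, init=init),
        ReLU6(),
        GlobalAvgPool(),
        Conv2d(HEAD_MID, HEAD_WIDE, 1, bias=True, rng=rng, init=init),
        ReLU6(),
    ]
    if variant != "no_dropout":
        layers.append(Dropout(spec.dropout_rate, rng=np.random.default_rng(
            (0 if seed is None else seed) + 1)))
    # final classifier starts at zero so training begins from uniform logits
    layers.append(Conv2d(HEAD_WIDE, spec.num_classes, 1, bias=True, init="zeros"))
    return Network(spec, variant, Sequential(layers))


def count_parameters(spec: NetworkSpec | None = None, variant: str = "full") -> int:
    """Analytic learnable-scalar total for a variant (closed form, no tensors built)."""
    if spec is None:
        spec = NetworkSpec()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    use_eca = variant != "no_eca"
    total = 3 * 3 * 3 * STEM_OUT + 2 * STEM_OUT  # stem conv + BN
    for row in spec.rows:
        total += block_param_count(row, use_eca=use_eca)
    last = spec.rows[-1].out_channels
    total += last * HEAD_MID + 2 * HEAD_MID                # 1x1 conv + BN
    total += HEAD_MID * HEAD_WIDE + HEAD_WIDE              # 1x1 conv + bias
    total += HEAD_WIDE * spec.num_classes + spec.num_classes  # classifier + bias
    return total


def parameter_ledger(spec: NetworkSpec | None = None, variant: str = "full"):
    """Per-row parameter table: list of (row label, count) plus the grand total."""
    if spec is None:
        spec = NetworkSpec()
    use_eca = variant != "no_eca"
    rows = [("stem Conv2d 3x3 s2 (3->16) + BN", 3 * 3 * 3 * STEM_OUT + 2 * STEM_OUT)]
    for i, r in enumerate(spec.rows):
        label = (f"{r.kind} {r.kernel}x{r.kernel} s{r.stride} "
                 f"({r.in_channels}->{r.expansion_channels}->{r.out_channels})")
        rows.append((f"block {i + 1}: {label}", block_param_count(r, use_eca=use_eca)))
    last = spec.rows[-1].out_channels
    rows.append((f"head Conv2d 1x1 ({last}->{HEAD_MID}) + BN",
                 last * HEAD_MID + 2 * HEAD_MID))
    rows.append((f"head Conv2d 1x1 ({HEAD_MID}->{HEAD_WIDE}) + bias",
                 HEAD_MID * HEAD_WIDE + HEAD_WIDE))
    rows.append((f"classifier Conv2d 1x1 ({HEAD_WIDE}->{spec.num_classes}) + bias",
                 HEAD_WIDE * spec.num_classes + spec.num_classes))
    total = sum(c for _, c in rows)
    return rows, total


def expected_output_sizes(spec: NetworkSpec | None = None):
    """Per-stage (H, W, C) trace matching the architecture table's output column."""
    if spec is None:
        spec = NetworkSpec()
    s = spec.input_size
    trace = []
    h = -(-s // 2)
    trace.append((h, h, STEM_OUT))  # stem
    for row in spec.rows:
        if row.stride == 2:
            h = -(-h // 2)
        trace.append((h, h, row.out_channels))
    trace.append((h, h, HEAD_MID))       # head 1x1 conv
    trace.append((1, 1, HEAD_MID))       # global average pool
    trace.append((1, 1, HEAD_WIDE))      # head 1x1 conv
    trace.append((1, 1, HEAD_WIDE))      # dropout
    trace.append((1, 1, spec.num_classes))
    return trace


def predict(network: Network, batch: np.ndarray):
    """Class labels and softmax scores for a batch of (N, 3, S, S) images."""
    batch = np.asarray(batch, np.float32)
    if batch.ndim != 4 or batch.shape[0] == 0:
        raise ValueError("expected a non-empty (N, 3, S, S) batch")
    logits = network.forward(batch, training=False)
    scores = softmax(logits)
    return scores.argmax(axis=1), scores
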