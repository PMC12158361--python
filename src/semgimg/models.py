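"""Declarative architecture specs for the single-, dual-, and three-stream CNNs.

A :class:`BranchSpec` describes one convolutional stream (conv/pool stack on
one image type); a :class:`ModelSpec` groups 1-3 branches with the fully
connected fusion head.  Specs can be traced layer by layer (shape
verification), counted (multiply-accumulate operations), serialized to
JSON, and instantiated as runnable numpy networks.

The reference three-stream configuration for 20-sample, 10-channel windows
is: a Sigimg branch on 20x100 images (3x3 convs) and GADF/MTF branches on
20x200 images (3x3 then 5x5 convs), each conv stack being
conv16 -> pool -> conv32 -> pool, fused by concatenating the flattened
branch features (4000 + 8000 + 8000 = 20000) into dense layers
4096 -> 2048 -> n_classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .windows import ConfigurationError

__all__ = [
    "ConvLayer",
    "PoolLayer",
    "BranchSpec",
    "ModelSpec",
    "mscnn_spec",
    "sscnn_spec",
    "dscnn_spec",
    "count_macs",
    "build_network",
]

STREAMS = ("sigimg", "gadf", "mtf")


@dataclass(frozen=True)
class ConvLayer:
    filters: int
    kernel: tuple[int, int]
    stride: int = 1
    pad: int = 0


@dataclass(frozen=True)
class PoolLayer:
    size: int = 2
    stride: int = 2


@dataclass(frozen=True)
class BranchSpec:
    """One convolutional stream: input image shape plus conv/pool stack."""

    stream: str
    input_shape: tuple[int, int, int]  # (H, W, 1)
    layers: tuple = ()

    def trace_shapes(self) -> list[tuple[int, int, int]]:
        """Output (H, W, C) after each layer, starting from the input."""
        h, w, c = self.input_shape
        shapes = [(h, w, c)]
        for layer in self.layers:
            if isinstance(layer, ConvLayer):
                kh, kw = layer.kernel
                h = (h + 2 * layer.pad - kh) // layer.stride + 1
                w = (w + 2 * layer.pad - kw) // layer.stride + 1
                c = layer.filters
            elif isinstance(layer, PoolLayer):
                h //= layer.stride
                w //= layer.stride
            else:  # pragma: no cover - spec construction guards this
                raise TypeError(f"unknown layer type: {layer!r}")
            shapes.append((h, w, c))
        return shapes

    @property
    def flatten_size(self) -> int:
        h, w, c = self.trace_shapes()[-1]
        return h * w * c


@dataclass(frozen=True)
class ModelSpec:
    """1-3 branches plus the fully connected fusion stack."""

    branches: tuple[BranchSpec, ...]
    fusion_fc: tuple[int, ...]  # hidden sizes then class_count
    dropout_rate: float = 0.5
    batchnorm: bool = True
    name: str = "model"

    def __post_init__(self) -> None:
        if not 1 <= len(self.branches) <= 3:
            raise ConfigurationError("a model has between 1 and 3 branches")
        if len(self.fusion_fc) < 1:
            raise ConfigurationError("fusion stack needs at least the output layer")

    @property
    def streams(self) -> tuple[str, ...]:
        return tuple(b.stream for b in self.branches)

    @property
    def fusion_input_size(self) -> int:
        return sum(b.flatten_size for b in self.branches)

    @property
    def class_count(self) -> int:
        return self.fusion_fc[-1]

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "dropout_rate": self.dropout_rate,
            "batchnorm": self.batchnorm,
            "fusion_fc": list(self.fusion_fc),
            "branches": [
                {
                    "stream": b.stream,
                    "input_shape": list(b.input_shape),
                    "layers": [
                        {"type": "conv", "filters": l.filters,
                         "kernel": list(l.kernel), "stride": l.stride,
                         "pad": l.pad}
                        if isinstance(l, ConvLayer)
                        else {"type": "pool", "size": l.size, "stride": l.stride}
                        for l in b.layers
                    ],
                }
                for b in self.branches
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        branches = []
        for b in d["branches"]:
            layers = []
            for l in b["layers"]:
                if l["type"] == "conv":
                    layers.append(ConvLayer(l["filters"], tuple(l["kernel"]),
                                            l["stride"], l["pad"]))
                else:
                    layers.append(PoolLayer(l["size"], l["stride"]))
            branches.append(BranchSpec(b["stream"], tuple(b["input_shape"]),
                                       tuple(layers)))
        return cls(branches=tuple(branches), fusion_fc=tuple(d["fusion_fc"]),
                   dropout_rate=d["dropout_rate"], batchnorm=d["batchnorm"],
                   name=d["name"])


def _scaled(filters: int, width_scale: float) -> int:
    return max(1, int(round(filters * width_scale)))


def _branch(stream: str, tw: int, channels: int, width_scale: float) -> BranchSpec:
    """Build the reference conv stack for one stream at the given geometry."""
    if stream == "sigimg":
        shape = (tw, channels * channels, 1)
        conv2 = ConvLayer(_scaled(32, width_scale), (3, 3), 1, 1)
    elif stream in ("gadf", "mtf"):
        shape = (tw, channels * tw, 1)
        conv2 = ConvLayer(_scaled(32, width_scale), (5, 5), 1, 2)
    else:
        raise ConfigurationError(f"unknown stream: {stream!r}")
    layers = (
        ConvLayer(_scaled(16, width_scale), (3, 3), 1, 1),
        PoolLayer(2, 2),
        conv2,
        PoolLayer(2, 2),
    )
    return BranchSpec(stream=stream, input_shape=shape, layers=layers)


def mscnn_spec(class_count: int = 52, tw: int = 20, channels: int = 10,
               width_scale: float = 1.0,
               fc_sizes: tuple[int, int] = (4096, 2048)) -> ModelSpec:
    """Three-stream CNN: Sigimg + GADF + MTF branches fused at dense layers.

    ``width_scale`` scales conv filter counts (0.5 gives the half-width
    desk-scale model); ``fc_sizes`` are the two hidden fusion widths.
    """
    if class_count < 2:
        raise ConfigurationError("need at least 2 classes")
    branches = tuple(_branch(s, tw, channels, width_scale) for s in STREAMS)
    return ModelSpec(branches=branches, fusion_fc=(*fc_sizes, class_count),
                     name="mscnn")


def sscnn_spec(stream: str, class_count: int = 52, tw: int = 20,
               channels: int = 10, width_scale: float = 1.0,
               fc_sizes: tuple[int, int] | None = None) -> ModelSpec:
    """Single-stream CNN; dense stack 1024/256 for Sigimg, 2048/512 for GADF/MTF."""
    if stream not in STREAMS:
        raise ConfigurationError(f"unknown stream: {stream!r}")
    if fc_sizes is None:
        fc_sizes = (1024, 256) if stream == "sigimg" else (2048, 512)
    branch = _branch(stream, tw, channels, width_scale)
    return ModelSpec(branches=(branch,), fusion_fc=(*fc_sizes, class_count),
                     name=f"sscnn-{stream}")


def dscnn_spec(streams: tuple[str, str], class_count: int = 52, tw: int = 20,
               channels: int = 10, width_scale: float = 1.0,
               fc_sizes: tuple[int, int] = (4096, 1024)) -> ModelSpec:
    """Dual-stream CNN; supported pairs are (sigimg, gadf) and (gadf, mtf)."""
    pair = tuple(streams)
    if pair not in (("sigimg", "gadf"), ("gadf", "mtf")):
        raise ConfigurationError(
            f"unsupported stream pair {pair!r}; use (sigimg, gadf) or (gadf, mtf)"
        )
    branches = tuple(_branch(s, tw, channels, width_scale) for s in pair)
    return ModelSpec(branches=branches, fusion_fc=(*fc_sizes, class_count),
                     name=f"dscnn-{'-'.join(pair)}")


def count_macs(spec: ModelSpec) -> int:
    """Multiply-accumulate count of all conv and dense layers.

    Convolution: outH*outW*outC*kh*kw*inC per layer; dense: in*out.
    Batch norm, biases, pooling and activations are not counted.
    """
    total = 0
    for branch in spec.branches:
        shapes = branch.trace_shapes()
        cin = shapes[0][2]
        for layer, (h, w, c) in zip(branch.layers, shapes[1:]):
            if isinstance(layer, ConvLayer):
                kh, kw = layer.kernel
                total += h * w * c * kh * kw * cin
            cin = c
    n_in = spec.fusion_input_size
    for n_out in spec.fusion_fc:
        total += n_in * n_out
        n_in = n_out
    return total


def build_network(spec: ModelSpec, seed: int = 0) -> nn.MultiStreamNet:
    """Instantiate a runnable numpy network from a declarative spec.

    Branch stacks are conv -> BN -> ReLU -> pool; the head applies dropout
    before every dense layer, with ReLU between hidden layers.  The final
    dense layer emits logits (softmax lives in the loss / predict path).
    """
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(rng.integers(0, 2**31))
    branches = []
    for bspec in spec.branches:
        layers: list[nn.Layer] = []
        cin = bspec.input_shape[2]
        for layer in bspec.layers:
            if isinstance(layer, ConvLayer):
                kh, kw = layer.kernel
                layers.append(nn.Conv2D(cin, layer.filters, kh, kw,
                                        pad=layer.pad, rng=rng))
                if spec.batchnorm:
                    layers.append(nn.BatchNorm(layer.filters))
                layers.append(nn.ReLU())
                cin = layer.filters
            else:
                layers.append(nn.MaxPool2x2())
        layers.append(nn.Flatten())
        branches.append(layers)
    head: list[nn.Layer] = []
    n_in = spec.fusion_input_size
    for i, n_out in enumerate(spec.fusion_fc):
        if spec.dropout_rate > 0:
            head.append(nn.Dropout(spec.dropout_rate, drop_rng))
        head.append(nn.Dense(n_in, n_out, rng))
        if i < len(spec.fusion_fc) - 1:
            head.append(nn.ReLU())
        n_in = n_out
    return nn.MultiStreamNet(branches=branches, head=head,
                             flatten_sizes=[b.flatten_size for b in spec.branches])
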