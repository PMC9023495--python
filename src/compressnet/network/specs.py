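"""Layered network specifications.

A :class:`NetworkSpec` is an ordered list of :class:`LayerSpec` entries —
convolutions, depthwise convolutions, pointwise convolutions and the two
trailing fully-connected layers (hidden projection to D, then the classifier
head to C) — plus a grouping of the conv trunk into blocks. The deepest
prunable layers define the top-down cut order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

CONV_KINDS = ("conv", "depthwise_conv", "pointwise_conv")
KINDS = CONV_KINDS + ("fully_connected",)


class SpecError(ValueError):
    """Raised when a network specification is internally inconsistent."""


@dataclass(frozen=True)
class LayerSpec:
    """One parameter layer.

    ``residual_from`` names an earlier layer whose post-activation output is
    added to this layer's post-norm output before this layer's activation
    (identity skip). ``prunable`` marks layers whose filters may be cut.
    """

    name: str
    kind: str
    out_filters: int
    kernel: int = 1
    stride: int = 1
    has_norm: bool = True
    activation: str = "relu"
    prunable: bool = False
    bias: bool = False
    residual_from: Optional[int] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SpecError(f"layer {self.name}: unknown kind {self.kind!r}")
        if self.out_filters < 1:
            raise SpecError(f"layer {self.name}: out_filters must be positive")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise SpecError(f"layer {self.name}: kernel must be a positive odd integer")
        if self.stride < 1:
            raise SpecError(f"layer {self.name}: stride must be positive")
        if self.activation not in ("relu", "linear"):
            raise SpecError(f"layer {self.name}: unknown activation {self.activation!r}")
        if self.kind == "pointwise_conv" and self.kernel != 1:
            raise SpecError(f"layer {self.name}: pointwise_conv requires kernel 1")
        if self.kind == "fully_connected" and self.has_norm:
            raise SpecError(f"layer {self.name}: fully_connected layers carry no norm")

    @property
    def pad(self) -> int:
        return self.kernel // 2


@dataclass(frozen=True)
class NetworkSpec:
    """Full network: conv trunk, hidden projection, classifier head.

    The penultimate layer must be a fully-connected layer of width
    ``hidden_dim`` (the hidden vector H); the last layer is the classifier
    head of width ``n_classes``. ``blocks`` groups trunk layer indices into
    the prunable block structure used by the top-down cut loop.
    """

    layers: Tuple[LayerSpec, ...]
    hidden_dim: int
    n_classes: int
    in_channels: int = 3
    input_size: int = 64
    global_pool: bool = True
    blocks: Tuple[Tuple[int, ...], ...] = ()

    def __post_init__(self):
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        if len(layers) < 2:
            raise SpecError("need at least a hidden layer and a classifier head")
        hidden, head = layers[-2], layers[-1]
        if hidden.kind != "fully_connected" or hidden.out_filters != self.hidden_dim:
            raise SpecError("penultimate layer must be fully_connected with hidden_dim outputs")
        if head.kind != "fully_connected" or head.out_filters != self.n_classes:
            raise SpecError("last layer must be the fully_connected classifier head")
        if any(l.kind == "fully_connected" for l in layers[:-2]):
            raise SpecError("exactly one hidden vector may precede the classifier head")
        # channel chaining
        c = self.in_channels
        for i, l in enumerate(layers[:-2]):
            if l.kind == "depthwise_conv" and l.out_filters != c:
                raise SpecError(
                    f"layer {l.name}: depthwise_conv out_filters ({l.out_filters}) "
                    f"must equal input channels ({c})")
            if l.residual_from is not None:
                if not (0 <= l.residual_from < i) and l.residual_from != -1:
                    raise SpecError(f"layer {l.name}: bad residual_from index")
            c = l.out_filters
        for l in layers[-2:]:
            if l.prunable:
                raise SpecError(f"layer {l.name}: fully-connected layers are not prunable")
        # layers feeding residual joins must not be prunable
        feeds = {l.residual_from for l in layers if l.residual_from is not None}
        for i in feeds:
            if i >= 0 and layers[i].prunable:
                raise SpecError(f"layer {layers[i].name} feeds a residual join; not prunable")

    # -- derived geometry ----------------------------------------------------
    def in_filters(self, i: int) -> int:
        """Input channel count of layer ``i``."""
        if i == 0:
            return self.in_channels
        return self.layers[i - 1].out_filters

    def spatial_sizes(self) -> list:
        """Spatial side of each trunk layer's output feature map."""
        s = self.input_size
        sizes = []
        for l in self.layers[:-2]:
            s = (s + 2 * l.pad - l.kernel) // l.stride + 1
            sizes.append(s)
        return sizes

    def trunk_out_dim(self) -> int:
        """Flattened (or pooled) feature dimension entering the hidden layer."""
        if not self.layers[:-2]:
            c, side = self.in_channels, self.input_size
        else:
            c = self.layers[-3].out_filters
            side = self.spatial_sizes()[-1]
        return c if self.global_pool else c * side * side

    @property
    def hidden_index(self) -> int:
        return len(self.layers) - 2

    @property
    def head_index(self) -> int:
        return len(self.layers) - 1

    def prunable_layers(self) -> list:
        return [i for i, l in enumerate(self.layers) if l.prunable]

    @property
    def n_prunable(self) -> int:
        """T — the number of prunable filter layers."""
        return len(self.prunable_layers())

    def with_layer(self, i: int, **changes) -> "NetworkSpec":
        layers = list(self.layers)
        layers[i] = dataclasses.replace(layers[i], **changes)
        return dataclasses.replace(self, layers=tuple(layers))


# ---------------------------------------------------------------------------
# Reference architectures
# ---------------------------------------------------------------------------

def desk_student(n_classes: int = 10, hidden_dim: int = 64, input_size: int = 64,
                 block_cfg: Sequence[Tuple[int, int, int]] = ((16, 12, 2), (24, 16, 2), (32, 24, 1)),
                 stem_filters: int = 8, final_filters: int = 32) -> NetworkSpec:
    """Small depthwise-separable, inverted-bottleneck style network.

    ``block_cfg`` rows are (expansion_filters, project_filters, stride); the
    expansion pointwise conv of each block is the prunable filter bank and the
    block's final pointwise conv serves as the reference layer for scoring.
    """
    layers = [LayerSpec("stem", "conv", stem_filters, kernel=3, stride=2)]
    blocks = [(0,)]
    for b, (expand, project, stride) in enumerate(block_cfg):
        i0 = len(layers)
        layers.append(LayerSpec(f"b{b}.expand", "pointwise_conv", expand, prunable=True))
        layers.append(LayerSpec(f"b{b}.dw", "depthwise_conv", expand, kernel=3, stride=stride))
        layers.append(LayerSpec(f"b{b}.project", "pointwise_conv", project, activation="linear"))
        blocks.append(tuple(range(i0, i0 + 3)))
    i0 = len(layers)
    layers.append(LayerSpec("final", "pointwise_conv", final_filters))
    blocks.append((i0,))
    layers.append(LayerSpec("hidden", "fully_connected", hidden_dim,
                            has_norm=False, bias=True, activation="relu"))
    layers.append(LayerSpec("head", "fully_connected", n_classes,
                            has_norm=False, bias=True, activation="linear"))
    return NetworkSpec(tuple(layers), hidden_dim=hidden_dim, n_classes=n_classes,
                       input_size=input_size, blocks=tuple(blocks))


def desk_teacher(n_classes: int = 10, hidden_dim: int = 64, input_size: int = 64,
                 widths: Sequence[int] = (16, 32, 64)) -> NetworkSpec:
    """Residual-style teacher: stem + one identity-skip block per width stage.

    Deeper and wider than :func:`desk_student`; shares ``hidden_dim`` so the
    hidden-vector transfer loss applies without an adapter.
    """
    layers = [LayerSpec("stem", "conv", widths[0], kernel=3, stride=2)]
    blocks = [(0,)]
    for s, w in enumerate(widths):
        if s > 0:
            i0 = len(layers)
            layers.append(LayerSpec(f"s{s}.down", "conv", w, kernel=3, stride=2))
            blocks.append((i0,))
        i0 = len(layers)
        entry = i0 - 1  # output of the previous layer is the skip source
        layers.append(LayerSpec(f"s{s}.conv1", "conv", w, kernel=3, prunable=True))
        layers.append(LayerSpec(f"s{s}.conv2", "conv", w, kernel=3, residual_from=entry))
        blocks.append((i0, i0 + 1))
    layers.append(LayerSpec("hidden", "fully_connected", hidden_dim,
                            has_norm=False, bias=True, activation="relu"))
    layers.append(LayerSpec("head", "fully_connected", n_classes,
                            has_norm=False, bias=True, activation="linear"))
    return NetworkSpec(tuple(layers), hidden_dim=hidden_dim, n_classes=n_classes,
                       input_size=input_size, blocks=tuple(blocks))


_MBV2_SETTINGS = (  # (expansion factor, out channels, repeats, first stride)
    (1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
    (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1),
)


def student_reference(n_classes: int = 95, hidden_dim: int = 1280,
                      input_size: int = 224) -> NetworkSpec:
    """Full-scale depthwise-separable student with 17 prunable blocks."""
    layers = [LayerSpec("stem", "conv", 32, kernel=3, stride=2)]
    blocks = [(0,)]
    c_in, b = 32, 0
    for t, c, n, s in _MBV2_SETTINGS:
        for r in range(n):
            stride = s if r == 0 else 1
            expand = max(c_in * t, c_in)
            i0 = len(layers)
            skip = stride == 1 and c_in == c
            entry = i0 - 1
            layers.append(LayerSpec(f"b{b}.expand", "pointwise_conv", expand, prunable=True))
            layers.append(LayerSpec(f"b{b}.dw", "depthwise_conv", expand, kernel=3, stride=stride))
            layers.append(LayerSpec(f"b{b}.project", "pointwise_conv", c, activation="linear",
                                    residual_from=entry if skip else None))
            blocks.append((i0, i0 + 1, i0 + 2))
            c_in, b = c, b + 1
    i0 = len(layers)
    layers.append(LayerSpec("final", "pointwise_conv", 1280))
    blocks.append((i0,))
    layers.append(LayerSpec("hidden", "fully_connected", hidden_dim,
                            has_norm=False, bias=True, activation="relu"))
    layers.append(LayerSpec("head", "fully_connected", n_classes,
                            has_norm=False, bias=True, activation="linear"))
    return NetworkSpec(tuple(layers), hidden_dim=hidden_dim, n_classes=n_classes,
                       input_size=input_size, blocks=tuple(blocks))


def teacher_reference(n_classes: int = 95, hidden_dim: int = 1280,
                      input_size: int = 224,
                      widths: Sequence[int] = (64, 128, 256, 512),
                      depth: int = 2) -> NetworkSpec:
    """Full-scale residual-style teacher (deeper/wider than the student)."""
    layers = [LayerSpec("stem", "conv", widths[0], kernel=7, stride=4)]
    blocks = [(0,)]
    for s, w in enumerate(widths):
        if s > 0:
            i0 = len(layers)
            layers.append(LayerSpec(f"s{s}.down", "conv", w, kernel=3, stride=2))
            blocks.append((i0,))
        for d in range(depth):
            i0 = len(layers)
            entry = i0 - 1
            layers.append(LayerSpec(f"s{s}.{d}.conv1", "conv", w, kernel=3, prunable=True))
            layers.append(LayerSpec(f"s{s}.{d}.conv2", "conv", w, kernel=3, residual_from=entry))
            blocks.append((i0, i0 + 1))
    layers.append(LayerSpec("hidden", "fully_connected", hidden_dim,
                            has_norm=False, bias=True, activation="relu"))
    layers.append(LayerSpec("head", "fully_connected", n_classes,
                            has_norm=False, bias=True, activation="linear"))
    return NetworkSpec(tuple(layers), hidden_dim=hidden_dim, n_classes=n_classes,
                       input_size=input_size, blocks=tuple(blocks))
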