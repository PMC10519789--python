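"""Declarative construction of the FCA-EfficientNet model family.

Any member of the family — from the squeeze-excitation baseline (B0) to the
final trimmed coordinate-attention network — is described by an
:class:`ArchitectureSpec` and materialised by :func:`build_model`.  The
module also accounts for model complexity (:func:`count_params`,
:func:`count_macs`) and enumerates the layer-count search space over the
three deepest repeated stages.

The backbone plan (seven bottleneck stages between a 3x3/stride-2 stem and a
1x1 -> pool -> fully-connected head) follows the standard B0 layout:

====== ======== ====== ======= ====== ========
stage  expand t kernel stride  chans  repeats
====== ======== ====== ======= ====== ========
2      1        3      1       16     1
3      6        3      2       24     2
4      6        5      2       40     2
5      6        3      2       80     3
6      6        5      1       112    3
7      6        5      2       192    4
8      6        3      1       320    1
====== ======== ====== ======= ====== ========

Stages 5-7 are the trimmable ones; their repeat counts form the
``layers_567`` triple (original (3, 3, 4), optimum (2, 3, 2)).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import yaml

from . import autograd as ag
from .autograd import Tensor
from .blocks import (AdaptiveFusion, BlockConfig, CoordinateAttention,
                     FullConvCoordAttention, MBConvBlock, SqueezeExcitation,
                     attention_mid_channels, make_act, make_norm)
from .layers import (Conv2d, Dropout, GlobalAvgPool, Linear, Module)

# (expansion, out_channels, kernel, stride, repeats)
_STAGE_PLAN = (
    (1, 16, 3, 1, 1),
    (6, 24, 3, 2, 2),
    (6, 40, 5, 2, 2),
    (6, 80, 3, 2, 3),
    (6, 112, 5, 1, 3),
    (6, 192, 5, 2, 4),
    (6, 320, 3, 1, 1),
)
_TRIMMABLE = {3: 0, 4: 1, 5: 2}          # stage-plan index -> layers_567 slot
_ORIGINAL_567 = (3, 3, 4)
_STEM_CHANNELS = 32
_HEAD_CHANNELS = 1280
_TOTAL_BLOCKS_ORIGINAL = 16              # denominators of the drop-rate ramp
_BRANCH_DROP_MAX = 0.2
_CLASSIFIER_DROPOUT = 0.2

AF_NODES = ("none", "node1", "node2", "node3")


@dataclass(frozen=True)
class StageSpec:
    """Resolved configuration of one backbone stage."""

    operator: str                 # 'stem_conv' | 'mbconv' | 'head'
    expansion: int = 0
    kernel: int = 0
    out_channels: int = 0
    repeats: int = 1
    stride: int = 1
    in_resolution: int = 0
    drop_factor: float = 0.0      # branch-drop rate of the stage's first block


@dataclass(frozen=True)
class ArchitectureSpec:
    """Complete declarative description of a model in the family."""

    attention: str = "fca"                 # 'se' | 'ca' | 'fca' | 'none'
    norm: str = "ln"                       # 'bn' | 'ln'
    activation: str = "gelu"               # 'swish' | 'gelu'
    af_node: str = "node2"                 # 'none' | 'node1' | 'node2' | 'node3'
    layers_567: tuple[int, int, int] = (2, 3, 2)
    num_classes: int = 6
    input_resolution: int = 224

    def __post_init__(self):
        if self.attention not in ("se", "ca", "fca", "none"):
            raise ValueError(f"unknown attention {self.attention!r}")
        if self.norm not in ("bn", "ln"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.activation not in ("swish", "gelu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.af_node not in AF_NODES:
            raise ValueError(f"af_node must be one of {AF_NODES}, got {self.af_node!r}")
        t = tuple(self.layers_567)
        object.__setattr__(self, "layers_567", t)
        if len(t) != 3 or any(not isinstance(v, int) for v in t):
            raise ValueError("layers_567 must be a triple of ints")
        if any(v < 1 for v in t) or any(v > o for v, o in zip(t, _ORIGINAL_567)):
            raise ValueError(
                f"layers_567 must be elementwise within [1, {_ORIGINAL_567}], got {t}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if self.input_resolution < 32 or self.input_resolution % 32:
            raise ValueError("input_resolution must be a positive multiple of 32")

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {"attention": self.attention, "norm": self.norm,
                "activation": self.activation, "af_node": self.af_node,
                "layers_567": list(self.layers_567),
                "num_classes": self.num_classes,
                "input_resolution": self.input_resolution}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        if "layers_567" in d:
            d["layers_567"] = tuple(d["layers_567"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def baseline_b0(num_classes: int = 6, input_resolution: int = 224) -> ArchitectureSpec:
    """The unmodified squeeze-excitation baseline."""
    return ArchitectureSpec(attention="se", norm="bn", activation="swish",
                            af_node="none", layers_567=_ORIGINAL_567,
                            num_classes=num_classes,
                            input_resolution=input_resolution)


def final_spec(num_classes: int = 6, input_resolution: int = 224) -> ArchitectureSpec:
    """The published end configuration: FCA attention, LN + GELU, fusion at
    the post-first-block node, trimmed (2, 3, 2) deep stages."""
    return ArchitectureSpec(num_classes=num_classes,
                            input_resolution=input_resolution)


def block_configs(spec: ArchitectureSpec) -> list[BlockConfig]:
    """Flatten the stage plan into per-block configurations.

    When a stage is trimmed, its leading (strided, channel-changing) block is
    kept and repeats are removed from the tail.  The branch-drop rate ramps
    linearly as 0.2 * i / 16 with i the 1-based position of the block in the
    built network — for the trimmed (2, 3, 2) network this yields the stage
    factors 0.0125, 0.025, 0.05, 0.075, 0.1, 0.1375, 0.1625.
    """
    cfgs: list[BlockConfig] = []
    c_in = _STEM_CHANNELS
    res = -(-spec.input_resolution // 2)   # after the stride-2 stem
    i = 0
    for stage_idx, (t, c_out, k, s, repeats) in enumerate(_STAGE_PLAN):
        if stage_idx in _TRIMMABLE:
            repeats = spec.layers_567[_TRIMMABLE[stage_idx]]
        for r in range(repeats):
            i += 1
            cfgs.append(BlockConfig(
                in_channels=c_in if r == 0 else c_out,
                out_channels=c_out,
                expansion=t,
                kernel=k,
                stride=s if r == 0 else 1,
                attention=spec.attention,
                drop_rate=_BRANCH_DROP_MAX * i / _TOTAL_BLOCKS_ORIGINAL,
                in_resolution=res,
            ))
            if r == 0 and s == 2:
                res = -(-res // 2)
        c_in = c_out
    return cfgs


def stage_specs(spec: ArchitectureSpec) -> list[StageSpec]:
    """Per-stage summary rows (stem + 7 bottleneck stages + head)."""
    cfgs = block_configs(spec)
    rows = [StageSpec("stem_conv", kernel=3, out_channels=_STEM_CHANNELS,
                      stride=2, in_resolution=spec.input_resolution)]
    pos = 0
    for stage_idx, (t, c_out, k, s, repeats) in enumerate(_STAGE_PLAN):
        if stage_idx in _TRIMMABLE:
            repeats = spec.layers_567[_TRIMMABLE[stage_idx]]
        first = cfgs[pos]
        rows.append(StageSpec("mbconv", expansion=t, kernel=k, out_channels=c_out,
                              repeats=repeats, stride=s,
                              in_resolution=first.in_resolution,
                              drop_factor=first.drop_rate))
        pos += repeats
    rows.append(StageSpec("head", kernel=1, out_channels=_HEAD_CHANNELS,
                          in_resolution=cfgs[-1].out_resolution))
    return rows


class FCAEfficientNet(Module):
    """A built classifier of the family; see :func:`build_model`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.stem_conv = Conv2d(3, _STEM_CHANNELS, 3, stride=2, padding="same",
                                bias=False, rng=rng)
        self.stem_norm = make_norm(spec.norm, _STEM_CHANNELS)
        self.act = make_act(spec.activation)
        cfgs = block_configs(spec)
        self.blocks = [MBConvBlock(c, spec.norm, spec.activation, rng=rng)
                       for c in cfgs]
        self.head_conv = Conv2d(cfgs[-1].out_channels, _HEAD_CHANNELS, 1,
                                bias=False, rng=rng)
        self.head_norm = make_norm(spec.norm, _HEAD_CHANNELS)
        self.pool = GlobalAvgPool()
        self.dropout = Dropout(_CLASSIFIER_DROPOUT, rng=rng)
        self.fc = Linear(_HEAD_CHANNELS, spec.num_classes, rng=rng)
        if spec.af_node == "none":
            self.af = None
            self._af_after = None
        else:
            # node1: after the stem conv; node2: after the first bottleneck
            # block; node3: after the second bottleneck block (stride-2, so
            # the pooled branch shrinks by 4).
            node_channels = {"node1": _STEM_CHANNELS,
                             "node2": cfgs[0].out_channels,
                             "node3": cfgs[1].out_channels}[spec.af_node]
            pool_factor = 4 if spec.af_node == "node3" else 2
            self.af = AdaptiveFusion(3, node_channels, pool_factor, rng=rng)
            self._af_after = {"node1": "stem", "node2": "block1",
                              "node3": "block2"}[spec.af_node]
        self.seed_stochastic(seed)

    # -- plumbing ------------------------------------------------------------
    def seed_stochastic(self, seed: int) -> None:
        """Reseed every stochastic layer (branch drops, classifier dropout)."""
        seq = np.random.SeedSequence(seed)
        mods = [self.dropout] + [b.drop for b in self.blocks]
        for m, child in zip(mods, seq.spawn(len(mods))):
            m.rng = np.random.default_rng(child)

    def layer_names(self) -> list[str]:
        return (["stem"] + [f"block{i + 1}" for i in range(len(self.blocks))]
                + ["head"])

    # -- forward -------------------------------------------------------------
    def forward(self, x: Tensor, capture: str | None = None) -> Tensor:
        if capture is not None and capture not in self.layer_names():
            raise ValueError(f"unknown layer {capture!r}; "
                             f"expected one of {self.layer_names()}")
        captured: Tensor | None = None
        x_in = x
        h = self.act(self.stem_norm(self.stem_conv(x)))
        if self._af_after == "stem":
            h = self.af(x_in, h)
        if capture == "stem":
            captured = h
        for i, block in enumerate(self.blocks):
            h = block(h)
            name = f"block{i + 1}"
            if self._af_after == name:
                h = self.af(x_in, h)
            if capture == name:
                captured = h
        h = self.act(self.head_norm(self.head_conv(h)))
        if capture == "head":
            captured = h
        feats = self.dropout(self.pool(h))
        logits = self.fc(feats)
        self._captured = captured
        return logits

    def predict_logits(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference over an (N, 3, H, W) array, without building a graph."""
        self.eval()
        outs = []
        with ag.no_grad():
            for start in range(0, len(images), batch_size):
                xb = Tensor(images[start:start + batch_size])
                outs.append(self.forward(xb).numpy())
        return np.concatenate(outs, axis=0)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> FCAEfficientNet:
    """Materialise a trainable classifier from a declarative spec.

    Building twice with the same spec and seed yields identical parameters.
    """
    return FCAEfficientNet(spec, seed=seed)


def count_params(model: FCAEfficientNet) -> int:
    """Exact number of trainable scalars in a built model."""
    return model.num_params()


@dataclass
class ComplexityReport:
    params: int
    macs: int

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def macs_m(self) -> float:
        return self.macs / 1e6

    def __str__(self):
        return f"{self.params_m:.2f}M params, {self.macs_m:.2f}M MACs"


def count_macs(model: FCAEfficientNet, input_resolution: int | None = None) -> int:
    """Multiply-accumulate count of one forward pass.

    Convention: convolution and linear layers contribute their dense MAC
    counts; every normalisation layer contributes 2 ops per output element
    (centre/scale and affine); pooling and activations count zero.
    """
    spec = model.spec
    res = input_resolution or spec.input_resolution
    if res != spec.input_resolution and spec.attention == "fca":
        raise ValueError("a full-conv coordinate-attention model is bound to "
                         "its build resolution")
    macs = 0
    r = -(-res // 2)
    macs += 9 * 3 * _STEM_CHANNELS * r * r           # stem conv
    macs += 2 * _STEM_CHANNELS * r * r               # stem norm
    if model.af is not None:
        pf = model.af.pool_factor
        node_res = res // pf
        macs += 3 * model.af.proj.out_channels * node_res * node_res
    for block in model.blocks:
        cfg = block.cfg
        ri, ro = cfg.in_resolution, cfg.out_resolution
        ce = cfg.expanded
        if cfg.expansion != 1:
            macs += cfg.in_channels * ce * ri * ri   # expand conv
            macs += 2 * ce * ri * ri                 # its norm
        macs += cfg.kernel ** 2 * ce * ro * ro       # depthwise conv
        macs += 2 * ce * ro * ro                     # its norm
        att = block.attention
        if isinstance(att, SqueezeExcitation):
            sq = att.reduce.out_channels
            macs += ce * sq + sq * ce
        elif isinstance(att, CoordinateAttention):   # includes the FCA subclass
            mid = att.mid
            if isinstance(att, FullConvCoordAttention):
                macs += 2 * ce * ro * ro             # the two directional convs
            macs += ce * mid * (ro + ro)             # mid conv on the (H+W) map
            macs += mid * ce * ro + mid * ce * ro    # the two gate convs
        macs += ce * cfg.out_channels * ro * ro      # project conv
        macs += 2 * cfg.out_channels * ro * ro       # its norm
    r_out = model.blocks[-1].cfg.out_resolution
    macs += model.blocks[-1].cfg.out_channels * _HEAD_CHANNELS * r_out * r_out
    macs += 2 * _HEAD_CHANNELS * r_out * r_out
    macs += _HEAD_CHANNELS * spec.num_classes
    return int(macs)


def complexity(spec: ArchitectureSpec) -> ComplexityReport:
    model = build_model(spec)
    return ComplexityReport(count_params(model), count_macs(model))


def enumerate_search_space(base: ArchitectureSpec | None = None) -> list[ArchitectureSpec]:
    """The twelve trimmed variants over stages 5-7, in lexicographic order
    (stage-5 repeats in {2, 3}, stage-6 in {2, 3}, stage-7 in {2, 3, 4})."""
    base = base or final_spec()
    out = []
    for s5 in (2, 3):
        for s6 in (2, 3):
            for s7 in (2, 3, 4):
                out.append(replace(base, layers_567=(s5, s6, s7)))
    return out


def summarize(spec: ArchitectureSpec) -> str:
    """Human-readable per-stage table plus complexity totals."""
    model = build_model(spec)
    rows = stage_specs(spec)
    att = spec.attention.upper()
    op_names = {"stem_conv": "Conv3x3",
                "head": "Conv1x1 & Pooling & FC"}
    buf = io.StringIO()
    header = (f"{'Stage':>5}  {'Operator':<28} {'Resolution':>11} "
              f"{'Channels':>8} {'Layers':>6} {'Drop':>7}")
    buf.write(header + "\n" + "-" * len(header) + "\n")
    for i, row in enumerate(rows, start=1):
        if row.operator == "mbconv":
            name = f"{att + '-' if att != 'NONE' else ''}MBConv{row.expansion}, " \
                   f"k{row.kernel}x{row.kernel}"
        else:
            name = op_names[row.operator]
        buf.write(f"{i:>5}  {name:<28} {row.in_resolution:>7}x{row.in_resolution:<3} "
                  f"{row.out_channels:>8} {row.repeats:>6} {row.drop_factor:>7.4f}\n")
    rep = ComplexityReport(count_params(model), count_macs(model))
    buf.write("-" * len(header) + "\n")
    buf.write(f"attention={spec.attention} norm={spec.norm} "
              f"act={spec.activation} af_node={spec.af_node} "
              f"layers_567={spec.layers_567} classes={spec.num_classes}\n")
    buf.write(f"total: {rep}\n")
    return buf.getvalue()
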