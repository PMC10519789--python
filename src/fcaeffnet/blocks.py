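"""Building blocks of the FCA-EfficientNet family.

The mobile inverted bottleneck (MBConv) expands channels with a 1x1
convolution, filters spatially with a depthwise k x k convolution, applies a
channel-attention module, and projects back with a 1x1 convolution; a
residual connection (with stochastic depth) closes the block when shapes
allow.  Three attention variants are provided:

* ``SqueezeExcitation`` — global average pool + two-layer gating network.
* ``CoordinateAttention`` — pools the expanded map separately along height
  and width so the gates retain positional information.
* ``FullConvCoordAttention`` — the fully-convolution-based variant: the two
  directional global average pools are replaced by *full-extent* depthwise
  convolutions with kernels (1, W) and (H, 1).  Because those kernels span
  the whole spatial extent, a block is bound to the resolution it was built
  for.

``AdaptiveFusion`` merges a max-pooled, 1x1-projected copy of the network
input into a shallow backbone node as ``w1 * pooled + w2 * backbone`` with
two unconstrained learnable scalars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (BatchNorm2d, Conv2d, DepthwiseConv2d, GELU, Identity,
                     LayerNorm2d, Module, StochasticDepth, Swish)

#: channel-reduction divisor of the coordinate-attention mid convolution and
#: the floor on its width.  Calibrated so that the CA and FCA model variants
#: reach their published parameter totals; see docs/methods.md.
ATTENTION_REDUCTION = 16
ATTENTION_MIN_WIDTH = 8


def attention_mid_channels(channels: int,
                           reduction: int = ATTENTION_REDUCTION,
                           floor: int = ATTENTION_MIN_WIDTH) -> int:
    return max(floor, channels // reduction)


def make_norm(kind: str, channels: int) -> Module:
    if kind == "bn":
        return BatchNorm2d(channels)
    if kind == "ln":
        return LayerNorm2d(channels)
    raise ValueError(f"unknown norm {kind!r}; expected 'bn' or 'ln'")


def make_act(kind: str) -> Module:
    if kind == "swish":
        return Swish()
    if kind == "gelu":
        return GELU()
    raise ValueError(f"unknown activation {kind!r}; expected 'swish' or 'gelu'")


# -- functional surface --------------------------------------------------------

def swish(x):
    """Elementwise x * sigmoid(x); accepts arrays or tensors."""
    out = ag.swish(ag.as_tensor(x))
    return out if isinstance(x, Tensor) else out.numpy()


def gelu(x):
    """Elementwise x * Phi(x), exact standard-normal CDF."""
    out = ag.gelu(ag.as_tensor(x))
    return out if isinstance(x, Tensor) else out.numpy()


def normalize(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
              eps: float = 1e-6, mode: str = "ln") -> np.ndarray:
    """One-shot normalisation of a (N, C, H, W) batch.

    ``mode='bn'`` uses batch statistics per channel (training semantics);
    ``mode='ln'`` uses per-sample statistics over (C, H, W).  ``gamma`` and
    ``beta`` are per-channel.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    fn = ag.layer_norm if mode == "ln" else ag.batch_norm
    if mode not in ("ln", "bn"):
        raise ValueError(f"unknown mode {mode!r}")
    return fn(Tensor(x), Tensor(gamma), Tensor(beta), eps).numpy()


# -- attention modules ---------------------------------------------------------

class SqueezeExcitation(Module):
    """Global-pool channel gating; squeeze width is ``max(1, block_in // 4)``."""

    def __init__(self, channels: int, block_in_channels: int, act: str = "swish",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        squeeze = max(1, block_in_channels // 4)
        self.reduce = Conv2d(channels, squeeze, 1, bias=True, rng=rng)
        self.act = make_act(act)
        self.expand = Conv2d(squeeze, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        s = ag.reshape(ag.mean(x, axis=(2, 3)), (n, c, 1, 1))
        s = ag.sigmoid(self.expand(self.act(self.reduce(s))))
        return ag.mul(x, s)


class CoordinateAttention(Module):
    """Directional average pooling -> shared mid conv -> two sigmoid gates.

    All three 1x1 convolutions are bias-free and unnormalised (calibrated
    against the published model sizes); the mid activation is the model-wide
    nonlinearity.
    """

    def __init__(self, channels: int, act: str = "swish",
                 reduction: int = ATTENTION_REDUCTION,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        mid = attention_mid_channels(channels, reduction)
        self.channels, self.mid = channels, mid
        self.conv_mid = Conv2d(channels, mid, 1, bias=False, rng=rng)
        self.act = make_act(act)
        self.conv_h = Conv2d(mid, channels, 1, bias=False, rng=rng)
        self.conv_w = Conv2d(mid, channels, 1, bias=False, rng=rng)

    def _directional(self, x: Tensor) -> tuple[Tensor, Tensor]:
        zh = ag.mean(x, axis=3, keepdims=True)                # (n, c, h, 1)
        zw = ag.mean(x, axis=2, keepdims=True)                # (n, c, 1, w)
        return zh, zw

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        zh, zw = self._directional(x)
        zw_col = ag.reshape(zw, (n, c, w, 1))
        f = self.act(self.conv_mid(ag.concat([zh, zw_col], axis=2)))
        fh, fw = f[:, :, :h, :], f[:, :, h:, :]
        gh = ag.sigmoid(self.conv_h(fh))                      # (n, c, h, 1)
        gw = ag.reshape(ag.sigmoid(self.conv_w(fw)), (n, c, 1, w))
        return ag.mul(ag.mul(x, gh), gw)


class FullConvCoordAttention(CoordinateAttention):
    """Coordinate attention whose directional pools are learnable full-extent
    depthwise convolutions; bound to the (height, width) given at build time."""

    def __init__(self, channels: int, height: int, width: int, act: str = "swish",
                 reduction: int = ATTENTION_REDUCTION,
                 rng: np.random.Generator | None = None):
        super().__init__(channels, act, reduction, rng=rng)
        self.height, self.width = height, width
        self.dir_h = DepthwiseConv2d(channels, (1, width), bias=False, rng=rng)
        self.dir_w = DepthwiseConv2d(channels, (height, 1), bias=False, rng=rng)

    def _directional(self, x: Tensor) -> tuple[Tensor, Tensor]:
        if x.shape[2] != self.height or x.shape[3] != self.width:
            raise ValueError(
                f"input is {x.shape[2]}x{x.shape[3]} but the directional kernels "
                f"were built for {self.height}x{self.width}")
        return self.dir_h(x), self.dir_w(x)


@dataclass(frozen=True)
class BlockConfig:
    """Configuration of one inverted-residual block."""

    in_channels: int
    out_channels: int
    expansion: int           # 1 or 6
    kernel: int              # 3 or 5
    stride: int              # 1 or 2
    attention: str           # 'se' | 'ca' | 'fca' | 'none'
    drop_rate: float = 0.0   # stochastic-depth rate of the residual branch
    in_resolution: int = 224  # spatial size of the block input (square)

    def __post_init__(self):
        if self.expansion not in (1, 6):
            raise ValueError("expansion factor must be 1 or 6")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if not 0.0 <= self.drop_rate < 1.0:
            raise ValueError("drop_rate must be in [0, 1)")

    @property
    def expanded(self) -> int:
        return self.in_channels * self.expansion

    @property
    def has_residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels

    @property
    def out_resolution(self) -> int:
        return -(-self.in_resolution // self.stride)


class MBConvBlock(Module):
    """Inverted residual block with configurable attention/norm/activation."""

    def __init__(self, cfg: BlockConfig, norm: str = "bn", act: str = "swish",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        ce = cfg.expanded
        if cfg.expansion != 1:
            self.expand_conv = Conv2d(cfg.in_channels, ce, 1, bias=False, rng=rng)
            self.expand_norm = make_norm(norm, ce)
        else:
            self.expand_conv = None
            self.expand_norm = None
        self.act = make_act(act)
        self.dw = DepthwiseConv2d(ce, cfg.kernel, cfg.stride, "same", rng=rng)
        self.dw_norm = make_norm(norm, ce)
        res = cfg.out_resolution
        if cfg.attention == "se":
            self.attention: Module = SqueezeExcitation(ce, cfg.in_channels, act, rng=rng)
        elif cfg.attention == "ca":
            self.attention = CoordinateAttention(ce, act, rng=rng)
        elif cfg.attention == "fca":
            self.attention = FullConvCoordAttention(ce, res, res, act, rng=rng)
        elif cfg.attention == "none":
            self.attention = Identity()
        else:
            raise ValueError(f"unknown attention {cfg.attention!r}")
        self.project = Conv2d(ce, cfg.out_channels, 1, bias=False, rng=rng)
        self.project_norm = make_norm(norm, cfg.out_channels)
        if cfg.has_residual:
            # residual branches start as identity (zero-init of the final
            # affine scale), the standard deep-residual training aid
            self.project_norm.gamma.data[:] = 0.0
        self.drop = StochasticDepth(cfg.drop_rate, rng=rng)

    def expanded_features(self, x: Tensor) -> Tensor:
        """The feature map the attention module sees (post expand + depthwise)."""
        h = x
        if self.expand_conv is not None:
            h = self.act(self.expand_norm(self.expand_conv(h)))
        return self.act(self.dw_norm(self.dw(h)))

    def forward(self, x: Tensor) -> Tensor:
        xhat = self.expanded_features(x)
        h = self.attention(xhat)
        h = self.project_norm(self.project(h))
        if self.cfg.has_residual:
            if h.shape != x.shape:
                raise ValueError(
                    f"residual shape mismatch: {x.shape} vs {h.shape}")
            h = ag.add(x, self.drop(h))
        return h


class AdaptiveFusion(Module):
    """Weighted fusion of a pooled/projected copy of the input into a node.

    ``forward(x_input, backbone_out)`` max-pools the raw input by
    ``pool_factor`` (2 for nodes at half resolution), projects its channels
    with a bare 1x1 convolution, and returns ``w1 * pooled + w2 * backbone``.
    ``w1``/``w2`` start at 1.0 and are unconstrained.
    """

    def __init__(self, in_channels: int, node_channels: int, pool_factor: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.pool_factor = pool_factor
        self.proj = Conv2d(in_channels, node_channels, 1, bias=True, rng=rng)
        self.w1 = Tensor(np.ones(1), requires_grad=True)
        self.w2 = Tensor(np.ones(1), requires_grad=True)

    def forward(self, x_input: Tensor, backbone_out: Tensor) -> Tensor:
        ym = self.proj(ag.max_pool2d(x_input, self.pool_factor))
        if ym.shape != backbone_out.shape:
            raise ValueError(
                f"fusion shape mismatch: pooled branch {ym.shape} vs "
                f"backbone {backbone_out.shape} — wrong node placement")
        w1 = ag.reshape(self.w1, (1, 1, 1, 1))
        w2 = ag.reshape(self.w2, (1, 1, 1, 1))
        return ag.add(ag.mul(w1, ym), ag.mul(w2, backbone_out))


def adaptive_fusion(x_input, backbone_out, w1: float, w2: float,
                    proj_weight: np.ndarray, pool_factor: int = 2) -> np.ndarray:
    """Functional fusion with explicit weights (convenience for analysis)."""
    ym = ag.conv2d(ag.max_pool2d(Tensor(np.asarray(x_input)), pool_factor),
                   Tensor(np.asarray(proj_weight)))
    out = w1 * ym.numpy() + w2 * np.asarray(backbone_out)
    return out
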