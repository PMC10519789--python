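"""Neural-network layers on top of the autograd engine.

Modules follow the familiar container pattern: parameters are tensors with
``requires_grad=True`` discovered by attribute walking, ``train()/eval()``
toggles stochastic behaviour, and ``state_dict()`` round-trips every
parameter and buffer as plain NumPy arrays (the checkpoint format is a
compressed ``.npz``; see :mod:`fcaeffnet.training`).
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class providing parameter discovery, mode switching and state IO."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- forward -------------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs) -> Tensor:
        return self.forward(*args, **kwargs)

    # -- traversal -----------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if name.startswith("_"):
                continue
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, child in self.children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name.startswith("_"):
                continue
            if isinstance(value, Tensor) and value.requires_grad:
                yield (f"{prefix}.{name}" if prefix else name), value
        for name, child in self.children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        """Count of trainable scalars (buffers such as running stats excluded)."""
        return int(sum(p.size for p in self.parameters()))

    # -- modes ---------------------------------------------------------------
    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- state ---------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self.named_modules():
            for bname, buf in m._buffers.items():
                key = f"{mname}.{bname}" if mname else bname
                state[key] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        for mname, m in self.named_modules():
            for bname in m._buffers:
                key = f"{mname}.{bname}" if mname else bname
                buffers[key] = (m, bname)
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{params[key].data.shape} vs {value.shape}")
                params[key].data = value.astype(np.float32).copy()
            elif key in buffers:
                m, bname = buffers[key]
                m._buffers[bname] = value.copy()
                setattr(m, bname, m._buffers[bname])
            else:
                raise KeyError(f"unexpected key in state dict: {key}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def _param(arr: np.ndarray) -> Tensor:
    return Tensor(arr.astype(np.float32), requires_grad=True)


class Conv2d(Module):
    """Dense 2-D convolution; ``padding='same'`` keeps H/W at stride 1 and
    halves them (ceil) at stride 2, matching the stage plan's resolutions."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | str = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding == "same":
            padding = (kernel_size - 1) // 2
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding
        fan_out = out_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_out)
        self.weight = _param(rng.normal(0.0, std,
                             (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = _param(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)

    def macs(self, h_in: int, w_in: int) -> tuple[int, int, int]:
        ho = -(-h_in // self.stride) if self.padding else (h_in - self.kernel_size) // self.stride + 1
        wo = -(-w_in // self.stride) if self.padding else (w_in - self.kernel_size) // self.stride + 1
        m = self.kernel_size ** 2 * self.in_channels * self.out_channels * ho * wo
        return m, ho, wo


class DepthwiseConv2d(Module):
    """Per-channel convolution; kernel may be rectangular (for the
    full-extent directional kernels of the coordinate-attention variant)."""

    def __init__(self, channels: int, kernel_size: int | tuple[int, int],
                 stride: int = 1, padding: int | str = 0, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if padding == "same":
            if kh != kw:
                raise ValueError("'same' padding requires a square kernel")
            padding = (kh - 1) // 2
        self.channels, self.kh, self.kw = channels, kh, kw
        self.stride, self.padding = stride, padding
        fan_out = kh * kw
        std = np.sqrt(2.0 / fan_out)
        self.weight = _param(rng.normal(0.0, std, (channels, kh, kw)))
        self.bias = _param(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)

    def macs(self, h_in: int, w_in: int) -> tuple[int, int, int]:
        if self.padding:
            ho, wo = -(-h_in // self.stride), -(-w_in // self.stride)
        else:
            ho = (h_in - self.kh) // self.stride + 1
            wo = (w_in - self.kw) // self.stride + 1
        return self.kh * self.kw * self.channels * ho * wo, ho, wo


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.in_features, self.out_features = in_features, out_features
        self.weight = _param(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = _param(rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, ag.transpose(self.weight, (1, 0)))
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out


class BatchNorm2d(Module):
    """Batch normalisation with running statistics for inference.

    Defaults follow the common EfficientNet setting (eps 1e-3, momentum 0.01).
    """

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.01):
        super().__init__()
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    @property
    def running_mean(self):
        return self._buffers["running_mean"]

    @property
    def running_var(self):
        return self._buffers["running_var"]

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0, 2, 3)
            mu = x.data.mean(axis=axes, dtype=np.float32)
            var = x.data.var(axis=axes, dtype=np.float32)
            m = self.momentum
            self._buffers["running_mean"] = (1 - m) * self.running_mean + m * mu
            self._buffers["running_var"] = (1 - m) * self.running_var + m * var
            return ag.batch_norm(x, self.gamma, self.beta, self.eps)
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        out = ag.mul(x, Tensor(scale[None, :, None, None]))
        return ag.add(out, Tensor(shift[None, :, None, None]))


class LayerNorm2d(Module):
    """Per-sample normalisation over (C, H, W) with per-channel affine.

    Identical statistics in training and inference; a sample's output never
    depends on its batch companions.
    """

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.channels, self.eps = channels, eps
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta, self.eps)


class Swish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.swish(x)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.gelu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return ag.max_pool2d(x, self.kernel)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return ag.mean(x, axis=(2, 3))


class Dropout(Module):
    """Standard inverted dropout on the flattened features before the classifier."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return ag.mul(x, Tensor(mask.astype(np.float32)))


class StochasticDepth(Module):
    """Row-wise residual-branch drop (drop-connect): with probability ``p`` a
    sample's whole branch output is zeroed during training, otherwise scaled
    by 1/(1-p).  At inference the branch passes through unchanged."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("drop rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self.force_drop: bool | None = None  # test hook: True/False overrides sampling

    def forward(self, x: Tensor) -> Tensor:
        if self.p == 0.0 and self.force_drop is None:
            return x
        if not self.training and self.force_drop is None:
            return x
        n = x.shape[0]
        if self.force_drop is None:
            keep = (self.rng.random((n, 1, 1, 1)) >= self.p) / (1.0 - self.p)
        else:
            keep = np.zeros((n, 1, 1, 1)) if self.force_drop else np.ones((n, 1, 1, 1))
        return ag.mul(x, Tensor(keep.astype(np.float32)))
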