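"""Module/parameter containers and the standard layers used by the models."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .autograd import Tensor, as_tensor
from .profile import record_macs

__all__ = [
    "Parameter", "Module", "Linear", "Conv2d", "CausalConv1d",
    "LayerNorm", "GroupNorm", "seed_all", "get_rng",
]

_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the global parameter-initialisation RNG (deterministic builds)."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    """A trainable float32 array."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container: attribute discovery, parameter iteration,
    state dicts.  Lists/tuples of modules are traversed in order."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, (Parameter, Module)):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in self._children():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            else:
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, value in self._children():
            if isinstance(value, Module):
                yield from value.named_modules(prefix=f"{prefix}{name}.")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} unexpected={sorted(unexpected)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _uniform(shape, bound):
    return _RNG.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    """Affine map over the last axis; weight ``(out_features, in_features)``.

    ``mac_category`` controls how this layer's MACs are tallied during
    profiling ("linear" for standalone layers, "ssm_proj" inside an SSM's
    fused path).
    """

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 mac_category: str = "linear"):
        self.in_features = in_features
        self.out_features = out_features
        self.mac_category = mac_category
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(_uniform((out_features, in_features), bound))
        self.bias = Parameter(_uniform((out_features,), bound)) if bias else None

    def forward(self, x):
        x = as_tensor(x)
        record_macs(self.mac_category,
                    self.in_features * self.out_features * (x.size // x.shape[-1]))
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """Stride-1 2-D convolution, dense (``groups=1``) or depthwise
    (``groups == channels``)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, bias: bool = True, depthwise: bool = False):
        if depthwise and in_channels != out_channels:
            raise ValueError("depthwise conv requires in_channels == out_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.depthwise = depthwise
        fan_in = (1 if depthwise else in_channels) * kernel_size ** 2
        bound = 1.0 / math.sqrt(fan_in)
        shape = (in_channels, kernel_size, kernel_size) if depthwise \
            else (out_channels, in_channels, kernel_size, kernel_size)
        self.weight = Parameter(_uniform(shape, bound))
        self.bias = Parameter(_uniform((out_channels,), bound)) if bias else None

    def forward(self, x):
        x = as_tensor(x)
        B, C, H, W = x.shape
        Ho = H + 2 * self.padding - self.kernel_size + 1
        Wo = W + 2 * self.padding - self.kernel_size + 1
        per_out = (1 if self.depthwise else self.in_channels) * self.kernel_size ** 2
        record_macs("conv2d", B * self.out_channels * Ho * Wo * per_out)
        if self.depthwise:
            return F.conv2d_depthwise(x, self.weight, self.bias, padding=self.padding)
        return F.conv2d(x, self.weight, self.bias, padding=self.padding)


class CausalConv1d(Module):
    """Causal 1-D convolution over token sequences ``(B, L, C)``.

    ``mode="depthwise"`` is the grouped convolution of reference Mamba blocks;
    ``mode="full"`` is the dense variant matching the closed-form
    ``d_conv * d_inner**2 + d_inner`` parameter term.
    """

    def __init__(self, channels: int, kernel_size: int, mode: str = "depthwise"):
        if mode not in ("depthwise", "full"):
            raise ValueError(f"unknown conv mode {mode!r}")
        self.channels = channels
        self.kernel_size = kernel_size
        self.mode = mode
        fan_in = kernel_size * (1 if mode == "depthwise" else channels)
        bound = 1.0 / math.sqrt(fan_in)
        shape = (channels, kernel_size) if mode == "depthwise" \
            else (channels, channels, kernel_size)
        self.weight = Parameter(_uniform(shape, bound))
        self.bias = Parameter(_uniform((channels,), bound))

    def forward(self, x):
        x = as_tensor(x)
        B, L, C = x.shape
        per_out = self.kernel_size * (1 if self.mode == "depthwise" else C)
        record_macs("conv1d", B * L * self.channels * per_out)
        if self.mode == "depthwise":
            return F.conv1d_causal_depthwise(x, self.weight, self.bias)
        return F.conv1d_causal(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, features: int, eps: float = 1e-5):
        self.features = features
        self.eps = eps
        self.weight = Parameter(np.ones(features))
        self.bias = Parameter(np.zeros(features))

    def forward(self, x):
        return F.layer_norm(x, self.weight, self.bias, eps=self.eps)


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x):
        return F.group_norm(x, self.weight, self.bias, self.groups, eps=self.eps)
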