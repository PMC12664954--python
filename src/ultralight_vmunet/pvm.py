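"""Parallel Vision Mamba (PVM) layer.

The layer normalises a token sequence, splits its channels into ``k`` equal
groups, runs a Vision Mamba unit — a Mamba block plus a ``theta``-weighted
residual — on each C/k-channel group, concatenates the groups back to C
channels, normalises again and applies a pointwise linear projection that
also performs the stage's channel change.

Because each group has C/k channels, the Mamba operating width (and hence
its dominant, quadratic-in-width parameter terms) shrinks with ``k`` while
the total processed channel count stays constant.  By default the groups
share one Mamba block, one scalar ``theta`` and one LayerNorm (applied both
before the split and after the concatenation); this weight tying is what
makes the ultra-light model budgets attainable.  Fully independent branches
are available via ``shared_branches=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import nn
from .mamba import MambaBlock, MambaConfig
from .ss2d import VSSBlock, VSSConfig

__all__ = ["PVMConfig", "split_channels", "PVMLayer", "ParallelVSS"]


@dataclass(frozen=True)
class PVMConfig:
    """Configuration of one PVM layer.

    ``mamba`` is a template whose ``d_model`` is ignored; each branch uses
    ``in_channels // k``.
    """

    in_channels: int
    out_channels: int
    k: int = 4
    theta_init: float = 1.0
    theta_learnable: bool = True
    shared_branches: bool = True
    mamba: MambaConfig = field(default_factory=lambda: MambaConfig(d_model=1))

    def __post_init__(self):
        if self.k not in (1, 2, 4):
            raise ValueError(f"parallelism k must be 1, 2 or 4, got {self.k}")
        if self.in_channels % self.k:
            raise ValueError(
                f"in_channels={self.in_channels} not divisible by k={self.k}")

    def branch_config(self) -> MambaConfig:
        m = self.mamba
        return MambaConfig(d_model=self.in_channels // self.k, expand=m.expand,
                           d_state=m.d_state, d_conv=m.d_conv, dt_rank=m.dt_rank,
                           conv_mode=m.conv_mode)


def split_channels(x, k: int):
    """Split the channel (last) axis of a ``(B, N, C)`` sequence into ``k``
    equal contiguous slices; concatenating the slices restores the input."""
    x = nn.as_tensor(x)
    C = x.shape[-1]
    if k < 1 or C % k:
        raise ValueError(f"cannot split {C} channels into {k} equal groups")
    step = C // k
    return [x[..., i * step:(i + 1) * step] for i in range(k)]


class PVMLayer(nn.Module):
    """Parallel Vision Mamba layer over token sequences ``(B, N, C_in)``."""

    def __init__(self, cfg: PVMConfig):
        self.cfg = cfg
        self.norm = nn.LayerNorm(cfg.in_channels)
        branch_cfg = cfg.branch_config()
        if cfg.shared_branches:
            self.mamba = MambaBlock(branch_cfg)
            self.theta = nn.Parameter([cfg.theta_init])
        else:
            self.mambas = [MambaBlock(branch_cfg) for _ in range(cfg.k)]
            self.thetas = [nn.Parameter([cfg.theta_init]) for _ in range(cfg.k)]
        if not cfg.theta_learnable:
            for p in ([self.theta] if cfg.shared_branches else self.thetas):
                p.requires_grad = False
        self.proj = nn.Linear(cfg.in_channels, cfg.out_channels, bias=True)

    @classmethod
    def create(cls, in_channels: int, out_channels: int, k: int = 4,
               conv_mode: str = "depthwise", **kwargs) -> "PVMLayer":
        mamba = MambaConfig(d_model=max(1, in_channels // k), conv_mode=conv_mode)
        return cls(PVMConfig(in_channels, out_channels, k=k, mamba=mamba, **kwargs))

    def forward(self, x):
        x = nn.as_tensor(x)
        cfg = self.cfg
        if x.ndim != 3 or x.shape[-1] != cfg.in_channels:
            raise ValueError(
                f"expected (B, N, {cfg.in_channels}) input, got {x.shape}")
        xn = self.norm(x)
        parts = split_channels(xn, cfg.k)
        if cfg.shared_branches:
            if cfg.k == 1:
                outs = [self.mamba(parts[0]) + self.theta * parts[0]]
            else:
                # one weight set: stack the groups along the batch axis and
                # run the scan once
                stacked = nn.concat(parts, axis=0)
                y = self.mamba(stacked) + self.theta * stacked
                B = x.shape[0]
                outs = [y[i * B:(i + 1) * B] for i in range(cfg.k)]
        else:
            outs = [m(p) + t * p
                    for m, t, p in zip(self.mambas, self.thetas, parts)]
        merged = nn.concat(outs, axis=-1)
        return self.proj(self.norm(merged))


class ParallelVSS(nn.Module):
    """Channel-parallel wrapper around VSS blocks on ``(B, C, H, W)`` maps.

    Splits the channels into ``k`` equal groups, applies a (shared) VSS block
    of width C/k per group and concatenates.  With ``k=1`` this is exactly a
    single VSS block.  Used for block-level parameter-reduction audits of the
    SS2D variant.
    """

    def __init__(self, channels: int, k: int = 4, conv_mode: str = "depthwise",
                 d_state: int = 16, d_conv: int = 3, expand: int = 2):
        if k < 1 or channels % k:
            raise ValueError(f"channels={channels} not divisible by k={k}")
        self.channels = channels
        self.k = k
        self.vss = VSSBlock(VSSConfig(d_model=channels // k, d_state=d_state,
                                      d_conv=d_conv, expand=expand,
                                      conv_mode=conv_mode))

    def forward(self, fmap):
        fmap = nn.as_tensor(fmap)
        if fmap.ndim != 4 or fmap.shape[1] != self.channels:
            raise ValueError(
                f"expected (B, {self.channels}, H, W) input, got {fmap.shape}")
        step = self.channels // self.k
        outs = [self.vss(fmap[:, i * step:(i + 1) * step])
                for i in range(self.k)]
        return nn.concat(outs, axis=1)
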