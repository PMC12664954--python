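"""Selective state-space (Mamba / S6) block.

A Mamba block maps a token sequence ``(batch, length, d_model)`` to a
sequence of the same shape.  One shared input projection produces both the
main stream and the gate; the main stream runs through a short causal
convolution, SiLU, a low-rank projection producing the per-token step size
``delta`` and the input/output matrices ``B``/``C``, and the selective scan;
the result is gated by ``SiLU`` of the second stream and projected back to
``d_model``.

The state recurrence uses zero-order-hold discretisation for the learned
decay matrix ``A = -exp(A_logs)`` and Euler discretisation for ``B``:
``h_t = exp(delta_t A) h_{t-1} + (delta_t B_t) u_t``; the skip gain ``D``
adds the input back into the read-out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as Fn
from .nn.profile import record_macs

__all__ = ["MambaConfig", "resolve_dt_rank", "selective_scan", "MambaBlock"]

#: re-exported scan primitive (see :func:`ultralight_vmunet.nn.functional.selective_scan`)
selective_scan = Fn.selective_scan


def resolve_dt_rank(d_model: int, dt_rank_spec) -> int:
    """Resolve the rank of the step-size projection.

    ``"auto"`` resolves to ``ceil(d_model / 16)``, floored at 1 so that the
    narrow branch widths of a parallel layer (6, 8, 12, 16 channels) still
    get a non-empty projection.
    """
    if d_model < 1:
        raise ValueError(f"d_model must be >= 1, got {d_model}")
    if dt_rank_spec == "auto":
        return max(1, math.ceil(d_model / 16))
    rank = int(dt_rank_spec)
    if rank < 1:
        raise ValueError(f"dt_rank must be >= 1, got {rank}")
    return rank


@dataclass(frozen=True)
class MambaConfig:
    """Hyperparameters of one selective-SSM block.

    ``conv_mode`` selects the internal 1-D convolution: ``"depthwise"`` is
    the grouped convolution used by trained blocks, ``"full"`` the dense
    variant matching the closed-form ``d_conv*d_inner**2 + d_inner`` count.
    """

    d_model: int
    expand: int = 2
    d_state: int = 16
    d_conv: int = 4
    dt_rank: object = "auto"
    conv_mode: str = "depthwise"

    def __post_init__(self):
        if self.d_model < 1:
            raise ValueError("d_model must be >= 1")
        if self.expand < 1 or self.d_state < 1 or self.d_conv < 1:
            raise ValueError("expand, d_state and d_conv must be >= 1")
        if self.conv_mode not in ("depthwise", "full"):
            raise ValueError(f"unknown conv_mode {self.conv_mode!r}")
        resolve_dt_rank(self.d_model, self.dt_rank)  # validates

    @property
    def d_inner(self) -> int:
        return self.expand * self.d_model

    @property
    def dt_rank_resolved(self) -> int:
        return resolve_dt_rank(self.d_model, self.dt_rank)


def _init_dt_proj(dt_proj: nn.Linear, rng, dt_min: float = 1e-3,
                  dt_max: float = 1e-1) -> None:
    """Stable SSM step-size initialisation: weights at scale rank**-0.5 and a
    bias whose softplus lands log-uniformly in [dt_min, dt_max]."""
    rank = dt_proj.in_features
    scale = rank ** -0.5
    dt_proj.weight.data = rng.uniform(-scale, scale,
                                      size=dt_proj.weight.shape).astype(np.float32)
    dt = np.exp(rng.uniform(math.log(dt_min), math.log(dt_max),
                            size=dt_proj.out_features))
    dt = np.clip(dt, 1e-4, None)
    # inverse softplus: softplus(x) = dt  =>  x = log(expm1(dt))
    dt_proj.bias.data = np.log(np.expm1(dt)).astype(np.float32)


class MambaBlock(nn.Module):
    """One selective-SSM block (see module docstring for the dataflow)."""

    def __init__(self, cfg: MambaConfig):
        self.cfg = cfg
        d_inner, d_state = cfg.d_inner, cfg.d_state
        rank = cfg.dt_rank_resolved
        self.in_proj = nn.Linear(cfg.d_model, 2 * d_inner, bias=False,
                                 mac_category="ssm_proj")
        self.conv1d = nn.CausalConv1d(d_inner, cfg.d_conv, mode=cfg.conv_mode)
        self.x_proj = nn.Linear(d_inner, rank + 2 * d_state, bias=False,
                                mac_category="ssm_proj")
        self.dt_proj = nn.Linear(rank, d_inner, bias=True, mac_category="ssm_proj")
        self.out_proj = nn.Linear(d_inner, cfg.d_model, bias=False,
                                  mac_category="ssm_proj")
        _init_dt_proj(self.dt_proj, nn.get_rng())
        # log of 1..d_state per channel: A = -exp(A_logs) decays state k at rate k
        self.A_logs = nn.Parameter(
            np.log(np.tile(np.arange(1, d_state + 1, dtype=np.float64), (d_inner, 1))))
        self.D = nn.Parameter(np.ones(d_inner))

    def forward(self, x):
        """Apply the block to a ``(batch, length, d_model)`` sequence."""
        x = nn.as_tensor(x)
        cfg = self.cfg
        if x.ndim != 3 or x.shape[-1] != cfg.d_model:
            raise ValueError(
                f"expected (batch, length, {cfg.d_model}) input, got {x.shape}")
        B, L, _ = x.shape
        d_inner, d_state, rank = cfg.d_inner, cfg.d_state, cfg.dt_rank_resolved
        xz = self.in_proj(x)
        xm, z = xz[:, :, :d_inner], xz[:, :, d_inner:]
        u = self.conv1d(xm).silu()
        dbc = self.x_proj(u)
        dt = dbc[:, :, :rank]
        Bm = dbc[:, :, rank:rank + d_state]
        Cm = dbc[:, :, rank + d_state:]
        delta = self.dt_proj(dt).softplus()
        A = -self.A_logs.exp()
        record_macs("scan", B * L * (4 * d_inner * d_state + d_inner))
        y = Fn.selective_scan(u, delta, A, Bm, Cm, self.D)
        return self.out_proj(y * z.silu())
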