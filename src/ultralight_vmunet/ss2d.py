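"""2-D selective scan (SS2D) and the two-branch VSS block.

SS2D flattens a feature map along four scan directions (row-major and its
reverse, column-major from the top-right corner and its reverse), refines
each directional sequence with an independent S6 parameter slice, and merges
the four refined sequences back onto the grid by inverse permutation and
summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .mamba import resolve_dt_rank
from .nn import functional as Fn
from .nn.autograd import make
from .nn.profile import record_macs

__all__ = ["VSSConfig", "scan_orders", "scan_expand", "scan_merge", "VSSBlock"]


@dataclass(frozen=True)
class VSSConfig:
    """Hyperparameters of one VSS (SS2D) block; ``K`` is the number of scan
    directions and is fixed at 4."""

    d_model: int
    expand: int = 2
    d_state: int = 16
    d_conv: int = 3
    dt_rank: object = "auto"
    K: int = 4
    conv_mode: str = "depthwise"

    def __post_init__(self):
        if self.d_model < 1:
            raise ValueError("d_model must be >= 1")
        if self.K != 4:
            raise ValueError("SS2D uses exactly 4 scan directions")
        if self.conv_mode not in ("depthwise", "full"):
            raise ValueError(f"unknown conv_mode {self.conv_mode!r}")
        resolve_dt_rank(self.d_model, self.dt_rank)

    @property
    def d_inner(self) -> int:
        return self.expand * self.d_model

    @property
    def dt_rank_resolved(self) -> int:
        return resolve_dt_rank(self.d_model, self.dt_rank)


def scan_orders(H: int, W: int):
    """Token orders (indices into the row-major flattening) of the four scan
    directions:

    0. top-left -> bottom-right, row-major;
    1. reverse of 0 (bottom-right -> top-left);
    2. top-right -> bottom-left, column-major (columns right to left, each
       top to bottom);
    3. reverse of 2 (bottom-left -> top-right).
    """
    if H < 1 or W < 1:
        raise ValueError("scan_orders: empty map")
    rowmajor = np.arange(H * W)
    grid = rowmajor.reshape(H, W)
    colmajor_tr = grid[:, ::-1].T.reshape(-1)  # columns W-1..0, rows 0..H-1
    return [rowmajor, rowmajor[::-1].copy(), colmajor_tr, colmajor_tr[::-1].copy()]


def scan_expand(fmap):
    """Expand a ``(B, C, H, W)`` map into four ``(B, H*W, C)`` sequences, one
    per scan direction.  Each sequence visits every spatial position once."""
    fmap = nn.as_tensor(fmap)
    if fmap.ndim != 4:
        raise ValueError(f"expected (B, C, H, W) map, got shape {fmap.shape}")
    B, C, H, W = fmap.shape
    tokens = fmap.reshape(B, C, H * W).transpose(0, 2, 1)  # (B, L, C) row-major
    return [tokens.index_select(1, order) for order in scan_orders(H, W)]


def scan_merge(seqs, H: int, W: int):
    """Inverse-permute four ``(B, H*W, C)`` directional sequences back onto the
    grid and sum them into one ``(B, C, H, W)`` map."""
    if len(seqs) != 4:
        raise ValueError("scan_merge expects exactly 4 sequences")
    orders = scan_orders(H, W)
    total = None
    for seq, order in zip(seqs, orders):
        seq = nn.as_tensor(seq)
        if seq.ndim != 3 or seq.shape[1] != H * W:
            raise ValueError(
                f"sequence length {seq.shape} does not match {H}x{W} map")
        inv = np.argsort(order)
        restored = seq.index_select(1, inv)
        total = restored if total is None else total + restored
    return total.transpose(0, 2, 1).reshape(total.shape[0], -1, H, W)


class VSSBlock(nn.Module):
    """Two-branch VSS block.

    Branch 1 is a SiLU gate on a linear projection of the input; branch 2 is
    linear -> 2-D convolution -> SiLU -> SS2D -> LayerNorm.  The branches are
    merged by elementwise multiplication and projected back to ``d_model``.
    The four scan directions use independent slices of ``x_proj``,
    ``dt_proj``, ``A_logs`` and ``Ds``.
    """

    def __init__(self, cfg: VSSConfig):
        self.cfg = cfg
        d_inner, d_state, K = cfg.d_inner, cfg.d_state, cfg.K
        rank = cfg.dt_rank_resolved
        self.in_proj = nn.Linear(cfg.d_model, 2 * d_inner, bias=False,
                                 mac_category="ssm_proj")
        self.conv2d = nn.Conv2d(d_inner, d_inner, cfg.d_conv,
                                padding=(cfg.d_conv - 1) // 2, bias=True,
                                depthwise=cfg.conv_mode == "depthwise")
        rng = nn.get_rng()
        bound = 1.0 / np.sqrt(d_inner)
        self.x_proj_weight = nn.Parameter(
            rng.uniform(-bound, bound, size=(K, rank + 2 * d_state, d_inner)))
        self.dt_proj_weight = nn.Parameter(
            rng.uniform(-rank ** -0.5, rank ** -0.5, size=(K, d_inner, rank)))
        dt = np.clip(np.exp(rng.uniform(np.log(1e-3), np.log(1e-1),
                                        size=(K, d_inner))), 1e-4, None)
        self.dt_proj_bias = nn.Parameter(np.log(np.expm1(dt)))
        self.A_logs = nn.Parameter(
            np.log(np.tile(np.arange(1, d_state + 1, dtype=np.float64),
                           (K * d_inner, 1))))
        self.Ds = nn.Parameter(np.ones(K * d_inner))
        self.out_norm = nn.LayerNorm(d_inner)
        self.out_proj = nn.Linear(d_inner, cfg.d_model, bias=False,
                                  mac_category="ssm_proj")

    def _direction_scan(self, seq, k: int):
        """S6 refinement of direction ``k``'s token sequence."""
        cfg = self.cfg
        d_inner, d_state, rank = cfg.d_inner, cfg.d_state, cfg.dt_rank_resolved
        B, L, _ = seq.shape
        record_macs("ssm_proj", B * L * d_inner * (rank + 2 * d_state + rank))
        dbc = seq @ self.x_proj_weight[k].transpose(1, 0)
        dt, Bm, Cm = (dbc[:, :, :rank], dbc[:, :, rank:rank + d_state],
                      dbc[:, :, rank + d_state:])
        delta = (dt @ self.dt_proj_weight[k].transpose(1, 0)
                 + self.dt_proj_bias[k]).softplus()
        A = -self.A_logs[k * d_inner:(k + 1) * d_inner].exp()
        D = self.Ds[k * d_inner:(k + 1) * d_inner]
        record_macs("scan", B * L * (4 * d_inner * d_state + d_inner))
        return Fn.selective_scan(seq, delta, A, Bm, Cm, D)

    def forward(self, fmap):
        """Apply the block to a ``(B, d_model, H, W)`` feature map; spatial
        size is preserved."""
        fmap = nn.as_tensor(fmap)
        cfg = self.cfg
        if fmap.ndim != 4 or fmap.shape[1] != cfg.d_model:
            raise ValueError(
                f"expected (B, {cfg.d_model}, H, W) input, got {fmap.shape}")
        B, C, H, W = fmap.shape
        d_inner = cfg.d_inner
        tokens = fmap.reshape(B, C, H * W).transpose(0, 2, 1)
        xz = self.in_proj(tokens)
        x, z = xz[:, :, :d_inner], xz[:, :, d_inner:]
        x = x.transpose(0, 2, 1).reshape(B, d_inner, H, W)
        x = self.conv2d(x).silu()
        seqs = scan_expand(x)
        refined = [self._direction_scan(seq, k) for k, seq in enumerate(seqs)]
        y = scan_merge(refined, H, W)
        y = y.reshape(B, d_inner, H * W).transpose(0, 2, 1)
        y = self.out_norm(y)
        out = self.out_proj(y * z.silu())
        return out.transpose(0, 2, 1).reshape(B, cfg.d_model, H, W)
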