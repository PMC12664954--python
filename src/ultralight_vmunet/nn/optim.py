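"""Optimisation: AdamW and a cosine-annealing learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["AdamW", "cosine_annealing_lr"]


class AdamW:
    """Decoupled-weight-decay Adam over a list of Parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.data.dtype)


def cosine_annealing_lr(epoch: int, total_epochs: int, lr_init: float,
                        lr_min: float) -> float:
    """Cosine decay from ``lr_init`` to ``lr_min`` over ``total_epochs``
    (single period, no restarts)."""
    if total_epochs <= 1:
        return lr_init
    frac = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + math.cos(math.pi * frac))
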