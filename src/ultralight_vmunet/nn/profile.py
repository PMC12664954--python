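"""Multiply-accumulate (MAC) tallying for forward passes.

Modules report their MAC count under a category each time they run inside a
:func:`mac_tally` context.  Categories:

``conv2d``
    2-D convolutions (encoder/decoder/attention-bridge/head).
``conv1d``
    the short causal convolution inside a Mamba block.
``linear``
    standalone linear layers (PVM projection, channel-attention maps).
``ssm_proj``
    Mamba/VSS internal projections (in/x/dt/out) — part of the fused
    selective-scan path.
``scan``
    the selective-scan recurrence itself.
"""

from __future__ import annotations

from collections import defaultdict
from contextlib import contextmanager

_TALLY = None

#: categories counted by each reporting convention
CONVENTIONS = {
    # hook-style profiling of a model whose selective-scan path executes as a
    # single fused primitive: only conv and standalone linear layers are seen
    "fused": ("conv2d", "conv1d", "linear"),
    # every multiply-accumulate including the SSM projections and recurrence
    "full": ("conv2d", "conv1d", "linear", "ssm_proj", "scan"),
}


@contextmanager
def mac_tally():
    """Collect per-category MAC counts from all modules run in this context."""
    global _TALLY
    prev = _TALLY
    _TALLY = defaultdict(int)
    try:
        yield _TALLY
    finally:
        _TALLY = prev


def record_macs(category: str, n: int) -> None:
    if _TALLY is not None:
        _TALLY[category] += int(n)


def total_macs(tally, convention: str = "fused") -> int:
    try:
        cats = CONVENTIONS[convention]
    except KeyError:
        raise ValueError(f"unknown MAC convention {convention!r}") from None
    return sum(tally.get(c, 0) for c in cats)
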