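import numpy as np
import pytest

from ultralight_vmunet import nn


@pytest.fixture(autouse=True)
def _seeded_init():
    """Every test constructs modules from the same initialisation stream."""
    nn.seed_all(0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_scan_inputs(rng, b=2, l=5, d=4, n=3, dtype=np.float64):
    """Random, well-conditioned inputs for the selective scan."""
    return dict(
        u=rng.standard_normal((b, l, d)).astype(dtype),
        delta=rng.uniform(0.01, 0.5, (b, l, d)).astype(dtype),
        A=(-np.exp(rng.standard_normal((d, n)))).astype(dtype),
        B=rng.standard_normal((b, l, n)).astype(dtype),
        C=rng.standard_normal((b, l, n)).astype(dtype),
        D=rng.standard_normal(d).astype(dtype),
    )


def reference_scan(u, delta, A, B, C, D):
    """Per-token, per-batch sequential recurrence: the brute-force oracle."""
    b, l, d = u.shape
    y = np.zeros_like(u)
    for bi in range(b):
        h = np.zeros_like(A)
        for t in range(l):
            decay = np.exp(delta[bi, t][:, None] * A)
            h = decay * h + (delta[bi, t][:, None] * B[bi, t][None, :]) * u[bi, t][:, None]
            y[bi, t] = h @ C[bi, t] + D * u[bi, t]
    return y
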