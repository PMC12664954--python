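"""Neural-network kernels with hand-written backward passes.

Axis conventions: feature maps are ``(batch, channels, H, W)``; token
sequences are ``(batch, length, channels)``.  Convolutions are stride-1;
1-D convolutions over token sequences are causal (left padding, output
cropped to the input length).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, make, _unbroadcast

__all__ = [
    "conv2d", "conv2d_depthwise", "conv1d_causal", "conv1d_causal_depthwise",
    "max_pool2x2", "upsample_bilinear_2x", "layer_norm", "group_norm",
    "selective_scan",
]


def _bias_backward_nchw(g):
    return g.sum(axis=(0, 2, 3))


def conv2d(x, weight, bias=None, padding: int = 0):
    """Dense 2-D convolution, weight ``(out_c, in_c, kh, kw)``."""
    x, weight = as_tensor(x), as_tensor(weight)
    B, C, H, W = x.shape
    O, Ci, kh, kw = weight.shape
    if Ci != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Ci}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("conv2d: kernel larger than padded input")
    y = np.zeros((B, O, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            y += np.einsum("oc,bchw->bohw", weight.data[:, :, i, j],
                           xp[:, :, i:i + Ho, j:j + Wo], optimize=True)
    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        y += bias.data[None, :, None, None]
        parents.append(bias)

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(weight.data)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i:i + Ho, j:j + Wo]
                dw[:, :, i, j] = np.einsum("bohw,bchw->oc", g, patch, optimize=True)
                dxp[:, :, i:i + Ho, j:j + Wo] += np.einsum(
                    "oc,bohw->bchw", weight.data[:, :, i, j], g, optimize=True)
        dx = dxp[:, :, p:p + H, p:p + W] if p else dxp
        if bias is not None:
            return dx, dw, _bias_backward_nchw(g)
        return dx, dw

    return make(y, tuple(parents), backward)


def conv2d_depthwise(x, weight, bias=None, padding: int = 0):
    """Depthwise 2-D convolution, weight ``(channels, kh, kw)``."""
    x, weight = as_tensor(x), as_tensor(weight)
    B, C, H, W = x.shape
    Cw, kh, kw = weight.shape
    if Cw != C:
        raise ValueError("conv2d_depthwise: channel mismatch")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    y = np.zeros((B, C, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            y += weight.data[None, :, i, j, None, None] * xp[:, :, i:i + Ho, j:j + Wo]
    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        y += bias.data[None, :, None, None]
        parents.append(bias)

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(weight.data)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i:i + Ho, j:j + Wo]
                dw[:, i, j] = (g * patch).sum(axis=(0, 2, 3))
                dxp[:, :, i:i + Ho, j:j + Wo] += weight.data[None, :, i, j, None, None] * g
        dx = dxp[:, :, p:p + H, p:p + W] if p else dxp
        if bias is not None:
            return dx, dw, _bias_backward_nchw(g)
        return dx, dw

    return make(y, tuple(parents), backward)


def conv1d_causal(x, weight, bias=None):
    """Dense causal 1-D convolution over tokens; weight ``(out_c, in_c, K)``."""
    x, weight = as_tensor(x), as_tensor(weight)
    B, L, C = x.shape
    O, Ci, K = weight.shape
    if Ci != C:
        raise ValueError("conv1d_causal: channel mismatch")
    xp = np.pad(x.data, ((0, 0), (K - 1, 0), (0, 0)))
    y = np.zeros((B, L, O), dtype=x.dtype)
    for k in range(K):
        y += np.einsum("oc,blc->blo", weight.data[:, :, k], xp[:, k:k + L, :],
                       optimize=True)
    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        y += bias.data
        parents.append(bias)

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(weight.data)
        for k in range(K):
            patch = xp[:, k:k + L, :]
            dw[:, :, k] = np.einsum("blo,blc->oc", g, patch, optimize=True)
            dxp[:, k:k + L, :] += np.einsum("oc,blo->blc", weight.data[:, :, k], g,
                                            optimize=True)
        dx = dxp[:, K - 1:, :]
        if bias is not None:
            return dx, dw, g.sum(axis=(0, 1))
        return dx, dw

    return make(y, tuple(parents), backward)


def conv1d_causal_depthwise(x, weight, bias=None):
    """Depthwise causal 1-D convolution; weight ``(channels, K)``."""
    x, weight = as_tensor(x), as_tensor(weight)
    B, L, C = x.shape
    Cw, K = weight.shape
    if Cw != C:
        raise ValueError("conv1d_causal_depthwise: channel mismatch")
    xp = np.pad(x.data, ((0, 0), (K - 1, 0), (0, 0)))
    y = np.zeros((B, L, C), dtype=x.dtype)
    for k in range(K):
        y += weight.data[None, None, :, k] * xp[:, k:k + L, :]
    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        y += bias.data
        parents.append(bias)

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(weight.data)
        for k in range(K):
            dw[:, k] = (g * xp[:, k:k + L, :]).sum(axis=(0, 1))
            dxp[:, k:k + L, :] += weight.data[None, None, :, k] * g
        dx = dxp[:, K - 1:, :]
        if bias is not None:
            return dx, dw, g.sum(axis=(0, 1))
        return dx, dw

    return make(y, tuple(parents), backward)


def max_pool2x2(x):
    """2x2 max pooling, stride 2, floor division of odd sizes."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    if H2 < 1 or W2 < 1:
        raise ValueError("max_pool2x2: spatial size must be at least 2x2")
    xc = x.data[:, :, :H2 * 2, :W2 * 2]
    win = xc.reshape(B, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
    idx = np.argmax(win, axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        z = np.zeros((B, C, H2, W2, 4), dtype=g.dtype)
        np.put_along_axis(z, idx[..., None], g[..., None], axis=-1)
        z = z.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2 * 2, W2 * 2)
        if (H2 * 2, W2 * 2) != (H, W):
            full = np.zeros_like(x.data)
            full[:, :, :H2 * 2, :W2 * 2] = z
            return (full,)
        return (z,)

    return make(out, (x,), backward)


def _interp_coords(n_in: int, dtype):
    """Source indices/weights for 2x bilinear upsampling (align_corners=True)."""
    n_out = 2 * n_in
    if n_in == 1:
        i0 = np.zeros(n_out, dtype=np.intp)
        return i0, i0, np.zeros(n_out, dtype=dtype)
    src = np.arange(n_out, dtype=np.float64) * (n_in - 1) / (n_out - 1)
    i0 = np.floor(src).astype(np.intp)
    i0 = np.minimum(i0, n_in - 2)
    w = (src - i0).astype(dtype)
    return i0, i0 + 1, w


def upsample_bilinear_2x(x):
    """Parameter-free 2x bilinear upsampling of a ``(B,C,H,W)`` map."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    i0, i1, wi = _interp_coords(H, x.data.dtype)
    j0, j1, wj = _interp_coords(W, x.data.dtype)
    rows = x.data[:, :, i0, :] * (1 - wi)[None, None, :, None] + \
        x.data[:, :, i1, :] * wi[None, None, :, None]
    out = rows[:, :, :, j0] * (1 - wj)[None, None, None, :] + \
        rows[:, :, :, j1] * wj[None, None, None, :]

    def backward(g):
        drows = np.zeros((B, C, 2 * H, W), dtype=g.dtype)
        np.add.at(drows, (slice(None), slice(None), slice(None), j0),
                  g * (1 - wj)[None, None, None, :])
        np.add.at(drows, (slice(None), slice(None), slice(None), j1),
                  g * wj[None, None, None, :])
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), slice(None), i0),
                  drows * (1 - wi)[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), i1),
                  drows * wi[None, None, :, None])
        return (dx,)

    return make(out, (x,), backward)


def layer_norm(x, weight, bias, eps: float = 1e-5):
    """Layer normalisation over the last axis with per-feature affine."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = xhat * weight.data + bias.data

    def backward(g):
        dxhat = g * weight.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        lead = tuple(range(g.ndim - 1))
        return dx, (g * xhat).sum(axis=lead), g.sum(axis=lead)

    return make(y, (x, weight, bias), backward)


def group_norm(x, weight, bias, groups: int, eps: float = 1e-5):
    """Group normalisation of a ``(B,C,H,W)`` map with per-channel affine."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    B, C, H, W = x.shape
    if C % groups:
        raise ValueError("group_norm: channels not divisible by groups")
    xg = x.data.reshape(B, groups, -1)
    mu = xg.mean(axis=-1, keepdims=True)
    xc = xg - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xc * inv).reshape(B, C, H, W)
    y = xhat * weight.data[None, :, None, None] + bias.data[None, :, None, None]

    def backward(g):
        dxhat = (g * weight.data[None, :, None, None]).reshape(B, groups, -1)
        xh = xhat.reshape(B, groups, -1)
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xh).mean(axis=-1, keepdims=True)
        dx = (inv * (dxhat - m1 - xh * m2)).reshape(B, C, H, W)
        return dx, (g * xhat).sum(axis=(0, 2, 3)), g.sum(axis=(0, 2, 3))

    return make(y, (x, weight, bias), backward)


def selective_scan(u, delta, A, B, C, D):
    """Selective state-space (S6) scan.

    Zero-order-hold discretisation of the state matrix and Euler
    discretisation of the input matrix: per channel and token

    ``h_t = exp(delta_t * A) * h_{t-1} + (delta_t * B_t) * u_t``,  ``h_0 = 0``
    ``y_t = C_t . h_t + D * u_t``

    Parameters
    ----------
    u, delta : (batch, length, d_inner); ``delta`` strictly positive.
    A : (d_inner, d_state), strictly negative (stable decay).
    B, C : (batch, length, d_state) input/output matrices per token.
    D : (d_inner,) skip gain.
    """
    u, delta = as_tensor(u), as_tensor(delta)
    A, Bm, Cm, D = as_tensor(A), as_tensor(B), as_tensor(C), as_tensor(D)
    for name, t in (("u", u), ("delta", delta), ("A", A), ("B", Bm), ("C", Cm), ("D", D)):
        if not np.all(np.isfinite(t.data)):
            raise ValueError(f"selective_scan: non-finite values in {name}")
    b, L, d = u.shape
    d_a, n = A.shape
    if delta.shape != (b, L, d) or d_a != d or Bm.shape != (b, L, n) \
            or Cm.shape != (b, L, n) or D.shape != (d,):
        raise ValueError("selective_scan: inconsistent shapes")
    if np.any(delta.data <= 0):
        raise ValueError("selective_scan: delta must be positive")

    acc = np.float64 if u.dtype == np.float64 else np.float32
    dA = np.exp(delta.data[..., None].astype(acc) * A.data.astype(acc))   # (b,L,d,n)
    dBu = (delta.data * u.data)[..., None].astype(acc) * Bm.data[:, :, None, :].astype(acc)
    hs = np.empty((b, L, d, n), dtype=acc)
    h = np.zeros((b, d, n), dtype=acc)
    for t in range(L):
        h = dA[:, t] * h + dBu[:, t]
        hs[:, t] = h
    y = np.einsum("bldn,bln->bld", hs, Cm.data.astype(acc), optimize=True)
    y = (y + u.data * D.data).astype(u.dtype)

    def backward(g):
        gdy = g.astype(acc)
        dD = (g * u.data).sum(axis=(0, 1))
        dC = np.einsum("bld,bldn->bln", gdy, hs, optimize=True)
        ddA = np.empty_like(hs)
        ddBu = np.empty_like(hs)
        dh_next = np.zeros((b, d, n), dtype=acc)
        Cacc = Cm.data.astype(acc)
        for t in range(L - 1, -1, -1):
            dh = gdy[:, t, :, None] * Cacc[:, t, None, :] + dh_next
            ddA[:, t] = dh * (hs[:, t - 1] if t > 0 else 0.0)
            ddBu[:, t] = dh
            dh_next = dh * dA[:, t]
        # dA_bar/d(delta) = A*dA_bar ; dA_bar/dA = delta*dA_bar
        ddelta = np.einsum("bldn,bldn->bld", ddA, dA * A.data.astype(acc), optimize=True)
        ddelta += np.einsum("bldn,bln->bld", ddBu, Bm.data.astype(acc), optimize=True) * u.data
        dA_mat = np.einsum("bldn,bldn,bld->dn", ddA, dA, delta.data.astype(acc), optimize=True)
        dB = np.einsum("bldn,bld->bln", ddBu, (delta.data * u.data).astype(acc), optimize=True)
        du = np.einsum("bldn,bln->bld", ddBu, Bm.data.astype(acc), optimize=True) * delta.data
        du += g * D.data
        return (du.astype(u.dtype), ddelta.astype(delta.dtype), dA_mat.astype(A.dtype),
                dB.astype(Bm.dtype), dC.astype(Cm.dtype), dD.astype(D.dtype))

    return make(y, (u, delta, A, Bm, Cm, D), backward)
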