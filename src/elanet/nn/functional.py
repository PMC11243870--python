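"""Array-level neural-network operations (forward + backward).

All feature maps are ``(N, C, H, W)`` float32.  Convolution is computed by
an explicit patch gather followed by a grouped ``einsum``; its backward
pass scatters patch gradients back with per-tap slice additions, which is
exact because taps at a fixed kernel offset never overlap.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "adaptive_avg_pool2d",
    "upsample_bilinear",
    "global_avg_pool",
    "global_max_pool",
]


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride=1,
    padding=0,
    dilation=1,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation with stride, zero padding, dilation and groups.

    ``weight`` has shape ``(C_out, C_in // groups, kh, kw)``.
    """
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"conv2d: input channels {cin} incompatible with weight "
            f"{weight.shape} and groups={groups}"
        )
    hout = (h + 2 * ph - dh * (kh - 1) - 1) // sh + 1
    wout = (w + 2 * pw - dw * (kw - 1) - 1) // sw + 1
    if hout < 1 or wout < 1:
        raise ValueError(f"conv2d: output would be empty for input {x.shape}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    hp, wp = xp.shape[2:]
    ri = np.arange(kh)[:, None] * dh + np.arange(hout)[None, :] * sh  # (kh, hout)
    ci = np.arange(kw)[:, None] * dw + np.arange(wout)[None, :] * sw  # (kw, wout)
    # patches: (n, cin, kh, kw, hout, wout), C-contiguous after the gather
    patches = xp[:, :, ri[:, None, :, None], ci[None, :, None, :]]
    cols = patches.reshape(n, groups, cin_g * kh * kw, hout * wout)
    wg = weight.data.reshape(groups, cout // groups, cin_g * kh * kw)
    out = np.matmul(wg, cols)  # (n, groups, cout_g, hout*wout)
    out = out.reshape(n, cout, hout, wout)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gg = np.ascontiguousarray(g.reshape(n, groups, cout // groups, hout * wout))
        if weight.requires_grad:
            dw_ = np.matmul(gg, cols.swapaxes(2, 3)).sum(axis=0)
            weight._accum(dw_.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dp = np.matmul(wg.swapaxes(1, 2), gg)  # (n, groups, ck, hw)
            dp = dp.reshape(n, cin, kh, kw, hout, wout)
            dxp = np.zeros((n, cin, hp, wp), dtype=np.float32)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[
                        :,
                        :,
                        ki * dh : ki * dh + sh * hout : sh,
                        kj * dw : kj * dw + sw * wout : sw,
                    ] += dp[:, :, ki, kj]
            if ph or pw:
                dxp = dxp[:, :, ph : hp - ph, pw : wp - pw]
            x._accum(dxp)

    return Tensor._node(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None) -> Tensor:
    """Non-overlapping max pooling (kernel == stride, no padding)."""
    if stride is None:
        stride = kernel
    if stride != kernel:
        raise ValueError("only non-overlapping max pooling is supported")
    n, c, h, w = x.shape
    if h % kernel or w % kernel:
        raise ValueError(f"max_pool2d: spatial dims {h}x{w} not divisible by {kernel}")
    h2, w2 = h // kernel, w // kernel
    xr = x.data.reshape(n, c, h2, kernel, w2, kernel).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h2, w2, kernel * kernel)
    idx = np.argmax(xr, axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, h2, w2, kernel, kernel).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(n, c, h, w))

    return Tensor._node(out, (x,), backward)


def avg_pool2d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping average pooling by an integer factor."""
    n, c, h, w = x.shape
    if h % kernel or w % kernel:
        raise ValueError(f"avg_pool2d: spatial dims {h}x{w} not divisible by {kernel}")
    h2, w2 = h // kernel, w // kernel
    out = x.data.reshape(n, c, h2, kernel, w2, kernel).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gg = np.repeat(np.repeat(g, kernel, axis=2), kernel, axis=3)
            x._accum(gg / (kernel * kernel))

    return Tensor._node(out, (x,), backward)


def _bin_edges(size: int, bins: int) -> list[tuple[int, int]]:
    return [(int(np.floor(i * size / bins)), int(np.ceil((i + 1) * size / bins))) for i in range(bins)]


def adaptive_avg_pool2d(x: Tensor, out_hw) -> Tensor:
    """Average pooling to an arbitrary output grid (PyTorch bin convention)."""
    gh, gw = _pair(out_hw)
    n, c, h, w = x.shape
    rows = _bin_edges(h, gh)
    cols = _bin_edges(w, gw)
    out = np.empty((n, c, gh, gw), dtype=np.float32)
    for i, (r0, r1) in enumerate(rows):
        for j, (c0, c1) in enumerate(cols):
            out[:, :, i, j] = x.data[:, :, r0:r1, c0:c1].mean(axis=(2, 3))

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                area = (r1 - r0) * (c1 - c0)
                dx[:, :, r0:r1, c0:c1] += g[:, :, i : i + 1, j : j + 1] / area
        x._accum(dx)

    return Tensor._node(out, (x,), backward)


def _interp_matrix(src: int, dst: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((dst, src), dtype=np.float32)
    coords = (np.arange(dst, dtype=np.float64) + 0.5) * (src / dst) - 0.5
    coords = np.clip(coords, 0, src - 1)
    lo = np.floor(coords).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    frac = (coords - lo).astype(np.float32)
    for i in range(dst):
        m[i, lo[i]] += 1.0 - frac[i]
        m[i, hi[i]] += frac[i]
    return m


def upsample_bilinear(x: Tensor, out_hw) -> Tensor:
    """Bilinear resampling to ``out_hw`` with the align_corners=False rule."""
    oh, ow = _pair(out_hw)
    n, c, h, w = x.shape
    if (oh, ow) == (h, w):
        return x
    a = _interp_matrix(h, oh)  # (oh, h)
    b = _interp_matrix(w, ow)  # (ow, w)
    out = np.einsum("ij,ncjk,lk->ncil", a, x.data, b, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("ij,ncil,lk->ncjk", a, g, b, optimize=True))

    return Tensor._node(out.astype(np.float32), (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes, keeping (N, C, 1, 1)."""
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    """Max over the spatial axes, keeping (N, C, 1, 1)."""
    n, c = x.shape[:2]
    return x.reshape(n, c, 1, x.shape[2] * x.shape[3]).max(axis=3, keepdims=True)
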