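"""Independent explicit-loop reference implementations.

Everything here is written as direct nested loops / elementwise formulas
on (C, H, W) numpy arrays, deliberately sharing no code with the package
internals, so that block outputs can be checked against a second,
transparent route.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(np.asarray(x, dtype=np.float64), -15, 15)))


def conv2d_loop(x, w, b=None, stride=1, pad=(0, 0), dil=(1, 1)):
    """x: (C,H,W), w: (O,C,kh,kw) -> (O,H',W'); plain quadruple loop."""
    o, c, kh, kw = w.shape
    xp = np.pad(np.asarray(x, np.float64), ((0, 0), (pad[0], pad[0]), (pad[1], pad[1])))
    ho = (xp.shape[1] - dil[0] * (kh - 1) - 1) // stride + 1
    wo = (xp.shape[2] - dil[1] * (kw - 1) - 1) // stride + 1
    out = np.zeros((o, ho, wo))
    for oc in range(o):
        for i in range(ho):
            for j in range(wo):
                for ki in range(kh):
                    for kj in range(kw):
                        out[oc, i, j] += (
                            w[oc, :, ki, kj]
                            * xp[:, i * stride + ki * dil[0], j * stride + kj * dil[1]]
                        ).sum()
    return out + (0 if b is None else np.asarray(b)[:, None, None])


def maxpool2x2_loop(x):
    c, h, w = x.shape
    out = np.zeros((c, h // 2, w // 2))
    for i in range(h // 2):
        for j in range(w // 2):
            out[:, i, j] = x[:, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].max(axis=(1, 2))
    return out


def adaptive_avg_loop(x, grid):
    c, h, w = x.shape
    out = np.zeros((c, grid, grid))
    for i in range(grid):
        for j in range(grid):
            r0, r1 = int(np.floor(i * h / grid)), int(np.ceil((i + 1) * h / grid))
            c0, c1 = int(np.floor(j * w / grid)), int(np.ceil((j + 1) * w / grid))
            out[:, i, j] = x[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return out


def bilinear_loop(x, oh, ow):
    """align_corners=False: src = (dst + 0.5) * size_ratio - 0.5, clamped."""
    c, h, w = x.shape
    out = np.zeros((c, oh, ow))
    for i in range(oh):
        for j in range(ow):
            fy = min(max((i + 0.5) * h / oh - 0.5, 0), h - 1)
            fx = min(max((j + 0.5) * w / ow - 0.5, 0), w - 1)
            y0, x0 = int(np.floor(fy)), int(np.floor(fx))
            y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
            dy, dx = fy - y0, fx - x0
            out[:, i, j] = (
                x[:, y0, x0] * (1 - dy) * (1 - dx) + x[:, y0, x1] * (1 - dy) * dx
                + x[:, y1, x0] * dy * (1 - dx) + x[:, y1, x1] * dy * dx
            )
    return out


def channel_attention_oracle(x, w1, b1, w2, b2):
    """Eq-(2) chain: sigmoid(MLP(avgpool) + MLP(maxpool)), shared weights."""
    def mlp(v):
        hidden = np.maximum(w1 @ v + (0 if b1 is None else b1), 0)
        return w2 @ hidden + (0 if b2 is None else b2)

    avg = x.mean(axis=(1, 2))
    mx = x.max(axis=(1, 2))
    return sigmoid(mlp(avg) + mlp(mx))  # (C,)


def spatial_attention_oracle(x, w7, b7=None):
    """Eq-(3) chain: sigmoid(conv7x7([mean_c; max_c]))."""
    stacked = np.stack([x.mean(axis=0), x.max(axis=0)])
    return sigmoid(conv2d_loop(stacked, w7, b7, pad=(3, 3))[0])  # (H,W)


def cbam_oracle(x, ca_w, sa_w):
    """Eq-(4): F' = CA(F) * F, F'' = SA(F') * F'."""
    w1, b1, w2, b2 = ca_w
    ca = channel_attention_oracle(x, w1, b1, w2, b2)
    xp = ca[:, None, None] * x
    sa = spatial_attention_oracle(xp, *sa_w)
    return sa[None] * xp


def channel_shuffle_oracle(x, groups):
    c = x.shape[0]
    idx = np.arange(c).reshape(groups, c // groups).T.reshape(-1)
    return x[idx]


def brm_oracle(x, att_left, att_right, w31l, w31r, w13l, w13r, d, groups=2):
    """The ten-step bilateral-residual chain with zero-initialized BNs
    treated as exact identities (as in the package's identity mode)."""
    c = x.shape[0] // 2
    x1, x2 = x[:c], x[c:]
    y1 = att_left(x1) * x1
    y2 = att_right(x2) * x2
    a1 = conv2d_loop(y1, w31l, pad=(d, 0), dil=(d, 1))
    a2 = conv2d_loop(y2, w31r, pad=(d, 0), dil=(d, 1))
    shared = np.maximum(a1 + a2, 0)
    out1 = np.maximum(conv2d_loop(shared, w13l, pad=(0, d), dil=(1, d)), 0)
    out2 = np.maximum(conv2d_loop(shared, w13r, pad=(0, d), dil=(1, d)), 0)
    y = np.concatenate([out1, out2]) + x
    return channel_shuffle_oracle(y, groups)


def ppm_oracle(x, reduce_ws, proj_w, post_w, grids=(1, 2, 3, 6), groups=4):
    """Pool -> 1x1 reduce -> ReLU -> upsample -> concat -> grouped 1x1 ->
    ReLU -> shuffle -> grouped 3x3 -> residual add (BNs as identities)."""
    c, h, w = x.shape
    branches = []
    for wk, grid in zip(reduce_ws, grids):
        pooled = adaptive_avg_loop(x, grid)
        red = np.einsum("oc,chw->ohw", wk[:, :, 0, 0], pooled)
        branches.append(bilinear_loop(np.maximum(red, 0), h, w))
    y = np.concatenate(branches)
    y = np.maximum(grouped_1x1_loop(y, proj_w, groups), 0)
    y = channel_shuffle_oracle(y, groups)
    y = grouped_conv_loop(y, post_w, groups, pad=(1, 1))
    return x + y


def grouped_1x1_loop(x, w, groups):
    c = x.shape[0]
    o = w.shape[0]
    cg, og = c // groups, o // groups
    out = np.zeros((o,) + x.shape[1:])
    for g in range(groups):
        out[g * og : (g + 1) * og] = np.einsum(
            "oc,chw->ohw", w[g * og : (g + 1) * og, :, 0, 0], x[g * cg : (g + 1) * cg]
        )
    return out


def grouped_conv_loop(x, w, groups, pad):
    c = x.shape[0]
    o = w.shape[0]
    cg, og = c // groups, o // groups
    return np.concatenate([
        conv2d_loop(x[g * cg : (g + 1) * cg], w[g * og : (g + 1) * og], pad=pad)
        for g in range(groups)
    ])


def ffm_oracle(a, b, w, cout):
    """concat -> 1x1 conv -> ReLU (BN identity) -> gate = sigmoid(GAP) ->
    U * g + U."""
    u = np.maximum(np.einsum("oc,chw->ohw", w[:, :, 0, 0], np.concatenate([a, b])), 0)
    g = sigmoid(u.mean(axis=(1, 2)))
    return u * g[:, None, None] + u


def confusion_oracle(pred, gt):
    """Brute-force per-pixel tally."""
    tp = fp = fn = tn = 0
    for p, g in zip(np.ravel(pred), np.ravel(gt)):
        if p == 1 and g == 1:
            tp += 1
        elif p == 1:
            fp += 1
        elif g == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def miou_oracle(tp, fp, fn, tn):
    ious = []
    if tp + fp + fn:
        ious.append(tp / (tp + fp + fn))
    if tn + fn + fp:
        ious.append(tn / (tn + fn + fp))
    return 100.0 * sum(ious) / len(ious)
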