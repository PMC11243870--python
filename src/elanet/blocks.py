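"""Architectural primitives of the lightweight segmentation network.

* :class:`Downsample` -- parallel max-pool / strided-conv halving (DSM)
* :class:`ChannelAttention`, :class:`SpatialAttention`, :class:`CBAM`
* :func:`channel_split`, :func:`channel_shuffle`
* :class:`PyramidPooling` (PPM) -- multi-grid context aggregation
* :class:`FeatureFusion` (FFM) -- concat + gated recalibration merge
* :class:`ContextBlock` -- narrow 3x3/1x1 residual refinement

Every block maps the batch axis elementwise and reports its analytic
complexity (trainable scalars, multiply-accumulates) for a ``(C, H, W)``
input through ``param_count`` / ``macs``.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "ConvBNReLU",
    "Downsample",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "channel_split",
    "channel_shuffle",
    "PyramidPooling",
    "FeatureFusion",
    "ContextBlock",
]


class ConvBNReLU(nn.Sequential):
    """Bias-free convolution + batch norm + ReLU."""

    def __init__(self, cin, cout, kernel, stride=1, padding=0, dilation=1, groups=1):
        super().__init__(
            nn.Conv2d(cin, cout, kernel, stride, padding, dilation, groups, bias=False),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
        )


class Downsample(nn.Module):
    """Halve the resolution while growing the channel count.

    Two parallel branches -- a 2x2 max pool keeping the ``cin`` input
    channels and a strided 3x3 convolution emitting ``cout - cin`` new
    channels -- are concatenated and passed through BN + ReLU.  Compared
    with pooling alone, the convolution branch supplements learned
    features at negligible extra cost.
    """

    def __init__(self, cin: int, cout: int):
        super().__init__()
        if cout <= cin:
            raise ValueError(
                f"Downsample requires cout > cin so the convolution branch emits "
                f"cout - cin channels; got cin={cin}, cout={cout}"
            )
        self.cin, self.cout = cin, cout
        self.conv = nn.Conv2d(cin, cout - cin, 3, stride=2, padding=1, bias=False)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        merged = concat([self.conv(x), F.max_pool2d(x, 2)], axis=1)
        return self.bn(merged).relu()

    def out_shape(self, in_shape):
        _, h, w = in_shape
        return (self.cout, h // 2, w // 2)

    def macs(self, in_shape):
        return self.conv.macs(in_shape)


class ChannelAttention(nn.Module):
    """Per-channel gate: sigmoid(MLP(avgpool) + MLP(maxpool)), Eq.-(2) style.

    The two spatially pooled descriptors share one two-layer perceptron
    ``C -> max(1, C // reduction) -> C``.
    """

    def __init__(self, channels: int, reduction: int = 16, bias: bool = True):
        super().__init__()
        if reduction < 1:
            raise ValueError(f"reduction must be >= 1, got {reduction}")
        hidden = max(1, channels // reduction)
        self.channels, self.reduction, self.hidden = channels, reduction, hidden
        self.fc1 = nn.Linear(channels, hidden, bias=bias)
        self.fc2 = nn.Linear(hidden, channels, bias=bias)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = F.global_avg_pool(x).reshape(n, c)
        mx = F.global_max_pool(x).reshape(n, c)
        gate = (self._mlp(avg) + self._mlp(mx)).sigmoid()
        return gate.reshape(n, c, 1, 1)

    def out_shape(self, in_shape):
        return (self.channels, 1, 1)

    def macs(self, in_shape=None):
        return 2 * (self.fc1.macs() + self.fc2.macs())


class SpatialAttention(nn.Module):
    """Per-position gate: sigmoid of a 7x7 convolution over the channel-wise
    mean and max maps, Eq.-(3) style."""

    def __init__(self, kernel: int = 7, bias: bool = False):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()

    def out_shape(self, in_shape):
        return (1, in_shape[1], in_shape[2])

    def macs(self, in_shape):
        return self.conv.macs((2, in_shape[1], in_shape[2]))


class CBAM(nn.Module):
    """Sequential channel-then-spatial recalibration:
    F' = CA(F) * F; F'' = SA(F') * F'."""

    def __init__(self, channels: int, reduction: int = 16, bias: bool = False):
        super().__init__()
        self.ca = ChannelAttention(channels, reduction, bias=bias)
        self.sa = SpatialAttention(bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        x = self.ca(x) * x
        return self.sa(x) * x

    def macs(self, in_shape):
        return self.ca.macs(in_shape) + self.sa.macs(in_shape)


def channel_split(x: Tensor) -> tuple[Tensor, Tensor]:
    """Split the channel axis in half; concatenating the halves restores x."""
    c = x.shape[1]
    if c % 2:
        raise ValueError(f"channel_split requires an even channel count, got {c}")
    return x.narrow(1, 0, c // 2), x.narrow(1, c // 2, c // 2)


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave channel groups: reshape (g, C/g) -> transpose -> flatten."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channel_shuffle: {c} channels not divisible by groups={groups}")
    return (
        x.reshape(n, groups, c // groups, h, w)
        .transpose(0, 2, 1, 3, 4)
        .reshape(n, c, h, w)
    )


class PyramidPooling(nn.Module):
    """Pyramid pooling context aggregator with a residual output.

    Four branches reduce the input to ``C/4`` channels and average-pool it
    to 1x1, 2x2, 3x3 and 6x6 grids; each is bilinearly upsampled back and
    the concatenation (C channels) is projected by a grouped 1x1
    convolution, shuffled, refined by a grouped 3x3 convolution and added
    to the input.  With all weights zeroed (and BN in identity mode) the
    block is an exact pass-through.

    Reduction order: for average pooling a 1x1 convolution commutes with
    the pooling, so the placement of the reduction is purely an
    implementation/cost choice; here the three finer branches reduce at
    map resolution and the coarsest (6x6) branch reduces after pooling.
    """

    GRIDS = (1, 2, 3, 6)

    def __init__(self, channels: int, groups: int = 4):
        super().__init__()
        if channels % 4:
            raise ValueError(f"PyramidPooling needs channels divisible by 4, got {channels}")
        self.channels, self.groups = channels, groups
        b = channels // 4
        self.reduce = nn.Sequential(
            *[nn.Conv2d(channels, b, 1, bias=False) for _ in self.GRIDS]
        )
        self.reduce_bn = nn.Sequential(*[nn.BatchNorm2d(b) for _ in self.GRIDS])
        # all but the last (6x6) branch reduce before pooling
        self.pre_pool = (True, True, True, False)
        self.proj = nn.Conv2d(channels, channels, 1, groups=groups, bias=False)
        self.proj_bn = nn.BatchNorm2d(channels)
        self.post = nn.Conv2d(channels, channels, 3, padding=1, groups=groups, bias=False)
        self.post_bn = nn.BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        branches = []
        for conv, bn, grid, pre in zip(
            self.reduce.layers, self.reduce_bn.layers, self.GRIDS, self.pre_pool
        ):
            if pre:
                y = F.adaptive_avg_pool2d(conv(x), (grid, grid))
            else:
                y = conv(F.adaptive_avg_pool2d(x, (grid, grid)))
            branches.append(F.upsample_bilinear(bn(y).relu(), (h, w)))
        y = concat(branches, axis=1)
        y = channel_shuffle(self.proj_bn(self.proj(y)).relu(), self.groups)
        y = self.post_bn(self.post(y))
        return x + y

    def macs(self, in_shape):
        c, h, w = in_shape
        total = 0
        for conv, grid, pre in zip(self.reduce.layers, self.GRIDS, self.pre_pool):
            total += conv.macs(in_shape if pre else (c, grid, grid))
        total += self.proj.macs(in_shape) + self.post.macs(in_shape)
        return total


class FeatureFusion(nn.Module):
    """Merge two aligned streams: concat -> 1x1 conv + BN + ReLU -> U, then
    recalibrate with the gate g = sigmoid(GAP(U)) and output U*g + U."""

    def __init__(self, cin_a: int, cin_b: int, cout: int):
        super().__init__()
        self.cin_a, self.cin_b, self.cout = cin_a, cin_b, cout
        self.fuse = ConvBNReLU(cin_a + cin_b, cout, 1)

    def forward(self, a: Tensor, b: Tensor) -> Tensor:
        if a.shape[2:] != b.shape[2:]:
            raise ValueError(
                f"FeatureFusion requires equal spatial dims, got {a.shape} vs {b.shape}"
            )
        u = self.fuse(concat([a, b], axis=1))
        gate = F.global_avg_pool(u).sigmoid()
        return u * gate + u

    def out_shape(self, in_shape):
        return (self.cout, in_shape[1], in_shape[2])

    def macs(self, in_shape):
        return self.fuse.macs((self.cin_a + self.cin_b, in_shape[1], in_shape[2]))


class ContextBlock(nn.Module):
    """Narrow residual refinement: x + BN(1x1_{w->C}(ReLU(BN(3x3_{C->w}(x)))))."""

    def __init__(self, channels: int, width: int):
        super().__init__()
        self.channels, self.width = channels, width
        self.squeeze = nn.Conv2d(channels, width, 3, padding=1, bias=False)
        self.squeeze_bn = nn.BatchNorm2d(width)
        self.expand = nn.Conv2d(width, channels, 1, bias=False)
        self.expand_bn = nn.BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        y = self.squeeze_bn(self.squeeze(x)).relu()
        return x + self.expand_bn(self.expand(y))

    def macs(self, in_shape):
        c, h, w = in_shape
        return self.squeeze.macs(in_shape) + self.expand.macs((self.width, h, w))
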