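"""Bilateral residual module (BRM).

The input is channel-split into two half-width branches, each branch is
recalibrated by its own attention mechanism (channel attention on the
left, spatial attention on the right in the hybrid configuration), then
processed by factorized dilated convolutions with an explicit
cross-branch information share: the 3x1 responses a1, a2 are computed
once and their sum feeds both branches' 1x3 convolutions.  The branch
outputs are concatenated, added to the input residually and channel
shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import ChannelAttention, SpatialAttention, channel_shuffle, channel_split
from .nn.tensor import Tensor, concat

__all__ = ["BRMConfig", "BRM", "ATTENTION_MODES"]

ATTENTION_MODES = ("SA", "CA", "HA")


@dataclass
class BRMConfig:
    """Hyperparameters of one bilateral residual module.

    attention_mode: 'HA' (hybrid: channel attention left, spatial right),
    'SA' or 'CA' (the same mechanism on both branches, the single-attention
    ablations).
    """

    channels: int
    dilation: int = 1
    attention_mode: str = "HA"
    shuffle_groups: int = 2
    dropout_rate: float = 0.0
    cbam_reduction: int = 16

    def __post_init__(self):
        if self.channels % 2:
            raise ValueError(f"BRM channels must be even, got {self.channels}")
        if self.attention_mode not in ATTENTION_MODES:
            raise ValueError(
                f"attention_mode must be one of {ATTENTION_MODES}, got {self.attention_mode!r}"
            )
        if self.dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {self.dilation}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


def _make_attention(kind: str, channels: int, reduction: int) -> nn.Module:
    if kind == "CA":
        return ChannelAttention(channels, reduction, bias=True)
    return SpatialAttention(bias=False)


class BRM(nn.Module):
    def __init__(self, cfg: BRMConfig):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels // 2
        left, right = {"HA": ("CA", "SA"), "SA": ("SA", "SA"), "CA": ("CA", "CA")}[
            cfg.attention_mode
        ]
        self.att_left = _make_attention(left, c, cfg.cbam_reduction)
        self.att_right = _make_attention(right, c, cfg.cbam_reduction)
        d = cfg.dilation
        self.conv31_l = nn.Conv2d(c, c, (3, 1), padding=0, bias=False)
        self.conv31_r = nn.Conv2d(c, c, (3, 1), padding=0, bias=False)
        self.conv13_l = nn.Conv2d(c, c, (1, 3), padding=0, bias=False)
        self.conv13_r = nn.Conv2d(c, c, (1, 3), padding=0, bias=False)
        # dilation on the extended axis only; padding keeps spatial dims
        for conv in (self.conv31_l, self.conv31_r):
            conv.dilation = (d, 1)
            conv.padding = (d, 0)
        for conv in (self.conv13_l, self.conv13_r):
            conv.dilation = (1, d)
            conv.padding = (0, d)
        self.bn_l = nn.BatchNorm2d(c)
        self.bn_r = nn.BatchNorm2d(c)
        self._drop_rng = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if x.shape[1] != cfg.channels:
            raise ValueError(f"BRM built for {cfg.channels} channels, got {x.shape[1]}")
        x1, x2 = channel_split(x)
        y1 = self.att_left(x1) * x1
        y2 = self.att_right(x2) * x2
        a1 = self.conv31_l(y1)
        a2 = self.conv31_r(y2)
        shared = (a1 + a2).relu()  # cross-branch information share, computed once
        y1 = self.bn_l(self.conv13_l(shared)).relu()
        y2 = self.bn_r(self.conv13_r(shared)).relu()
        y = concat([y1, y2], axis=1)
        if cfg.dropout_rate > 0.0 and self.training:
            keep = 1.0 - cfg.dropout_rate
            mask = self._drop_rng.random(y.shape) < keep
            y = y * Tensor((mask / keep).astype(np.float32))
        return channel_shuffle(y + x, cfg.shuffle_groups)

    def macs(self, in_shape):
        c2, h, w = in_shape
        c = c2 // 2
        px = h * w
        total = 4 * 3 * c * c * px
        total += self.att_left.macs((c, h, w)) + self.att_right.macs((c, h, w))
        return total

    @staticmethod
    def conv_param_count(channels: int) -> int:
        """Closed form for the factorized-convolution parameters: 4*3*(C/2)^2."""
        return 12 * (channels // 2) ** 2
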