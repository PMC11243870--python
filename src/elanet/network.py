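"""The full lightweight attention segmentation network.

Encoder: a stem downsample to 32 channels, then three levels of stacked
bilateral residual modules (32 @ H/2, 64 @ H/4, 128 @ H/8) separated by
downsample modules.  Bottleneck: optional multi-scale attention fusion
(MAF) of the three level outputs and an optional pyramid pooling module
(PPM); in the full configuration the fusion is wide (per-scale
projections, ungrouped merge) and is followed by a dilated BRM plus a
narrow context block, while the single-module ablations use the lean
grouped fusion alone.  Decoder: two feature-fusion merges against the
stage-2 and stage-1 skips, a 3x3 refinement, a 1x1 head and bilinear
upsampling to the input resolution with a sigmoid lesion-probability
output.

Variant wiring and the widths that the architecture description leaves
open (stage repeats beyond level 1, decoder widths, fusion internals)
are frozen by ``scripts/calibrate.py`` against the published parameter
and multiply-accumulate budgets of the six ablation variants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import (CBAM, ContextBlock, ConvBNReLU, Downsample,
                     FeatureFusion, PyramidPooling, channel_shuffle)
from .brm import ATTENTION_MODES, BRM, BRMConfig
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "NetworkConfig",
    "AblationSpec",
    "ABLATION_TABLE",
    "make_ablation",
    "MultiScaleFusion",
    "ELANet",
    "build",
    "save_checkpoint",
    "load_checkpoint",
]

# per-stage dilation patterns, cycled over the stage depth
_DILATION_CYCLES = ((1,), (1, 2, 5), (1, 2, 5, 9, 2, 5))


def _default_dilations(repeats):
    return tuple(
        tuple(cycle[i % len(cycle)] for i in range(n))
        for cycle, n in zip(_DILATION_CYCLES, repeats)
    )


@dataclass
class NetworkConfig:
    """Complete architectural hyperparameters.

    The defaults are the calibrated full model; ``make_ablation`` derives
    the five reduced variants from them.
    """

    in_channels: int = 3
    stage_widths: tuple[int, int, int] = (32, 64, 128)
    brm_repeats: tuple[int, int, int] = (3, 3, 3)
    dilation_schedule: tuple[tuple[int, ...], ...] | None = None
    attention_mode: str = "HA"
    use_maf: bool = True
    use_ppm: bool = True
    cbam_reduction: int = 16
    num_classes: int = 1
    input_size: tuple[int, int] = (512, 1024)  # (height, width)
    # calibrated internals
    decoder_widths: tuple[int, int] = (54, 50)
    head_width: int = 24
    maf_groups: int = 2          # lean fusion projection groups
    ppm_groups: int = 4
    refine_dilation: int = 2     # dilation of the full-model bottleneck BRM
    context_width: int = 20      # squeeze width of the full-model context block
    seed: int = 0

    def __post_init__(self):
        errors = []
        w = self.stage_widths
        if not all(a < b for a, b in zip(w, w[1:])):
            errors.append(f"stage_widths must be strictly increasing, got {w}")
        if any(x % 2 for x in w):
            errors.append(f"stage_widths must all be even, got {w}")
        if any(n < 1 for n in self.brm_repeats):
            errors.append(f"brm_repeats must all be >= 1, got {self.brm_repeats}")
        h, wd = self.input_size
        if h % 8 or wd % 8:
            errors.append(f"input_size must be divisible by 8, got {self.input_size}")
        if self.attention_mode not in ATTENTION_MODES:
            errors.append(f"attention_mode must be in {ATTENTION_MODES}")
        if errors:
            raise ValueError("invalid NetworkConfig: " + "; ".join(errors))
        if self.dilation_schedule is None:
            self.dilation_schedule = _default_dilations(self.brm_repeats)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        raw = json.loads(text)
        for key in ("stage_widths", "brm_repeats", "input_size", "decoder_widths"):
            raw[key] = tuple(raw[key])
        raw["dilation_schedule"] = tuple(tuple(d) for d in raw["dilation_schedule"])
        return cls(**raw)


@dataclass
class AblationSpec:
    """One row of the component-ablation grid (model ids 1..6)."""

    model_id: int
    maf: bool
    ppm: bool
    attention_mode: str


ABLATION_TABLE: dict[int, AblationSpec] = {
    1: AblationSpec(1, False, False, "SA"),
    2: AblationSpec(2, False, False, "CA"),
    3: AblationSpec(3, False, False, "HA"),
    4: AblationSpec(4, True, False, "HA"),
    5: AblationSpec(5, False, True, "HA"),
    6: AblationSpec(6, True, True, "HA"),
}


def make_ablation(spec: AblationSpec | int, **overrides) -> NetworkConfig:
    """NetworkConfig for an ablation variant (model 6 == the default)."""
    if isinstance(spec, int):
        if spec not in ABLATION_TABLE:
            raise ValueError(f"model_id must be in 1..6, got {spec}")
        spec = ABLATION_TABLE[spec]
    return NetworkConfig(
        attention_mode=spec.attention_mode,
        use_maf=spec.maf,
        use_ppm=spec.ppm,
        **overrides,
    )


class MultiScaleFusion(nn.Module):
    """CBAM-gated aggregation of the three encoder scales to C3 @ H/8.

    Each scale passes through its own CBAM; the finer scales are
    average-pooled to the coarsest grid and the concatenation is projected
    to ``c3`` channels.  ``wide=True`` (the full model) adds per-scale 1x1
    projections at native resolution and uses an ungrouped merge;
    ``wide=False`` (the lean ablation variant) uses a grouped merge
    followed by a channel shuffle.
    """

    def __init__(self, widths: tuple[int, int, int], reduction: int,
                 groups: int, wide: bool):
        super().__init__()
        c1, c2, c3 = widths
        self.widths, self.wide, self.groups = widths, wide, groups
        self.cbam1 = CBAM(c1, reduction, bias=False)
        self.cbam2 = CBAM(c2, reduction, bias=False)
        self.cbam3 = CBAM(c3, reduction, bias=False)
        if wide:
            self.proj1 = ConvBNReLU(c1, c1, 1)
            self.proj2 = ConvBNReLU(c2, c2, 1)
            self.proj3 = ConvBNReLU(c3, c3, 1)
            self.merge = ConvBNReLU(sum(widths), c3, 1)
        else:
            self.merge = ConvBNReLU(sum(widths), c3, 1, groups=groups)

    def forward(self, s1: Tensor, s2: Tensor, s3: Tensor) -> Tensor:
        h, w = s3.shape[2], s3.shape[3]
        if s1.shape[2] != 4 * h or s2.shape[2] != 2 * h:
            raise ValueError(
                "fusion inputs are not one encoder pyramid: "
                f"{s1.shape} / {s2.shape} / {s3.shape}"
            )
        s1 = self.cbam1(s1)
        s2 = self.cbam2(s2)
        s3 = self.cbam3(s3)
        if self.wide:
            s1, s2, s3 = self.proj1(s1), self.proj2(s2), self.proj3(s3)
        y = concat([F.avg_pool2d(s1, 4), F.avg_pool2d(s2, 2), s3], axis=1)
        y = self.merge(y)
        if not self.wide:
            y = channel_shuffle(y, self.groups)
        return y

    def macs(self, shapes) -> int:
        """shapes: ((c1,h1,w1), (c2,h2,w2), (c3,h3,w3))."""
        (c1, h1, w1), (c2, h2, w2), (c3, h3, w3) = shapes
        total = self.cbam1.macs(shapes[0]) + self.cbam2.macs(shapes[1]) + self.cbam3.macs(shapes[2])
        if self.wide:
            total += self.proj1.macs(shapes[0]) + self.proj2.macs(shapes[1]) + self.proj3.macs(shapes[2])
        total += self.merge.macs((c1 + c2 + c3, h3, w3))
        return total


class ELANet(nn.Module):
    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        c1, c2, c3 = cfg.stage_widths
        n1, n2, n3 = cfg.brm_repeats
        dil = cfg.dilation_schedule

        def stage(width, count, dils):
            return nn.Sequential(*[
                BRM(BRMConfig(width, dils[i], cfg.attention_mode,
                              cbam_reduction=cfg.cbam_reduction))
                for i in range(count)
            ])

        self.stem = Downsample(cfg.in_channels, c1)
        self.stage1 = stage(c1, n1, dil[0])
        self.down2 = Downsample(c1, c2)
        self.stage2 = stage(c2, n2, dil[1])
        self.down3 = Downsample(c2, c3)
        self.stage3 = stage(c3, n3, dil[2])

        full = cfg.use_maf and cfg.use_ppm
        if cfg.use_maf:
            self.maf = MultiScaleFusion(cfg.stage_widths, cfg.cbam_reduction,
                                        cfg.maf_groups, wide=full)
        if cfg.use_ppm:
            self.ppm = PyramidPooling(c3, groups=cfg.ppm_groups)
        if full:
            self.refine = BRM(BRMConfig(c3, cfg.refine_dilation, cfg.attention_mode,
                                        cbam_reduction=cfg.cbam_reduction))
            self.context = ContextBlock(c3, cfg.context_width)

        f1, f2 = cfg.decoder_widths
        self.ffm1 = FeatureFusion(c3, c2, f1)
        self.ffm2 = FeatureFusion(f1, c1, f2)
        self.prehead = ConvBNReLU(f2, cfg.head_width, 3, padding=1)
        self.head = nn.Conv2d(cfg.head_width, cfg.num_classes, 1, bias=True)

    # -- forward ---------------------------------------------------------
    def encode(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        s1 = self.stage1(self.stem(x))
        s2 = self.stage2(self.down2(s1))
        s3 = self.stage3(self.down3(s2))
        return s1, s2, s3

    def bottleneck(self, s1: Tensor, s2: Tensor, s3: Tensor) -> Tensor:
        cfg = self.cfg
        y = s3
        if cfg.use_maf:
            y = self.maf(s1, s2, s3)
        if cfg.use_ppm:
            y = self.ppm(y)
        if cfg.use_maf and cfg.use_ppm:
            y = self.context(self.refine(y))
        return y

    def forward_logits(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 8 or w % 8:
            raise ValueError(
                f"input of {h}x{w} is not divisible by 8; resize (e.g. letterbox) first"
            )
        s1, s2, s3 = self.encode(x)
        y = self.bottleneck(s1, s2, s3)
        y = self.ffm1(F.upsample_bilinear(y, (h // 4, w // 4)), s2)
        y = self.ffm2(F.upsample_bilinear(y, (h // 2, w // 2)), s1)
        y = self.head(self.prehead(y))
        return F.upsample_bilinear(y, (h, w))

    def forward(self, x: Tensor) -> Tensor:
        """Per-pixel lesion probability in (0, 1), same resolution as input."""
        return self.forward_logits(x).sigmoid()

    # -- complexity ------------------------------------------------------
    def components(self, input_hw: tuple[int, int] | None = None):
        """Yield (path, module, in_shape) for every costed component."""
        cfg = self.cfg
        h, w = input_hw or cfg.input_size
        c1, c2, c3 = cfg.stage_widths
        sh1, sh2, sh3 = (c1, h // 2, w // 2), (c2, h // 4, w // 4), (c3, h // 8, w // 8)
        yield "stem", self.stem, (cfg.in_channels, h, w)
        for i, m in enumerate(self.stage1.layers):
            yield f"stage1.{i}", m, sh1
        yield "down2", self.down2, sh1
        for i, m in enumerate(self.stage2.layers):
            yield f"stage2.{i}", m, sh2
        yield "down3", self.down3, sh2
        for i, m in enumerate(self.stage3.layers):
            yield f"stage3.{i}", m, sh3
        if cfg.use_maf:
            yield "maf", self.maf, (sh1, sh2, sh3)
        if cfg.use_ppm:
            yield "ppm", self.ppm, sh3
        if cfg.use_maf and cfg.use_ppm:
            yield "refine", self.refine, sh3
            yield "context", self.context, sh3
        f1, f2 = cfg.decoder_widths
        yield "ffm1", self.ffm1, (c3, h // 4, w // 4)
        yield "ffm2", self.ffm2, (f1, h // 2, w // 2)
        yield "prehead", self.prehead, (f2, h // 2, w // 2)
        yield "head", self.head, (cfg.head_width, h // 2, w // 2)


def build(cfg: NetworkConfig | None = None) -> ELANet:
    """Construct and initialize the network (seeded from cfg.seed)."""
    cfg = cfg or NetworkConfig()
    net = ELANet(cfg)
    net.initialize(np.random.default_rng(cfg.seed))
    return net


def save_checkpoint(path, net: ELANet, extra: dict | None = None):
    """Single-file weights container with an embedded config echo."""
    payload = {f"param/{k}": v for k, v in net.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        net.cfg.to_json().encode(), dtype=np.uint8
    )
    if extra:
        payload["extra_json"] = np.frombuffer(
            json.dumps(extra).encode(), dtype=np.uint8
        )
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[ELANet, dict]:
    with np.load(path) as z:
        cfg = NetworkConfig.from_json(bytes(z["config_json"]).decode())
        net = ELANet(cfg)
        net.load_state_dict(
            {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        )
        extra = json.loads(bytes(z["extra_json"]).decode()) if "extra_json" in z.files else {}
    return net, extra
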