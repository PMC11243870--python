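"""Dataset handling: ISIC-style directory reading, letterbox resizing,
the training augmentation recipe, and a synthetic dermoscopy-like lesion
generator.

The generator emulates the three hard regimes seen in dermoscopic lesion
photographs: *oversized* lesions whose boundary leaves the frame
(foreground fraction > 0.5), *irregular* lesions with strongly non-convex
outlines, and *blurred* lesions whose image boundary is low-contrast and
smoothed while the reference mask stays crisp.  Lesions are star-convex
polygons with randomized radial harmonics on a skin-toned, low-frequency
textured background; the mask is the exact polygon rasterization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

__all__ = [
    "ImageSample",
    "AugmentConfig",
    "SyntheticLesionSpec",
    "load_dataset",
    "write_dataset",
    "letterbox",
    "augment",
    "synthesize",
    "synthesize_mixed",
    "split_train_val",
]

_IMG_EXT = (".png", ".jpg", ".jpeg")
_MASK_SUFFIX = "_segmentation"


@dataclass
class ImageSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    id: str
    source: str = "disk"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"sample {self.id}: image {self.image.shape[:2]} and mask "
                f"{self.mask.shape} spatial dims differ"
            )


@dataclass
class AugmentConfig:
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.0, 2.0)
    rotation_degrees: float = 30.0
    target_size: tuple[int, int] = (512, 1024)  # (height, width)
    pad_value: int = 128
    seed: int = 0

    def __post_init__(self):
        h, w = self.target_size
        if h % 8 or w % 8:
            raise ValueError(f"target_size must be divisible by 8, got {self.target_size}")


@dataclass
class SyntheticLesionSpec:
    size: tuple[int, int] = (128, 128)  # (height, width)
    case: str = "irregular"             # oversized | irregular | blurred
    lesion_area_fraction: tuple[float, float] | None = None
    boundary_blur_sigma: float = 2.5
    background_texture_scale: float = 12.0
    seed: int = 0

    _DEFAULT_FRACTIONS = {
        "oversized": (0.55, 0.80),
        "irregular": (0.10, 0.40),
        "blurred": (0.10, 0.40),
    }

    def __post_init__(self):
        if self.case not in self._DEFAULT_FRACTIONS:
            raise ValueError(f"case must be one of {tuple(self._DEFAULT_FRACTIONS)}")
        if self.lesion_area_fraction is None:
            self.lesion_area_fraction = self._DEFAULT_FRACTIONS[self.case]
        lo, hi = self.lesion_area_fraction
        if not (0.0 < lo <= hi < 0.95):
            raise ValueError(f"area fraction interval must lie in (0, 0.95), got {(lo, hi)}")
        if self.case == "oversized" and hi <= 0.5:
            raise ValueError(
                f"oversized lesions require area fractions above 0.5, got {(lo, hi)}"
            )


# -- disk IO --------------------------------------------------------------

def _stem(path: Path) -> str:
    s = path.stem
    return s[: -len(_MASK_SUFFIX)] if s.endswith(_MASK_SUFFIX) else s


def load_dataset(images_dir, masks_dir) -> list[ImageSample]:
    """Read stem-matched image/mask pairs, sorted by stem.

    Masks are binarized with the >127 rule.  Unmatched stems on either
    side raise a single error listing all offenders.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    imgs = {p.stem: p for p in sorted(images_dir.glob("*")) if p.suffix.lower() in _IMG_EXT}
    masks = {_stem(p): p for p in sorted(masks_dir.glob("*")) if p.suffix.lower() in _IMG_EXT}
    missing = sorted(set(imgs) ^ set(masks))
    if missing:
        raise ValueError(f"unpaired stems between {images_dir} and {masks_dir}: {missing}")
    samples = []
    for stem in sorted(imgs):
        image = np.asarray(Image.open(imgs[stem]).convert("RGB"))
        mask = (np.asarray(Image.open(masks[stem]).convert("L")) > 127).astype(np.uint8)
        samples.append(ImageSample(image, mask, stem, source="disk"))
    return samples


def write_dataset(samples: list[ImageSample], root) -> None:
    """Write samples to the same layout load_dataset reads (images/, masks/)."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        Image.fromarray(s.image).save(root / "images" / f"{s.id}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            root / "masks" / f"{s.id}{_MASK_SUFFIX}.png"
        )


# -- geometry --------------------------------------------------------------

def letterbox_geometry(src_hw, target_hw):
    """(scale, content (h, w), offset (top, left)) of an aspect-preserving fit."""
    sh, sw = src_hw
    th, tw = target_hw
    if sh == 0 or sw == 0:
        raise ValueError(f"zero-area input {src_hw}")
    scale = min(th / sh, tw / sw)
    ch = max(1, round(sh * scale))
    cw = max(1, round(sw * scale))
    return scale, (ch, cw), ((th - ch) // 2, (tw - cw) // 2)


def letterbox(sample: ImageSample, target=(512, 1024), pad_value: int = 128) -> ImageSample:
    """Aspect-preserving resize into a gray-padded target frame.

    The mask undergoes the identical geometry with nearest-neighbour
    resampling and zero padding, so it stays strictly binary.
    """
    th, tw = target
    _, (ch, cw), (top, left) = letterbox_geometry(sample.image.shape[:2], target)
    img = np.asarray(
        Image.fromarray(sample.image).resize((cw, ch), Image.BILINEAR)
    )
    msk = np.asarray(
        Image.fromarray(sample.mask, mode="L").resize((cw, ch), Image.NEAREST)
    )
    out_img = np.full((th, tw, 3), pad_value, dtype=np.uint8)
    out_msk = np.zeros((th, tw), dtype=np.uint8)
    out_img[top : top + ch, left : left + cw] = img
    out_msk[top : top + ch, left : left + cw] = msk
    return ImageSample(out_img, out_msk, sample.id, sample.source)


def augment(sample: ImageSample, cfg: AugmentConfig,
            rng: np.random.Generator | None = None) -> ImageSample:
    """Random flip / rotation / Gaussian blur, then letterbox.

    Geometry is applied identically to image and mask (mask via nearest
    neighbour); blur touches the image only.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    img, msk = sample.image, sample.mask
    if rng.random() < cfg.hflip_prob:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < cfg.vflip_prob:
        img, msk = img[::-1], msk[::-1]
    angle = float(rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees))
    if abs(angle) > 1e-6:
        img = ndimage.rotate(img, angle, axes=(1, 0), reshape=False, order=1,
                             mode="constant", cval=cfg.pad_value)
        msk = ndimage.rotate(msk, angle, axes=(1, 0), reshape=False, order=0,
                             mode="constant", cval=0)
    sigma = float(rng.uniform(*cfg.blur_sigma_range))
    if sigma > 1e-3:
        img = ndimage.gaussian_filter(img.astype(np.float32), (sigma, sigma, 0))
    img = np.clip(img, 0, 255).astype(np.uint8)
    out = ImageSample(np.ascontiguousarray(img), np.ascontiguousarray(msk),
                      sample.id, sample.source)
    return letterbox(out, cfg.target_size, cfg.pad_value)


# -- synthesis --------------------------------------------------------------

def _radial_profile(rng: np.random.Generator, irregular: bool, n_theta: int = 256):
    """Unit star-convex radial function r(theta) with random harmonics."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    r = np.ones(n_theta)
    harmonics = range(2, 9)
    amp = 0.28 if irregular else 0.10
    for k in harmonics:
        a = rng.uniform(0, amp) / np.sqrt(k - 1)
        phi = rng.uniform(0, 2 * np.pi)
        r += a * np.cos(k * theta + phi)
    return theta, np.clip(r, 0.15, None)


def _clipped_fraction(theta, r, center, scale, shape) -> tuple[float, np.ndarray]:
    cy, cx = center
    rows = cy + scale * r * np.sin(theta)
    cols = cx + scale * r * np.cos(theta)
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rr, cc] = 1
    return mask.mean(), mask


def _lesion_mask(rng, spec: SyntheticLesionSpec) -> np.ndarray:
    h, w = spec.size
    target = rng.uniform(*spec.lesion_area_fraction)
    theta, r = _radial_profile(rng, irregular=spec.case == "irregular")
    if spec.case == "oversized":
        center = (h * rng.uniform(0.38, 0.62), w * rng.uniform(0.38, 0.62))
    else:
        center = (h * rng.uniform(0.30, 0.70), w * rng.uniform(0.30, 0.70))
    # bisect the radial scale: the clipped foreground fraction is monotone in it
    lo, hi = 1.0, 2.5 * max(h, w)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        frac, mask = _clipped_fraction(theta, r, center, mid, (h, w))
        if frac < target:
            lo = mid
        else:
            hi = mid
    return mask


_SKIN = np.array([208.0, 162.0, 140.0])
_LESION = np.array([118.0, 72.0, 58.0])


def _texture(rng, shape, scale) -> np.ndarray:
    """Low-frequency noise field in [-1, 1] with correlation length ~scale."""
    h, w = shape
    gh, gw = max(2, int(np.ceil(h / scale))), max(2, int(np.ceil(w / scale)))
    coarse = rng.normal(size=(gh, gw))
    field = ndimage.zoom(coarse, (h / gh, w / gw), order=3)[:h, :w]
    m = np.abs(field).max() or 1.0
    return field / m


def _render(rng, spec: SyntheticLesionSpec, mask: np.ndarray) -> np.ndarray:
    h, w = spec.size
    blurred = spec.case == "blurred"
    lesion_rgb = _LESION + (_SKIN - _LESION) * (0.45 if blurred else 0.0)
    alpha = mask.astype(np.float64)
    if blurred:
        alpha = ndimage.gaussian_filter(alpha, spec.boundary_blur_sigma)
    img = np.empty((h, w, 3))
    bg_tex = _texture(rng, (h, w), spec.background_texture_scale)
    fg_tex = _texture(rng, (h, w), spec.background_texture_scale / 2)
    for c in range(3):
        bg = _SKIN[c] * (1 + 0.06 * bg_tex)
        fg = lesion_rgb[c] * (1 + 0.10 * fg_tex)
        img[:, :, c] = bg * (1 - alpha) + fg * alpha
    img += rng.normal(0, 2.0, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def synthesize(spec: SyntheticLesionSpec, n: int) -> list[ImageSample]:
    """Generate ``n`` seeded, reproducible lesion samples for one regime."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    samples = []
    for i in range(n):
        rng = np.random.default_rng([spec.seed, i])
        mask = _lesion_mask(rng, spec)
        image = _render(rng, spec, mask)
        samples.append(
            ImageSample(image, mask, f"synthetic_{spec.case}_{spec.seed}_{i:04d}",
                        source="synthetic")
        )
    return samples


def synthesize_mixed(size, n: int, seed: int = 0) -> list[ImageSample]:
    """Round-robin over the three regimes (n samples in total)."""
    cases = ("oversized", "irregular", "blurred")
    per = {c: synthesize(SyntheticLesionSpec(size=size, case=c, seed=seed + j), (n + 2) // 3)
           for j, c in enumerate(cases)}
    out = []
    for i in range(n):
        out.append(per[cases[i % 3]][i // 3])
    return out


def split_train_val(samples: list[ImageSample], val_fraction: float = 0.2,
                    seed: int = 0) -> tuple[list[ImageSample], list[ImageSample]]:
    """Deterministic shuffled split (val gets ceil(n * val_fraction))."""
    order = np.random.default_rng(seed).permutation(len(samples))
    n_val = int(np.ceil(len(samples) * val_fraction))
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(samples) if i not in val_idx]
    val = [s for i, s in enumerate(samples) if i in val_idx]
    return train, val
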