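"""Dataset I/O, augmentation, splitting, and synthetic field scenes.

Samples are RGB images with per-pixel labels in {0 background, 1 corn,
2 weed}; label 255 marks ignored pixels (excluded from loss and metrics).
Datasets live on disk in the Pascal VOC segmentation layout::

    root/
      JPEGImages/<id>.jpg
      SegmentationClass/<id>.png        # palette-indexed PNG
      ImageSets/Segmentation/{train,val,trainval}.txt

The augmentation suite emits, per input, the original plus one variant for
each of five operations (horizontal flip, rotation within ±25°, Gaussian
blur, random crop to 80% area, HSV jitter), a sixfold expansion.  Geometric
operations transform image and mask with the same spatial map, masks always
by nearest-neighbor resampling; photometric operations leave the mask
untouched.

The synthetic generator stands in for field photographs that are not
publicly deposited.  Each scene is a textured soil background with one to
three maize plants drawn as elongated leaves radiating from a stem center
and a scatter of small weed rosettes — the radially-leaved geometry that
directional strip pooling is designed to capture.  Labels are exact by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

__all__ = [
    "IGNORE_LABEL",
    "CLASS_NAMES",
    "VOC_PALETTE",
    "SegSample",
    "SyntheticConfig",
    "read_voc_dataset",
    "write_voc_dataset",
    "augment_sixfold",
    "AUGMENTATION_KINDS",
    "split_dataset",
    "generate_synthetic_field",
]

IGNORE_LABEL = 255
CLASS_NAMES = ("background", "corn", "weed")

# palette index -> display color (background, corn, weed, ..., ignore)
VOC_PALETTE = {0: (0, 0, 0), 1: (0, 128, 0), 2: (128, 0, 0), 255: (224, 224, 192)}

AUGMENTATION_KINDS = ("flip", "rotation", "gaussian_blur", "random_crop", "hsv")


@dataclass
class SegSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8 labels in {0, 1, 2, IGNORE_LABEL}
    id: str

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"{self.id}: image must be (H, W, 3)")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(f"{self.id}: image and mask sizes differ")
        bad = set(np.unique(self.mask)) - {0, 1, 2, IGNORE_LABEL}
        if bad:
            raise ValueError(f"{self.id}: unexpected mask labels {sorted(bad)}")


# ---------------------------------------------------------------------------
# Pascal VOC layout
# ---------------------------------------------------------------------------


def _palette_bytes() -> bytes:
    pal = np.zeros((256, 3), dtype=np.uint8)
    for idx, rgb in VOC_PALETTE.items():
        pal[idx] = rgb
    return pal.tobytes()


def write_voc_dataset(
    samples: list[SegSample],
    root,
    split_ratio: float | None = 0.9,
    seed: int = 0,
) -> Path:
    """Write samples in VOC layout; optionally also write a train/val split."""
    root = Path(root)
    img_dir = root / "JPEGImages"
    msk_dir = root / "SegmentationClass"
    set_dir = root / "ImageSets" / "Segmentation"
    for d in (img_dir, msk_dir, set_dir):
        d.mkdir(parents=True, exist_ok=True)
    for s in samples:
        Image.fromarray(s.image).save(img_dir / f"{s.id}.jpg", quality=95)
        png = Image.fromarray(s.mask, mode="P")
        png.putpalette(_palette_bytes())
        png.save(msk_dir / f"{s.id}.png")
    names = [s.id for s in samples]
    (set_dir / "trainval.txt").write_text("\n".join(names) + "\n")
    if split_ratio is not None and len(samples) >= 2:
        train, val = split_dataset(samples, split_ratio, seed)
        (set_dir / "train.txt").write_text("\n".join(s.id for s in train) + "\n")
        (set_dir / "val.txt").write_text("\n".join(s.id for s in val) + "\n")
    return root


def read_voc_dataset(root, split: str | None = None) -> list[SegSample]:
    """Load a VOC-layout dataset.

    ``split`` names a list file under ImageSets/Segmentation (e.g. "train");
    by default every annotated basename is loaded.
    """
    root = Path(root)
    img_dir = root / "JPEGImages"
    msk_dir = root / "SegmentationClass"
    if split is not None:
        list_file = root / "ImageSets" / "Segmentation" / f"{split}.txt"
        if not list_file.exists():
            raise FileNotFoundError(f"missing split list {list_file}")
        names = [ln.strip() for ln in list_file.read_text().splitlines() if ln.strip()]
    else:
        names = sorted(p.stem for p in msk_dir.glob("*.png"))
    samples = []
    for name in names:
        ipath = img_dir / f"{name}.jpg"
        mpath = msk_dir / f"{name}.png"
        if not ipath.exists():
            raise FileNotFoundError(f"missing image for basename {name!r}")
        if not mpath.exists():
            raise FileNotFoundError(f"missing mask for basename {name!r}")
        image = np.asarray(Image.open(ipath).convert("RGB"))
        with Image.open(mpath) as png:
            if png.mode != "P":
                raise ValueError(f"{name!r}: mask PNG is not palette-indexed")
            mask = np.asarray(png)
        samples.append(SegSample(image=image, mask=mask, id=name))
    return samples


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _aug_flip(s: SegSample, rng) -> SegSample:
    return SegSample(s.image[:, ::-1].copy(), s.mask[:, ::-1].copy(), f"{s.id}_flip")


def _aug_rotation(s: SegSample, rng) -> SegSample:
    angle = float(rng.uniform(-25.0, 25.0))
    img = sktransform.rotate(
        s.image, angle, resize=False, order=1, mode="reflect", preserve_range=True
    )
    msk = sktransform.rotate(
        s.mask.astype(np.float64),
        angle,
        resize=False,
        order=0,
        mode="constant",
        cval=IGNORE_LABEL,
        preserve_range=True,
    )
    return SegSample(
        np.clip(img, 0, 255).astype(np.uint8),
        msk.astype(np.uint8),
        f"{s.id}_rot",
    )


def _aug_blur(s: SegSample, rng) -> SegSample:
    sigma = float(rng.uniform(1.0, 2.0))
    img = ndimage.gaussian_filter(s.image.astype(np.float32), sigma=(sigma, sigma, 0))
    return SegSample(
        np.clip(img, 0, 255).astype(np.uint8), s.mask.copy(), f"{s.id}_blur"
    )


def _aug_crop(s: SegSample, rng, area: float = 0.8) -> SegSample:
    h, w = s.mask.shape
    scale = math.sqrt(area)
    ch, cw = max(1, round(h * scale)), max(1, round(w * scale))
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    img = s.image[y0 : y0 + ch, x0 : x0 + cw]
    msk = s.mask[y0 : y0 + ch, x0 : x0 + cw]
    img = sktransform.resize(img, (h, w), order=1, preserve_range=True,
                             anti_aliasing=True)
    msk = sktransform.resize(msk, (h, w), order=0, preserve_range=True,
                             anti_aliasing=False)
    return SegSample(
        np.clip(img, 0, 255).astype(np.uint8), msk.astype(np.uint8), f"{s.id}_crop"
    )


def _aug_hsv(s: SegSample, rng) -> SegSample:
    hsv = skcolor.rgb2hsv(s.image)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-10 / 360, 10 / 360)) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(0.8, 1.2), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(0.8, 1.2), 0, 1)
    img = np.clip(skcolor.hsv2rgb(hsv) * 255.0, 0, 255).astype(np.uint8)
    return SegSample(img, s.mask.copy(), f"{s.id}_hsv")


_AUG_FNS = {
    "flip": _aug_flip,
    "rotation": _aug_rotation,
    "gaussian_blur": _aug_blur,
    "random_crop": _aug_crop,
    "hsv": _aug_hsv,
}


def augment_sixfold(samples: list[SegSample], seed: int = 0) -> list[SegSample]:
    """Original + one variant per operation = exactly 6 outputs per input."""
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        out.append(s)
        for kind in AUGMENTATION_KINDS:
            out.append(_AUG_FNS[kind](s, rng))
    return out


def split_dataset(
    samples: list[SegSample], ratio: float = 0.9, seed: int = 0
) -> tuple[list[SegSample], list[SegSample]]:
    """Random disjoint train/val split; |train| = floor(ratio·n + 0.5)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = len(samples)
    if n < 2:
        raise ValueError("need at least two samples to split")
    n_train = int(math.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:]]
    return train, val


# ---------------------------------------------------------------------------
# Synthetic maize/weed scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Scene composition knobs.

    ``corn_fraction`` is the accepted range of per-scene maize pixel share;
    scenes are adjusted (leaf widths rescaled) until the realized share falls
    inside it.  ``require_all_classes`` guarantees every emitted mask contains
    background, corn and weed pixels.
    """

    plants: tuple[int, int] = (1, 3)
    leaves_per_plant: tuple[int, int] = (5, 9)
    weeds: tuple[int, int] = (2, 8)
    corn_fraction: tuple[float, float] = (0.10, 0.40)
    require_all_classes: bool = True


def _draw_ellipse(mask, cy, cx, a, b, theta, label):
    """Rasterize a rotated ellipse into ``mask`` (in place)."""
    h, w = mask.shape
    r = int(math.ceil(max(a, b))) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask[y0:y1, x0:x1][inside] = label


def _smooth_noise(rng, size, sigma, lo, hi):
    g = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma)
    g -= g.min()
    rng_span = g.max() - g.min()
    if rng_span > 0:
        g /= rng_span
    return lo + g * (hi - lo)


def _render_scene(rng, size: int, cfg: SyntheticConfig) -> SegSample:
    # soil: brown base + low-frequency illumination + fine grain
    base = np.array([120, 92, 64], np.float32)
    illum = _smooth_noise(rng, size, sigma=size / 6, lo=0.75, hi=1.2)
    grain = rng.normal(0, 9, size=(size, size, 3)).astype(np.float32)
    img = base[None, None] * illum[..., None] + grain

    mask = np.zeros((size, size), np.uint8)

    # maize plants: elongated leaves radiating from a stem center
    n_plants = int(rng.integers(cfg.plants[0], cfg.plants[1] + 1))
    plant_params = []
    for _ in range(n_plants):
        cy = rng.uniform(0.22, 0.78) * size
        cx = rng.uniform(0.22, 0.78) * size
        n_leaves = int(rng.integers(cfg.leaves_per_plant[0],
                                    cfg.leaves_per_plant[1] + 1))
        base_angle = rng.uniform(0, math.pi)
        leaves = []
        for k in range(n_leaves):
            theta = base_angle + 2 * math.pi * k / n_leaves + rng.uniform(-0.25, 0.25)
            a = rng.uniform(0.12, 0.24) * size  # leaf half-length
            b = a * rng.uniform(0.16, 0.26)  # leaf half-width
            # leaf midpoint sits one half-length out along its direction
            leaves.append((cy + a * math.sin(theta), cx + a * math.cos(theta),
                           a, b, theta))
        plant_params.append(leaves)

    # weed rosettes: clusters of small leaves, drawn on top of maize
    weed_params = []
    n_weeds = int(rng.integers(cfg.weeds[0], cfg.weeds[1] + 1))
    for _ in range(n_weeds):
        cy = rng.uniform(0.06, 0.94) * size
        cx = rng.uniform(0.06, 0.94) * size
        for _ in range(int(rng.integers(3, 7))):
            theta = rng.uniform(0, math.pi)
            # a rosette leaf has a minimum physical size regardless of the
            # rendered resolution, so floor the axes at a few pixels
            a = max(rng.uniform(0.015, 0.05) * size, 2.5)
            b = max(a * rng.uniform(0.35, 0.7), 1.2)
            weed_params.append((cy + rng.uniform(-2, 2), cx + rng.uniform(-2, 2),
                                a, b, theta))

    def draw(width_scale: float) -> None:
        mask.fill(0)
        for leaves in plant_params:
            for cy, cx, a, b, theta in leaves:
                _draw_ellipse(mask, cy, cx, a, min(b * width_scale, a), theta, 1)
        for cy, cx, a, b, theta in weed_params:
            _draw_ellipse(mask, cy, cx, a, b, theta, 2)

    # adjust leaf widths until the maize pixel share (weeds included, since
    # they overdraw maize) meets the contract; covered area grows roughly
    # linearly with leaf width, so a proportional correction converges fast
    target_lo, target_hi = cfg.corn_fraction
    target_mid = 0.5 * (target_lo + target_hi)
    width_scale = 1.0
    for _ in range(12):
        draw(width_scale)
        frac = (mask == 1).mean()
        if target_lo <= frac <= target_hi:
            break
        width_scale *= float(np.clip(target_mid / max(frac, 1e-4), 0.6, 1.8))

    if cfg.require_all_classes:
        # weeds may have been fully overdrawn only if they never landed; the
        # draw order already keeps weeds on top, so just ensure presence
        if not (mask == 2).any():
            _draw_ellipse(mask, size * 0.1, size * 0.1, size * 0.04, size * 0.02,
                          0.5, 2)
        if not (mask == 1).any():  # pragma: no cover - fraction loop prevents this
            _draw_ellipse(mask, size * 0.5, size * 0.5, size * 0.2, size * 0.05,
                          0.3, 1)

    # vegetation colors with per-scene tone jitter
    corn_col = np.array([52, 128, 38], np.float32) * rng.uniform(0.85, 1.15)
    weed_col = np.array([80, 150, 70], np.float32) * rng.uniform(0.85, 1.15)
    veg_tex = _smooth_noise(rng, size, sigma=2.5, lo=0.8, hi=1.2)
    img[mask == 1] = corn_col[None] * veg_tex[mask == 1, None]
    img[mask == 2] = weed_col[None] * veg_tex[mask == 2, None]
    img *= illum[..., None] ** 0.3  # mild shared shading so classes are not flat
    img += rng.normal(0, 4, size=img.shape)

    return np.clip(img, 0, 255).astype(np.uint8), mask


def generate_synthetic_field(
    n: int,
    size: int = 512,
    seed: int = 0,
    class_balance: SyntheticConfig | None = None,
) -> list[SegSample]:
    """Generate ``n`` seeded synthetic field scenes with exact labels."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if size % 16 or size < 32:
        raise ValueError("size must be a multiple of 16 (and at least 32)")
    cfg = class_balance or SyntheticConfig()
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        img, mask = _render_scene(rng, size, cfg)
        samples.append(SegSample(img, mask, f"scene_{seed:05d}_{i:05d}"))
    return samples
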