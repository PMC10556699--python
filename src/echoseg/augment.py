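"""Augmentations: supervised-branch transforms and dual-view construction.

The unsupervised branch needs two randomly cropped, independently
photometrically perturbed views of one unlabeled image whose overlap region
corresponds pixel-for-pixel. The random rotation is therefore applied to the
*source* image once, before the two crops are taken — per-view rotations
would break the exact correspondence the directional contrastive loss
assumes on the overlap. Photometric transforms (blur, brightness/contrast/
gamma jitter) act per view and never move pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import rotate as _rotate

from .data import EchoSample

MAX_CROP_ATTEMPTS = 20


class ValidationError(ValueError):
    pass


@dataclass
class AugmentConfig:
    p_flip: float = 0.5
    p_blur: float = 0.5
    p_jitter: float = 0.5
    p_grayscale: float = 0.5      # no-op for single-channel input
    blur_sigma_range: tuple = (0.1, 1.5)
    brightness: float = 0.2
    contrast: float = 0.2
    gamma: float = 0.2
    crop_size: int = 320
    min_overlap_fraction: float = 0.25
    rotation_degrees: float = 15.0
    photometric: bool = True
    rotation: bool = True


@dataclass
class ViewPair:
    """Two augmented crops of one image plus exact overlap bookkeeping.

    `overlap1` / `overlap2` are half-open rectangles
    (row_start, row_end, col_start, col_end) locating the shared source
    region in each view's own coordinate frame; they always have identical
    height and width.
    """
    view1: np.ndarray
    view2: np.ndarray
    overlap1: tuple
    overlap2: tuple
    photometric_log: dict = field(default_factory=dict)

    def __post_init__(self):
        h1 = self.overlap1[1] - self.overlap1[0]
        w1 = self.overlap1[3] - self.overlap1[2]
        h2 = self.overlap2[1] - self.overlap2[0]
        w2 = self.overlap2[3] - self.overlap2[2]
        if (h1, w1) != (h2, w2):
            raise ValidationError("overlap rectangles must be congruent")
        if h1 <= 0 or w1 <= 0:
            raise ValidationError("overlap rectangle must be non-empty")


def _photometric(image: np.ndarray, rng: np.random.Generator,
                 cfg: AugmentConfig) -> tuple[np.ndarray, dict]:
    """Appearance-only transforms; intensities re-clipped to [-1, 1]."""
    log: dict = {}
    img = image
    if rng.random() < cfg.p_blur:
        sigma = rng.uniform(*cfg.blur_sigma_range)
        img = gaussian_filter(img, sigma)
        log["blur_sigma"] = sigma
    if rng.random() < cfg.p_jitter:
        scale = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
        shift = rng.uniform(-cfg.brightness, cfg.brightness)
        gamma = float(np.exp(rng.uniform(-cfg.gamma, cfg.gamma)))
        # gamma acts on the [0, 1] remap of the [-1, 1] intensity range
        img01 = np.clip((img + 1.0) / 2.0, 0.0, 1.0) ** gamma
        img = np.clip((img01 * 2.0 - 1.0) * scale + shift, -1.0, 1.0)
        log.update(jitter_scale=scale, jitter_shift=shift, jitter_gamma=gamma)
    if rng.random() < cfg.p_grayscale:
        log["grayscale"] = True  # single-channel input: identity
    return np.clip(img, -1.0, 1.0), log


def supervised_augment(sample: EchoSample, seed: int,
                       cfg: AugmentConfig | None = None) -> EchoSample:
    """Augment a labeled sample; geometry is applied to image and mask alike."""
    if sample.mask is None:
        raise ValidationError("supervised augmentation requires a mask")
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(seed)
    img, mask = sample.image, sample.mask
    if rng.random() < cfg.p_flip:
        img, mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
    img, _ = _photometric(img, rng, cfg) if cfg.photometric else (img, {})
    return EchoSample(image=img, mask=mask, patient=sample.patient,
                      view=sample.view, phase=sample.phase)


def _crop_origin(rng, limit: int) -> int:
    return int(rng.integers(0, limit + 1))


def dual_crop(sample: EchoSample, crop_size: int, min_overlap_fraction: float,
              seed: int, cfg: AugmentConfig | None = None) -> ViewPair:
    """Build the positive pair: two overlapping crops of one image.

    Crop origins are drawn by rejection until the intersection area reaches
    ``min_overlap_fraction * crop_size**2``; if rejection exhausts its
    attempt budget the second origin is resampled inside the feasible offset
    box around the first (which guarantees the overlap), so the call never
    fails. One shared rotation is applied to the source before cropping;
    photometric transforms are then drawn independently per view.
    """
    cfg = cfg or AugmentConfig()
    if not 0 < min_overlap_fraction <= 1:
        raise ValidationError("min_overlap_fraction must be in (0, 1]")
    h, w = sample.image.shape
    if crop_size > min(h, w):
        raise ValidationError(
            f"crop_size {crop_size} exceeds image side {min(h, w)}")
    rng = np.random.default_rng(seed)
    src = sample.image
    log: dict = {}
    if cfg.rotation:
        angle = rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees)
        src = _rotate(src, angle, order=1, mode="edge", preserve_range=True)
        log["rotation_degrees"] = float(angle)

    target = min_overlap_fraction * crop_size ** 2
    r1, c1 = _crop_origin(rng, h - crop_size), _crop_origin(rng, w - crop_size)
    r2 = c2 = None
    for _ in range(MAX_CROP_ATTEMPTS):
        rr, cc = _crop_origin(rng, h - crop_size), _crop_origin(rng, w - crop_size)
        ov = max(0, crop_size - abs(rr - r1)) * max(0, crop_size - abs(cc - c1))
        if ov >= target:
            r2, c2 = rr, cc
            break
    if r2 is None:
        # feasible offset box: |d| <= crop*(1 - sqrt(f)) keeps the overlap
        dmax = int(np.floor(crop_size * (1.0 - np.sqrt(min_overlap_fraction))))
        r2 = int(np.clip(r1 + rng.integers(-dmax, dmax + 1), 0, h - crop_size))
        c2 = int(np.clip(c1 + rng.integers(-dmax, dmax + 1), 0, w - crop_size))

    # shared region in source coordinates
    rs, re = max(r1, r2), min(r1, r2) + crop_size
    cs, ce = max(c1, c2), min(c1, c2) + crop_size
    overlap1 = (rs - r1, re - r1, cs - c1, ce - c1)
    overlap2 = (rs - r2, re - r2, cs - c2, ce - c2)

    view1 = src[r1:r1 + crop_size, c1:c1 + crop_size].copy()
    view2 = src[r2:r2 + crop_size, c2:c2 + crop_size].copy()
    if cfg.photometric:
        view1, log1 = _photometric(view1, rng, cfg)
        view2, log2 = _photometric(view2, rng, cfg)
        log["view1"], log["view2"] = log1, log2
    return ViewPair(view1=view1, view2=view2,
                    overlap1=overlap1, overlap2=overlap2, photometric_log=log)


def overlap_fraction(pair: ViewPair) -> float:
    h = pair.overlap1[1] - pair.overlap1[0]
    w = pair.overlap1[3] - pair.overlap1[2]
    return h * w / float(pair.view1.size)


def map_overlap_to_grid(pair: ViewPair, grid_size: int) -> tuple:
    """Rescale the overlap rectangles from crop to loss-grid coordinates.

    The crop must be an integer multiple of the grid (stride = crop/grid).
    Only grid cells whose pixel footprint lies fully inside the overlap are
    kept (starts ceiled, ends floored), so every retained cell pools overlap
    pixels exclusively; the two rectangles are then trimmed to their common
    height and width so they stay congruent. Overlaps too small to cover a
    full cell come back as zero-size rectangles for the caller to skip.
    """
    crop = pair.view1.shape[0]
    if crop % grid_size:
        raise ValidationError(
            f"grid_size {grid_size} does not divide crop size {crop}")
    stride = crop // grid_size

    def to_grid(rect):
        rs, re, cs, ce = rect
        return (-(-rs // stride), re // stride,
                -(-cs // stride), ce // stride)

    g1, g2 = to_grid(pair.overlap1), to_grid(pair.overlap2)
    h = min(g1[1] - g1[0], g2[1] - g2[0])
    w = min(g1[3] - g1[2], g2[3] - g2[2])
    if h <= 0 or w <= 0:
        return (0, 0, 0, 0), (0, 0, 0, 0)
    r1 = (g1[0], g1[0] + h, g1[2], g1[2] + w)
    r2 = (g2[0], g2[0] + h, g2[2], g2[2] + w)
    return r1, r2
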