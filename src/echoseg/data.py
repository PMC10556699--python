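"""Data handling: CAMUS-style readers, preprocessing, phantoms and splits.

Images are 2D grayscale echocardiograms with optional integer label masks
using the CAMUS encoding: 0 background, 1 left ventricle (LV), 2 myocardium,
3 left atrium (LA). Readers accept MetaImage (.mhd/.raw), NIfTI
(.nii/.nii.gz) and 8/16-bit PNG. Preprocessing resizes to a square target
(bilinear for images, nearest-neighbour for masks, no anti-aliasing so label
sets are preserved) and min–max normalises intensities to [-1, 1].

The phantom generator draws a sector-shaped synthetic echocardiogram — dark
elliptical LV cavity, bright myocardial shell, dark LA below the LV —
corrupted by controllable contrast reduction, Gaussian boundary blur,
multiplicative Rayleigh speckle (a standard ultrasound speckle
approximation) and, stochastically, apical truncation that removes the top
of the sector to emulate incomplete cardiac structures. The returned mask
always encodes the uncorrupted geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

VALID_LABELS = frozenset({0, 1, 2, 3})
CLASS_NAMES = ("background", "LV", "myocardium", "LA")


class ValidationError(ValueError):
    pass


@dataclass
class EchoSample:
    """One 2D grayscale image, an optional label mask, and provenance."""
    image: np.ndarray
    mask: np.ndarray | None = None
    patient: str = ""
    view: str = ""        # "2CH" or "4CH"
    phase: str = ""       # "ED" or "ES"

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValidationError(
                f"image must be 2D, got shape {self.image.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape:
                raise ValidationError(
                    f"mask shape {self.mask.shape} != image {self.image.shape}")
            bad = {int(v) for v in np.unique(self.mask)} - VALID_LABELS
            if bad:
                raise ValidationError(
                    f"mask contains invalid labels {sorted(bad)}; "
                    f"expected subset of {sorted(VALID_LABELS)}")
            self.mask = self.mask.astype(np.int64)


@dataclass
class DatasetSplit:
    labeled: list
    unlabeled: list
    test: list
    labeled_ratio: float

    def __post_init__(self):
        lab, unlab, test = set(self.labeled), set(self.unlabeled), set(self.test)
        if lab & unlab or (lab | unlab) & test:
            raise ValidationError("split groups must be disjoint")


@dataclass
class PhantomParams:
    """Geometry and corruption parameters of one synthetic echocardiogram."""
    image_size: int = 64
    lv_center: tuple = (0.42, 0.50)     # fractions of image size (row, col)
    lv_axes: tuple = (0.20, 0.13)       # ellipse semi-axes, fractions
    myo_thickness: float = 0.05         # shell thickness, fraction
    la_center: tuple = (0.74, 0.50)
    la_axes: tuple = (0.10, 0.11)
    contrast: float = 1.0               # in (0, 1]; 1 = nominal contrast
    speckle_scale: float = 0.0          # multiplicative speckle strength
    boundary_blur_sigma: float = 0.0    # pixels
    truncation_prob: float = 0.0        # chance of apical clipping
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValidationError("image_size must be >= 16")
        if not 0 < self.contrast <= 1:
            raise ValidationError("contrast must be in (0, 1]")
        if self.speckle_scale < 0 or self.boundary_blur_sigma < 0:
            raise ValidationError("noise parameters must be non-negative")
        if not 0 <= self.truncation_prob <= 1:
            raise ValidationError("truncation_prob must be in [0, 1]")
        if min(*self.lv_axes, *self.la_axes, self.myo_thickness) <= 0:
            raise ValidationError("geometric parameters must be positive")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------
_SITK_SUFFIXES = (".mhd", ".mha", ".nii", ".nii.gz")


def _read_array(path: Path) -> np.ndarray:
    name = path.name.lower()
    if not path.exists():
        raise IOError(f"cannot read image: {path} does not exist")
    if name.endswith(_SITK_SUFFIXES):
        import SimpleITK as sitk
        arr = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    elif name.endswith(".png"):
        from PIL import Image
        with Image.open(path) as im:
            # paletted PNGs (label masks) are read as raw palette indices
            arr = np.asarray(im, dtype=np.int64 if im.mode == "P" else None)
        if arr.ndim == 3:
            if np.all(arr[..., :1] == arr[..., :3]):   # replicated grayscale
                arr = arr[..., 0]
            else:
                raise ValidationError(f"{path}: expected a grayscale PNG")
    else:
        raise ValidationError(f"unsupported image format: {path}")
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2D image, got {arr.shape}")
    return arr


def read_sample(image_path, mask_path=None, patient: str = "",
                view: str = "", phase: str = "") -> EchoSample:
    """Load a raw-intensity sample (not yet preprocessed); mask optional."""
    image = _read_array(Path(image_path)).astype(np.float64)
    mask = None
    if mask_path is not None and str(mask_path) != "":
        mask = np.rint(_read_array(Path(mask_path))).astype(np.int64)
    return EchoSample(image=image, mask=mask, patient=patient,
                      view=view, phase=phase)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a label mask as a paletted PNG (one palette entry per class)."""
    from PIL import Image
    img = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    palette = [0, 0, 0, 220, 40, 40, 60, 200, 60, 60, 90, 220]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)


def write_mask_nifti(mask: np.ndarray, path) -> None:
    import SimpleITK as sitk
    sitk.WriteImage(sitk.GetImageFromArray(
        np.asarray(mask, dtype=np.uint8)), str(path))


def write_image_png(image: np.ndarray, path) -> None:
    """Write a float image as 8-bit grayscale PNG (min–max scaled)."""
    import imageio.v3 as iio
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    iio.imwrite(path, (scaled * 255).round().astype(np.uint8))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------
def preprocess(sample: EchoSample, target_size: int = 512) -> EchoSample:
    """Resize to target_size^2 and min–max normalise intensities to [-1, 1].

    Images are resized bilinearly, masks with nearest-neighbour interpolation
    (never inventing labels); a constant image maps to all zeros.
    """
    if target_size < 16:
        raise ValidationError("target_size must be >= 16")
    img = resize(sample.image, (target_size, target_size), order=1,
                 anti_aliasing=False, preserve_range=True)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = 2.0 * (img - lo) / (hi - lo) - 1.0
    else:
        img = np.zeros_like(img)
    mask = None
    if sample.mask is not None:
        mask = resize(sample.mask.astype(np.float64),
                      (target_size, target_size), order=0,
                      anti_aliasing=False, preserve_range=True)
        mask = np.rint(mask).astype(np.int64)
    return EchoSample(image=img, mask=mask, patient=sample.patient,
                      view=sample.view, phase=sample.phase)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------
_INTENSITY = {"outside": 0.02, "tissue": 0.40, "lv": 0.10,
              "myo": 0.70, "la": 0.13}
_SECTOR_APEX_ROW = 0.02
_SECTOR_HALF_ANGLE = np.deg2rad(45.0)
_SECTOR_RADIUS = 0.93


def _sector_mask(size: int) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    ar, ac = _SECTOR_APEX_ROW * size, size / 2.0
    dr, dc = rr - ar, cc - ac
    dist = np.hypot(dr, dc)
    angle = np.arctan2(np.abs(dc), np.maximum(dr, 1e-9))
    return (dr >= 0) & (dist <= _SECTOR_RADIUS * size) \
        & (angle <= _SECTOR_HALF_ANGLE)


def _ellipse_mask(size: int, center: tuple, axes: tuple) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    r0, c0 = center[0] * size, center[1] * size
    ar, ac = axes[0] * size, axes[1] * size
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def phantom_masks(params: PhantomParams) -> dict:
    """Boolean masks of the generating shapes, before priority resolution."""
    s = params.image_size
    lv = _ellipse_mask(s, params.lv_center, params.lv_axes)
    outer = _ellipse_mask(s, params.lv_center,
                          (params.lv_axes[0] + params.myo_thickness,
                           params.lv_axes[1] + params.myo_thickness))
    la = _ellipse_mask(s, params.la_center, params.la_axes)
    return {"lv": lv, "outer": outer, "la": la,
            "sector": _sector_mask(s)}


def generate_phantom(params: PhantomParams) -> EchoSample:
    """Deterministically synthesise one sector phantom and its clean mask."""
    s = params.image_size
    shapes = phantom_masks(params)
    structures = shapes["outer"] | shapes["la"]
    if np.any(structures & ~shapes["sector"]):
        raise ValidationError(
            "phantom geometry does not fit inside the sector field of view")
    # label priority: LV > myocardium (shell) > LA
    mask = np.zeros((s, s), dtype=np.int64)
    mask[shapes["la"]] = 3
    mask[shapes["outer"]] = 2
    mask[shapes["lv"]] = 1

    img = np.full((s, s), _INTENSITY["outside"])
    img[shapes["sector"]] = _INTENSITY["tissue"]
    img[mask == 2] = _INTENSITY["myo"]
    img[mask == 1] = _INTENSITY["lv"]
    img[mask == 3] = _INTENSITY["la"]

    rng = np.random.default_rng(params.seed)
    if params.contrast < 1.0:
        mid = _INTENSITY["tissue"]
        inside = shapes["sector"]
        img[inside] = mid + params.contrast * (img[inside] - mid)
    if params.boundary_blur_sigma > 0:
        img = gaussian_filter(img, params.boundary_blur_sigma)
    if params.speckle_scale > 0:
        ray = rng.rayleigh(scale=1.0, size=(s, s))
        ray /= np.sqrt(np.pi / 2.0)  # unit mean
        img = img * (1.0 + params.speckle_scale * (ray - 1.0))
    if params.truncation_prob > 0 and rng.random() < params.truncation_prob:
        depth = int(rng.uniform(0.08, 0.18) * s)
        cut = int(_SECTOR_APEX_ROW * s) + depth
        img[:cut, :] = _INTENSITY["outside"]
    img = np.clip(img, 0.0, 1.0)
    return EchoSample(image=img, mask=mask)


def sample_phantom_params(rng: np.random.Generator,
                          image_size: int = 64) -> PhantomParams:
    """Draw one realistic phantom configuration (geometry + corruption).

    Geometry is jittered around the nominal heart so that a handful of
    labeled phantoms does not cover the population; contrast, blur, speckle
    and apical truncation reproduce the characteristic low contrast, fuzzy
    boundaries and incomplete structures of clinical echocardiograms.
    """
    jit = lambda v, f=0.18: v * rng.uniform(1 - f, 1 + f)
    return PhantomParams(
        image_size=image_size,
        lv_center=(0.42 + rng.uniform(-0.025, 0.025),
                   0.50 + rng.uniform(-0.035, 0.035)),
        lv_axes=(jit(0.20), jit(0.13)),
        myo_thickness=jit(0.05, 0.25),
        la_center=(0.74 + rng.uniform(-0.02, 0.02),
                   0.50 + rng.uniform(-0.035, 0.035)),
        la_axes=(jit(0.10), jit(0.11)),
        contrast=rng.uniform(0.55, 0.95),
        speckle_scale=rng.uniform(0.2, 0.45),
        boundary_blur_sigma=rng.uniform(0.5, 1.5) * image_size / 64.0,
        truncation_prob=0.25,
        seed=int(rng.integers(0, 2 ** 31)),
    )


def generate_phantom_dataset(n: int, image_size: int = 64,
                             seed: int = 0) -> list:
    """Generate `n` preprocessed phantom samples, one synthetic patient each."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        params = sample_phantom_params(rng, image_size)
        sample = generate_phantom(params)
        sample = preprocess(sample, target_size=image_size)
        sample.patient = f"phantom{i:04d}"
        sample.view = "2CH" if i % 2 == 0 else "4CH"
        sample.phase = "ED" if (i // 2) % 2 == 0 else "ES"
        samples.append(sample)
    return samples


# ---------------------------------------------------------------------------
# splits and manifests
# ---------------------------------------------------------------------------
def make_split(sample_ids, labeled_ratio: float, test_fraction: float = 0.0,
               seed: int = 0) -> DatasetSplit:
    """Patient-level labeled/unlabeled/test split, reproducible by seed.

    The labeled count is ``round(n_train * labeled_ratio)`` with banker's
    rounding (ties to even), floored at one labeled patient.
    """
    ids = list(sample_ids)
    if len(ids) != len(set(ids)):
        raise ValidationError("sample ids must be unique")
    if len(ids) < 2:
        raise ValidationError("need at least 2 patients to split")
    if not 0 < labeled_ratio <= 1:
        raise ValidationError("labeled_ratio must be in (0, 1]")
    if not 0 <= test_fraction < 1:
        raise ValidationError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_test = int(round(test_fraction * len(order)))
    test, train = order[:n_test], order[n_test:]
    if not train:
        raise ValidationError("test_fraction leaves no training patients")
    n_labeled = int(round(len(train) * labeled_ratio))
    n_labeled = min(max(n_labeled, 1), len(train))
    return DatasetSplit(labeled=train[:n_labeled],
                        unlabeled=train[n_labeled:],
                        test=test, labeled_ratio=labeled_ratio)


MANIFEST_COLUMNS = ["patient_id", "view", "phase", "image_path", "mask_path"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_manifest_samples(path, view: str | None = None) -> list:
    """Read and return the raw samples listed in a manifest CSV."""
    df = read_manifest(path)
    if view:
        df = df[df["view"] == view]
    root = Path(path).parent
    samples = []
    for row in df.itertuples():
        image_path = root / row.image_path if not Path(
            row.image_path).is_absolute() else Path(row.image_path)
        mask_path = None
        if row.mask_path:
            mask_path = root / row.mask_path if not Path(
                row.mask_path).is_absolute() else Path(row.mask_path)
        samples.append(read_sample(image_path, mask_path, patient=row.patient_id,
                                   view=row.view, phase=row.phase))
    return samples
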