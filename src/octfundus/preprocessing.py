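"""Image conditioning, patch extraction, augmentation and prediction stitching.

The standard conditioning pipeline used before patch-based training is:
grayscale collapse → z-score normalization → rescale to [0, 1] → CLAHE →
gamma correction.  No edge cropping is performed.  Augmentation comes in
named presets mirroring the recipes of the published vessel-segmentation
networks:

* ``none`` — identity;
* ``iternet`` — photometric jitter (brightness/contrast) on the image plus
  geometric rotation (±20°), shear, reflection, shift and zoom in
  [0.8, 1.0] applied identically to image and mask;
* ``saunet`` — brightness/contrast/sharpness jitter, additive Gaussian
  noise, random rotation and random crop-resize;
* ``frunet`` — right-angle rotations (0/90/180/270°) and random flips
  only, which are exact on binary masks.

Masks are warped with nearest-neighbour interpolation and re-binarized, so
they stay strictly binary under every preset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure
from skimage.transform import AffineTransform, warp

from .core import FundusImage, ProbabilityMap, ValidationError, VesselMask

AUGMENT_PRESETS = ("none", "iternet", "saunet", "frunet")


@dataclass
class AugmentConfig:
    """Named augmentation recipe with optional parameter overrides."""

    preset: str = "none"
    rotation_deg: float = 20.0
    zoom_range: tuple[float, float] = (0.8, 1.0)
    shear_deg: float = 10.0
    shift_frac: float = 0.1
    brightness: float = 0.15
    contrast: float = 0.25
    sharpness: float = 1.0
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in AUGMENT_PRESETS:
            raise ValidationError(f"unknown preset {self.preset!r}; expected {AUGMENT_PRESETS}")
        if not (0.0 < self.zoom_range[0] <= self.zoom_range[1]):
            raise ValidationError("zoom_range must satisfy 0 < lo <= hi")
        if abs(self.rotation_deg) > 180:
            raise ValidationError("rotation bound must be within ±180°")


@dataclass
class PatchSet:
    """Aligned (image, mask) patch pairs with their source coordinates."""

    images: np.ndarray  # (N, size, size) float
    masks: np.ndarray   # (N, size, size) uint8
    coords: np.ndarray  # (N, 2) top-left (row, col)
    size: int
    seed: int

    def __len__(self) -> int:
        return len(self.images)


def preprocess_standard(image: FundusImage, clahe_clip: float = 0.02,
                        clahe_tiles: int = 8, gamma: float = 1.2) -> FundusImage:
    """Grayscale → z-score → rescale [0, 1] → CLAHE → gamma correction.

    A constant (zero-variance) image skips the z-score stage with a
    warning and passes through the rest of the pipeline unchanged in
    value.  ``clahe_clip`` uses the normalized [0, 1] clip-limit
    convention of adaptive histogram equalization; ``clahe_tiles`` is the
    number of contextual tiles per image side.  ``gamma=1`` together with
    ``clahe_clip=None`` reduces the pipeline to normalization alone.
    """
    px = image.pixels
    if px.ndim == 3:  # grayscale collapse: channel mean
        px = px.mean(axis=2)
    if px.max() > px.min():
        px = (px - px.mean()) / px.std()
    else:
        warnings.warn("zero-variance image; skipping z-score stage", stacklevel=2)
    lo, hi = px.min(), px.max()
    px = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px) + 0.5
    if clahe_clip is not None:
        kernel = (max(px.shape[0] // clahe_tiles, 1), max(px.shape[1] // clahe_tiles, 1))
        if hi > lo:  # CLAHE on a constant image is undefined; skip
            px = exposure.equalize_adapthist(px, kernel_size=kernel, clip_limit=clahe_clip)
    if gamma != 1.0:
        px = exposure.adjust_gamma(px, gamma=gamma)
    return FundusImage(np.clip(px, 0.0, 1.0), image.pixel_pitch_mm, image.provenance)


def zscore(px: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance normalization (the z-score stage alone)."""
    if px.max() == px.min():
        warnings.warn("zero-variance image; skipping z-score stage", stacklevel=2)
        return px.copy()
    return (px - px.mean()) / px.std()


def extract_patches(image: FundusImage, mask: VesselMask, n: int, size: int,
                    seed: int = 0) -> PatchSet:
    """Sample ``n`` aligned square patches at uniform random in-bounds positions."""
    img = image.pixels
    if img.shape[:2] != mask.shape:
        raise ValidationError(f"image shape {img.shape[:2]} != mask shape {mask.shape}")
    H, W = img.shape[:2]
    if size <= 0 or size > H or size > W:
        raise ValidationError(f"patch size {size} not in (0, min(image dims)={min(H, W)}]")
    if n < 0:
        raise ValidationError("patch count must be >= 0")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, H - size + 1, n)
    cols = rng.integers(0, W - size + 1, n)
    images = np.empty((n, size, size), dtype=np.float32)
    masks = np.empty((n, size, size), dtype=np.uint8)
    for i, (r, c) in enumerate(zip(rows, cols)):
        images[i] = img[r:r + size, c:c + size]
        masks[i] = mask.pixels[r:r + size, c:c + size]
    return PatchSet(images, masks, np.stack([rows, cols], axis=1), size, seed)


def _geometric(img: np.ndarray, msk: np.ndarray, tf: AffineTransform) -> tuple[np.ndarray, np.ndarray]:
    """Apply one affine transform to both patches; nearest-neighbour mask."""
    out_i = warp(img, tf.inverse, order=1, mode="reflect", preserve_range=True)
    out_m = warp(msk.astype(float), tf.inverse, order=0, mode="reflect", preserve_range=True)
    return out_i, (out_m > 0.5).astype(np.uint8)


def _centered(tf: AffineTransform, shape: tuple[int, int]) -> AffineTransform:
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    shift = AffineTransform(translation=(-cx, -cy))
    unshift = AffineTransform(translation=(cx, cy))
    return shift + tf + unshift


def augment(image_patch: np.ndarray, mask_patch: np.ndarray,
            config: AugmentConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random draw of the configured augmentation recipe.

    Geometric transforms are shared by image and mask; photometric ones
    touch only the image.  The ``frunet`` preset is exact on masks.
    """
    img = np.asarray(image_patch, dtype=np.float64)
    msk = np.asarray(mask_patch).astype(np.uint8)
    if config.preset == "none":
        return img.copy(), msk.copy()

    if config.preset == "frunet":
        k = int(rng.integers(4))
        img, msk = np.rot90(img, k), np.rot90(msk, k)
        if rng.integers(2):
            img, msk = np.flipud(img), np.flipud(msk)
        if rng.integers(2):
            img, msk = np.fliplr(img), np.fliplr(msk)
        return np.ascontiguousarray(img), np.ascontiguousarray(msk)

    if config.preset == "iternet":
        # photometric: brightness / contrast jitter
        img = img + rng.uniform(-config.brightness, config.brightness)
        img = (img - img.mean()) * rng.uniform(1 - config.contrast, 1 + config.contrast) + img.mean()
        # geometric: rotation, shear, reflection, shift, zoom
        ang = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
        shear = np.deg2rad(rng.uniform(-config.shear_deg, config.shear_deg))
        zoom = rng.uniform(*config.zoom_range)
        shift = rng.uniform(-config.shift_frac, config.shift_frac, 2) * np.array(img.shape)
        tf = _centered(
            AffineTransform(rotation=ang, shear=shear, scale=(zoom, zoom),
                            translation=(shift[1], shift[0])),
            img.shape,
        )
        if rng.integers(2):
            img, msk = np.fliplr(img).copy(), np.fliplr(msk).copy()
        img, msk = _geometric(img, msk, tf)
        return np.clip(img, 0.0, 1.0), msk

    # saunet: photometric jitter + noise + rotation + crop-resize
    img = img + rng.uniform(-config.brightness, config.brightness)
    img = (img - img.mean()) * rng.uniform(1 - config.contrast, 1 + config.contrast) + img.mean()
    if config.sharpness > 0:
        blurred = ndimage.gaussian_filter(img, 1.0)
        img = img + rng.uniform(0, config.sharpness) * (img - blurred)
    img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    ang = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
    tf = _centered(AffineTransform(rotation=ang), img.shape)
    img, msk = _geometric(img, msk, tf)
    crop = rng.uniform(0.85, 1.0)
    ch, cw = max(4, int(img.shape[0] * crop)), max(4, int(img.shape[1] * crop))
    r0 = int(rng.integers(0, img.shape[0] - ch + 1))
    c0 = int(rng.integers(0, img.shape[1] - cw + 1))
    from skimage.transform import resize
    img = resize(img[r0:r0 + ch, c0:c0 + cw], img.shape, order=1,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    msk_c = resize(msk[r0:r0 + ch, c0:c0 + cw].astype(float), msk.shape, order=0,
                   mode="edge", anti_aliasing=False, preserve_range=True)
    return np.clip(img, 0.0, 1.0), (msk_c > 0.5).astype(np.uint8)


def stitch_predictions(patch_probs: list[np.ndarray], coords: np.ndarray,
                       image_shape: tuple[int, int]) -> ProbabilityMap:
    """Average overlapping patch predictions back into a full-image map.

    Every pixel of ``image_shape`` must be covered by at least one patch.
    """
    acc = np.zeros(image_shape, dtype=np.float64)
    cnt = np.zeros(image_shape, dtype=np.int64)
    for prob, (r, c) in zip(patch_probs, np.asarray(coords)):
        p = np.asarray(prob)
        h, w = p.shape
        if r < 0 or c < 0 or r + h > image_shape[0] or c + w > image_shape[1]:
            raise ValidationError(f"patch at ({r}, {c}) of shape {p.shape} out of bounds")
        acc[r:r + h, c:c + w] += p
        cnt[r:r + h, c:c + w] += 1
    uncovered = int((cnt == 0).sum())
    if uncovered:
        raise ValidationError(f"{uncovered} pixels not covered by any patch")
    return ProbabilityMap(np.clip(acc / cnt, 0.0, 1.0))


def replicate_channels(patch: np.ndarray, channels: int = 3) -> np.ndarray:
    """Replicate a single-channel patch to ``channels`` identical channels."""
    return np.repeat(patch[..., None], channels, axis=-1)
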