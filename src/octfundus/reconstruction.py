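"""Layer-bounded axial projections and weighted fundus reconstructions.

An en-face projection between two retina layer borders averages, for each
A-scan (x, y), the voxels on the inclusive axial span between the borders:

    P(x, y) = (1 / n(x, y)) * sum_{z = top(x,y)}^{bottom(x,y)} I(x, y, z)

with ``n`` the voxel count of the span (a zero-thickness span yields the
single border voxel).  The count denominator makes the projection
independent of which way the axial index runs and reproduces constants
exactly.

Three standard projections are exposed: the ganglion-cell band
(NFL/GCL → GCL/IPL, vessels bright), the combined GCL+IPL band
(NFL/GCL → IPL/INL) and the hyper-reflective outer band
(IS/OS → RPE/CHR, vessel shadows dark).  Reconstructions combine them:

* P1 — the outer-band projection alone (the classical shadowgraph source);
* P2 — ``w1 * P_OS+RPE + w2 * f(P_GCL)`` with defaults w1 = 1.7, w2 = 0.8;
* P3 — ``w1 * P_OS+RPE + w2 * f(P_GCL+IPL)`` with defaults w1 = 2, w2 = 1.2.

With ``invert_inner`` enabled (the default) each component projection is
min–max normalized to [0, 1] and the inner term is inverted (1 − p), so
both terms render vessels dark and their contrast adds rather than
cancels.  With the flag off, ``f`` is the identity and the raw weighted
sum is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .core import FundusImage, LayerSurfaces, OCTVolume, ValidationError

#: Default weights per reconstruction variant: (w1 outer, w2 inner).
DEFAULT_WEIGHTS: dict[str, tuple[float, float]] = {
    "P1": (1.0, 0.0),
    "P2": (1.7, 0.8),
    "P3": (2.0, 1.2),
}


@dataclass
class ReconstructionConfig:
    """Which reconstruction to compute and with what weights."""

    variant: str = "P3"
    w1: float | None = None
    w2: float | None = None
    invert_inner: bool = True
    resample: bool = False
    interpolation_order: int = 3

    def __post_init__(self) -> None:
        if self.variant not in DEFAULT_WEIGHTS:
            raise ValidationError(
                f"unknown variant {self.variant!r}; expected one of {list(DEFAULT_WEIGHTS)}"
            )
        dw1, dw2 = DEFAULT_WEIGHTS[self.variant]
        if self.w1 is None:
            self.w1 = dw1
        if self.w2 is None:
            self.w2 = dw2
        if not (np.isfinite(self.w1) and np.isfinite(self.w2)):
            raise ValidationError("weights must be finite")


def _en_face_pitch(volume: OCTVolume) -> tuple[float, float]:
    (wx, wy, _), (X, Y, _) = volume.extent_mm, volume.dims
    return (wx / X, wy / Y)


def project_layer(volume: OCTVolume, surfaces: LayerSurfaces,
                  top_border: str, bottom_border: str,
                  provenance: str = "external") -> FundusImage:
    """Mean intensity over the inclusive axial span between two borders."""
    surfaces.validate_against(volume)
    top = surfaces[top_border]
    bot = surfaces[bottom_border]
    lo = np.minimum(top, bot)
    hi = np.maximum(top, bot)
    # cumulative sum along z: inclusive span sum = cs[hi + 1] - cs[lo]
    cs = np.zeros(volume.dims[:2] + (volume.dims[2] + 1,), dtype=np.float64)
    np.cumsum(volume.intensities, axis=2, dtype=np.float64, out=cs[:, :, 1:])
    X, Y, _ = volume.dims
    xs, ys = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
    span_sum = cs[xs, ys, hi + 1] - cs[xs, ys, lo]
    count = (hi - lo + 1).astype(np.float64)
    return FundusImage(span_sum / count, _en_face_pitch(volume), provenance)


def projection_gcl(volume: OCTVolume, surfaces: LayerSurfaces) -> FundusImage:
    """Ganglion-cell band projection (NFL/GCL → GCL/IPL); vessels bright."""
    return project_layer(volume, surfaces, "NFL/GCL", "GCL/IPL", provenance="GCL")


def projection_gcl_ipl(volume: OCTVolume, surfaces: LayerSurfaces) -> FundusImage:
    """Combined GCL+IPL band projection (NFL/GCL → IPL/INL)."""
    return project_layer(volume, surfaces, "NFL/GCL", "IPL/INL", provenance="GCL+IPL")


def projection_os_rpe(volume: OCTVolume, surfaces: LayerSurfaces) -> FundusImage:
    """Hyper-reflective outer band projection (IS/OS → RPE/CHR); shadows dark."""
    return project_layer(volume, surfaces, "IS/OS", "RPE/CHR", provenance="OS+RPE")


def _minmax(p: np.ndarray) -> np.ndarray:
    lo, hi = p.min(), p.max()
    if hi > lo:
        return (p - lo) / (hi - lo)
    return np.zeros_like(p)


def reconstruct(volume: OCTVolume, surfaces: LayerSurfaces,
                config: ReconstructionConfig | None = None) -> FundusImage:
    """Compute the P1/P2/P3 fundus reconstruction for a volume."""
    config = config or ReconstructionConfig()
    outer = projection_os_rpe(volume, surfaces)
    if config.variant == "P1":
        out = FundusImage(outer.pixels, outer.pixel_pitch_mm, "P1")
    else:
        inner = (projection_gcl if config.variant == "P2" else projection_gcl_ipl)(
            volume, surfaces
        )
        if config.invert_inner:
            px = config.w1 * _minmax(outer.pixels) + config.w2 * (1.0 - _minmax(inner.pixels))
        else:
            px = config.w1 * outer.pixels + config.w2 * inner.pixels
        out = FundusImage(px, outer.pixel_pitch_mm, config.variant)
    if config.resample:
        out = resample_isotropic(out, order=config.interpolation_order)
    return out


def resample_isotropic(image: FundusImage,
                       target_pitch_mm: float | str = "fast-axis",
                       order: int = 3) -> FundusImage:
    """Resample an anisotropic en-face image onto an isotropic pixel grid.

    The default target pitch is the fast-axis (finer) pitch, so the slow
    axis is enlarged — for the study geometry a 385 × 141 image over
    7 × 7 mm becomes 385 × 385.  Bicubic interpolation by default.
    """
    px, py = image.pixel_pitch_mm
    if target_pitch_mm == "fast-axis":
        target = min(px, py)
    else:
        target = float(target_pitch_mm)
        if target <= 0:
            raise ValidationError("target pitch must be positive")
    extent = (image.shape[0] * px, image.shape[1] * py)
    new_shape = (int(round(extent[0] / target)), int(round(extent[1] / target)))
    out = resize(
        image.pixels, new_shape, order=order, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return FundusImage(out, (target, target), image.provenance)


def resample_mask_isotropic(mask: np.ndarray, pitch_mm: tuple[float, float],
                            target_pitch_mm: float | str = "fast-axis") -> np.ndarray:
    """Nearest-neighbour isotropic resampling for binary masks."""
    px, py = pitch_mm
    target = min(px, py) if target_pitch_mm == "fast-axis" else float(target_pitch_mm)
    new_shape = (int(round(mask.shape[0] * px / target)),
                 int(round(mask.shape[1] * py / target)))
    out = resize(mask.astype(float), new_shape, order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)
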