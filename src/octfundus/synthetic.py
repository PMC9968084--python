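"""Synthetic OCT macula phantoms with known layer surfaces and vessel truth.

The phantom emulates the salient physics of a macular OCT scan used for
en-face fundus reconstruction:

* nine smooth, anatomically ordered layer borders with a foveal pit where
  the inner retinal bands thin to near zero;
* superficial vessels that appear *bright* inside the ganglion-cell band
  (and, away from the fovea, also in the inner plexiform band, mirroring
  how vessels dive deeper with eccentricity);
* vessel *shadows*: every voxel beneath a vessel is attenuated, so the
  hyper-reflective outer bands (OS+RPE) render vessels dark;
* multiplicative unit-mean gamma speckle.

Vessels are drawn as tortuous random-walk tubes in the en-face plane,
entering from the image borders and steering around a foveal avascular
disc; the en-face ground-truth mask is exactly the rasterized,
width-dilated centerline set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import (
    BORDER_NAMES,
    LayerSurfaces,
    OCTVolume,
    ValidationError,
    VesselMask,
)

# Mean reflectivity per region: vitreous, the eight tissue bands
# (NFL..OS+RPE), choroid.  OS+RPE is hyper-reflective; nuclear layers dark.
DEFAULT_REFLECTIVITY: tuple[float, ...] = (
    0.04,  # vitreous
    0.55,  # NFL
    0.35,  # GCL
    0.40,  # IPL
    0.25,  # INL
    0.45,  # OPL
    0.18,  # ONL
    0.35,  # IS
    0.80,  # OS+RPE
    0.30,  # choroid
)

# Band thicknesses as fractions of the axial extent (NFL..OS+RPE).
DEFAULT_THICKNESS_FRAC: tuple[float, ...] = (
    0.040, 0.055, 0.050, 0.040, 0.030, 0.085, 0.030, 0.060,
)

_INNER_BANDS = slice(0, 5)  # NFL..OPL collapse at the foveal pit


@dataclass
class PhantomConfig:
    """Parameters of the synthetic macula scan.

    Defaults mirror the study scan geometry: 141 B-scans of 385 px over a
    7×7 mm area, 640 axial px over 2 mm.  ``small()`` gives a reduced
    geometry for fast tests.
    """

    dims: tuple[int, int, int] = (385, 141, 640)
    extent_mm: tuple[float, float, float] = (7.0, 7.0, 2.0)
    reflectivity: tuple[float, ...] = DEFAULT_REFLECTIVITY
    thickness_frac: tuple[float, ...] = DEFAULT_THICKNESS_FRAC
    rpe_chr_depth_frac: float = 0.72
    undulation_px: float = 3.0
    # inner bands sum to 0.215 * Z; the pit deflection nearly matches it so
    # the inner retina collapses to ~0 thickness at the fovea center
    pit_depth_px: int = 132
    pit_radius_px: int = 45
    vessel_count: int = 14
    vessel_width_range: tuple[int, int] = (1, 5)
    tortuosity: float = 0.18
    branch_prob: float = 0.35
    fovea_avoid_radius_px: int = 18
    ipl_penetration_radius_px: int = 60
    vessel_gain: float = 1.6
    shadow_attenuation: float = 0.45
    speckle_shape: float | None = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.shadow_attenuation < 1.0):
            raise ValidationError("shadow_attenuation must lie in (0, 1)")
        if self.vessel_width_range[0] < 1:
            raise ValidationError("vessel widths must be >= 1 px")
        if any(not (0.0 <= r <= 1.0) for r in self.reflectivity):
            raise ValidationError("reflectivities must lie in [0, 1]")
        if len(self.reflectivity) != 10:
            raise ValidationError("reflectivity needs 10 values (vitreous, 8 bands, choroid)")
        if len(self.thickness_frac) != 8:
            raise ValidationError("thickness_frac needs 8 band values")
        total = self.rpe_chr_depth_frac
        if sum(self.thickness_frac) >= total:
            raise ValidationError(
                "configured band thicknesses exceed the axial space above RPE/CHR"
            )

    @classmethod
    def study(cls, **overrides) -> "PhantomConfig":
        """The full-size scan geometry (141 × 385 × 640 px, 7 × 7 × 2 mm)."""
        return cls(**overrides)

    @classmethod
    def small(cls, **overrides) -> "PhantomConfig":
        """A reduced 96 × 48 × 160 px phantom for fast desk-scale runs."""
        base = dict(
            dims=(96, 48, 160),
            undulation_px=1.5,
            pit_depth_px=33,
            pit_radius_px=12,
            vessel_count=8,
            vessel_width_range=(1, 4),
            fovea_avoid_radius_px=5,
            ipl_penetration_radius_px=16,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class Phantom:
    """A rendered phantom: volume, true layer surfaces and vessel mask."""

    volume: OCTVolume
    surfaces: LayerSurfaces
    vessel_mask: VesselMask
    config: PhantomConfig


def _smooth_field(shape: tuple[int, int], amplitude: float, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Low-frequency random undulation with roughly the given amplitude."""
    noise = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    peak = np.abs(field).max()
    if peak > 0:
        field = field / peak * amplitude
    return field


def _radius_grid(X: int, Y: int, aspect: float = 1.0) -> np.ndarray:
    """En-face distance (in fast-axis px) from the image center.

    ``aspect`` scales the slow axis so the distance is roughly physical
    when the two axes have different pitch.
    """
    cx, cy = (X - 1) / 2.0, (Y - 1) / 2.0
    xs = np.arange(X)[:, None] - cx
    ys = (np.arange(Y)[None, :] - cy) * aspect
    return np.hypot(xs, ys)


def _aspect(config: PhantomConfig) -> float:
    X, Y, _ = config.dims
    px = config.extent_mm[0] / X
    py = config.extent_mm[1] / Y
    return py / px


def generate_layer_surfaces(config: PhantomConfig,
                            rng: np.random.Generator) -> LayerSurfaces:
    """Nine smooth ordered border surfaces with a central foveal pit.

    Surfaces are built bottom-up from a gently undulating RPE/choroid
    interface by stacking the configured band thicknesses; the inner bands
    (NFL..OPL) are thinned by a Gaussian pit profile so the ILM deflects
    toward the outer retina at the fovea.
    """
    X, Y, Z = config.dims
    rpe = config.rpe_chr_depth_frac * Z + _smooth_field(
        (X, Y), config.undulation_px, sigma=max(X, Y) / 8.0, rng=rng
    )
    thick = np.array(config.thickness_frac) * Z  # (8,) band thicknesses, px

    r = _radius_grid(X, Y, _aspect(config))
    sigma = max(config.pit_radius_px, 1) / 1.5
    pit = config.pit_depth_px * np.exp(-0.5 * (r / sigma) ** 2)

    inner_total = thick[_INNER_BANDS].sum()
    # Distribute the pit deflection across the inner bands proportionally,
    # leaving a sliver (2%) so ordering never inverts after rounding.
    shrink = np.clip(pit / inner_total, 0.0, 0.98)

    borders_cont: dict[str, np.ndarray] = {}
    pos = rpe.copy()
    borders_cont["RPE/CHR"] = pos.copy()
    # walk upward: subtract OS+RPE, IS, ONL, OPL, INL, IPL, GCL, NFL
    for band_idx in range(7, -1, -1):
        t = np.full((X, Y), thick[band_idx])
        if band_idx < _INNER_BANDS.stop:
            t = t * (1.0 - shrink)
        pos = pos - t
        borders_cont[BORDER_NAMES[band_idx]] = pos.copy()
    grids = {
        name: np.clip(np.round(borders_cont[name]), 0, Z - 1).astype(np.int32)
        for name in BORDER_NAMES
    }
    return LayerSurfaces(grids)


def generate_vessel_network(config: PhantomConfig,
                            rng: np.random.Generator) -> VesselMask:
    """En-face vessel ground truth: tortuous tubes avoiding the fovea.

    Each vessel is a correlated random walk entering from an image border,
    heading roughly across the field, steered away from a foveal avascular
    disc; centerlines are rasterized and dilated to the drawn width
    (width 1 keeps the bare centerline — the thinnest vessels in this
    imaging geometry are a single pixel wide).
    """
    X, Y, Z = config.dims
    aspect = _aspect(config)
    mask = np.zeros((X, Y), dtype=bool)
    cx, cy = (X - 1) / 2.0, (Y - 1) / 2.0
    wmin, wmax = config.vessel_width_range
    max_steps = 3 * (X + Y)

    def walk(start: np.ndarray, heading: float, width: int, steps: int) -> list[np.ndarray]:
        pts = []
        pos = start.astype(float)
        h = heading
        pixels = np.zeros((X, Y), dtype=bool)
        for _ in range(steps):
            if not (0 <= pos[0] < X and 0 <= pos[1] < Y):
                break
            pts.append(pos.copy())
            ix, iy = int(round(pos[0])), int(round(pos[1]))
            if 0 <= ix < X and 0 <= iy < Y:
                pixels[ix, iy] = True
            # steer away from the foveal avascular zone
            dx, dy = pos[0] - cx, (pos[1] - cy) * aspect
            dist = np.hypot(dx, dy)
            if dist < 2.5 * config.fovea_avoid_radius_px and dist > 1e-6:
                away = np.arctan2(dy, dx)
                delta = (away - h + np.pi) % (2 * np.pi) - np.pi
                h += 0.25 * delta
            h += config.tortuosity * rng.standard_normal()
            pos = pos + np.array([np.cos(h), np.sin(h) / max(aspect, 1e-6)])
        if width > 1:
            radius = (width - 1) / 2.0
            yy, xx = np.ogrid[-int(np.ceil(radius)):int(np.ceil(radius)) + 1,
                              -int(np.ceil(radius)):int(np.ceil(radius)) + 1]
            selem = (xx ** 2 + yy ** 2) <= radius ** 2 + 1e-9
            pixels = ndimage.binary_dilation(pixels, structure=selem)
        mask[:] |= pixels
        return pts

    for _ in range(config.vessel_count):
        side = rng.integers(4)
        if side == 0:
            start = np.array([0.0, rng.uniform(0, Y)]); heading = 0.0
        elif side == 1:
            start = np.array([X - 1.0, rng.uniform(0, Y)]); heading = np.pi
        elif side == 2:
            start = np.array([rng.uniform(0, X), 0.0]); heading = np.pi / 2
        else:
            start = np.array([rng.uniform(0, X), Y - 1.0]); heading = -np.pi / 2
        heading += rng.uniform(-0.5, 0.5)
        width = int(rng.integers(wmin, wmax + 1))
        pts = walk(start, heading, width, max_steps)
        if pts and rng.uniform() < config.branch_prob and len(pts) > 10:
            branch_at = pts[int(rng.integers(5, len(pts)))]
            bh = rng.uniform(0, 2 * np.pi)
            bw = max(wmin, int(rng.integers(wmin, width + 1)))
            walk(branch_at, bh, bw, max_steps // 2)

    # constructive foveal avascular zone
    r = _radius_grid(X, Y, aspect)
    mask[r < config.fovea_avoid_radius_px] = False
    return VesselMask(mask.astype(np.uint8))


def render_phantom(config: PhantomConfig) -> Phantom:
    """Render the full phantom: banded volume + vessels + shadows + speckle.

    Construction order: (i) fill each inter-border band with its mean
    reflectivity, (ii) brighten vessel voxels inside the GCL band (and the
    IPL band beyond the configured eccentricity, where vessels penetrate
    deeper), (iii) attenuate every voxel below the vessel-bearing band in
    vessel columns (the shadow), (iv) apply unit-mean multiplicative gamma
    speckle, then clip to [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    surfaces = generate_layer_surfaces(config, rng)
    vessel_mask = generate_vessel_network(config, rng)

    X, Y, Z = config.dims
    zidx = np.arange(Z, dtype=np.int32)
    band_idx = np.zeros((X, Y, Z), dtype=np.int8)
    for name in BORDER_NAMES:
        band_idx += (zidx[None, None, :] >= surfaces[name][:, :, None])
    refl = np.asarray(config.reflectivity, dtype=np.float32)
    vol = refl[band_idx]

    vmask = vessel_mask.pixels.astype(bool)
    r = _radius_grid(X, Y, _aspect(config))
    deep = vmask & (r > config.ipl_penetration_radius_px)

    in_gcl = (band_idx == 2)  # GCL band
    in_ipl = (band_idx == 3)
    vol[vmask] = np.where(in_gcl[vmask], vol[vmask] * config.vessel_gain, vol[vmask])
    vol[deep] = np.where(in_ipl[deep], vol[deep] * config.vessel_gain, vol[deep])

    # shadow: below GCL/IPL in vessel columns (below IPL/INL where vessels
    # penetrate the IPL)
    shadow_border = np.where(deep, surfaces["IPL/INL"], surfaces["GCL/IPL"])
    below = zidx[None, None, :] > shadow_border[:, :, None]
    shadow = below & vmask[:, :, None]
    vol[shadow] *= config.shadow_attenuation

    if config.speckle_shape is not None and np.isfinite(config.speckle_shape):
        k = float(config.speckle_shape)
        vol = vol * rng.gamma(k, 1.0 / k, size=vol.shape).astype(np.float32)
    vol = np.clip(vol, 0.0, 1.0)

    volume = OCTVolume(vol, config.extent_mm)
    surfaces.validate_against(volume)
    return Phantom(volume, surfaces, vessel_mask, config)


def phantom_cohort(config: PhantomConfig, n: int, seed: int) -> list[Phantom]:
    """Render ``n`` independent phantoms with seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n) % (2**31 - 1)
    return [render_phantom(replace(config, seed=int(s))) for s in seeds]
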