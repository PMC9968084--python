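"""Core domain types and coordinate conventions.

The volumetric scan ``I(x, y, z)`` is held with ``x`` the fast-scan pixel
index (within a B-scan), ``y`` the B-scan index (slow axis), and ``z`` the
axial (depth) index.  By package convention ``z`` increases from the inner
retina (vitreous side) toward the choroid, so anatomically deeper layer
borders carry larger axial indices.  All layer-bounded projections use
voxel-count denominators, which makes them independent of this orientation
choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Anatomical order of the nine annotated retina layer borders, from the
#: inner limiting membrane down to the RPE/choroid interface.
BORDER_NAMES: tuple[str, ...] = (
    "ILM",
    "NFL/GCL",
    "GCL/IPL",
    "IPL/INL",
    "INL/OPL",
    "OPL/ONL",
    "ONL/IS",
    "IS/OS",
    "RPE/CHR",
)

#: Tissue bands delimited by consecutive borders (band i lies between
#: BORDER_NAMES[i] and BORDER_NAMES[i+1]); "vitreous" is above ILM and
#: "choroid" below RPE/CHR.
BAND_NAMES: tuple[str, ...] = (
    "NFL", "GCL", "IPL", "INL", "OPL", "ONL", "IS", "OS+RPE",
)


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its declared layout."""


@dataclass
class OCTVolume:
    """A 3D OCT intensity volume with physical extent metadata.

    Parameters
    ----------
    intensities
        Array of shape ``(X, Y, Z)`` with values in ``[0, 1]``.
    extent_mm
        Physical size ``(width, depth, height)`` in millimetres covered by
        the ``x``, ``y`` and ``z`` axes respectively.
    """

    intensities: np.ndarray
    extent_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValidationError(
                f"volume must be 3D, got shape {self.intensities.shape}"
            )
        if any(d < 2 for d in self.intensities.shape):
            raise ValidationError(f"all dims must be >= 2, got {self.dims}")
        if len(self.extent_mm) != 3 or any(e <= 0 for e in self.extent_mm):
            raise ValidationError(f"extent_mm must be 3 positive sizes, got {self.extent_mm}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("volume intensities must be finite")
        if self.intensities.min() < 0:
            raise ValidationError("volume intensities must be >= 0")
        self.extent_mm = tuple(float(e) for e in self.extent_mm)

    @property
    def dims(self) -> tuple[int, int, int]:
        """Voxel counts ``(X, Y, Z)``."""
        return self.intensities.shape

    @property
    def pitch_mm(self) -> tuple[float, float, float]:
        """Physical voxel pitch along each axis in mm."""
        return tuple(e / d for e, d in zip(self.extent_mm, self.dims))


@dataclass
class LayerSurfaces:
    """Per-(x, y) axial positions of named retina layer borders.

    ``borders`` maps border names (a subset of :data:`BORDER_NAMES`, in
    anatomical order) to ``(X, Y)`` integer grids of axial indices.
    """

    borders: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        cleaned: dict[str, np.ndarray] = {}
        shape = None
        for name in BORDER_NAMES:
            if name not in self.borders:
                continue
            grid = np.asarray(self.borders[name])
            if not np.issubdtype(grid.dtype, np.integer):
                if not np.allclose(grid, np.round(grid)):
                    raise ValidationError(f"border {name!r} has non-integer axial indices")
                grid = np.round(grid).astype(np.int32)
            else:
                grid = grid.astype(np.int32)
            if grid.ndim != 2:
                raise ValidationError(f"border {name!r} grid must be 2D")
            if shape is None:
                shape = grid.shape
            elif grid.shape != shape:
                raise ValidationError(
                    f"border {name!r} shape {grid.shape} != {shape}"
                )
            if grid.min() < 0:
                raise ValidationError(f"border {name!r} has negative axial index")
            cleaned[name] = grid
        unknown = set(self.borders) - set(BORDER_NAMES)
        if unknown:
            raise ValidationError(f"unknown border names: {sorted(unknown)}")
        self.borders = cleaned
        self._check_ordering()

    def _check_ordering(self) -> None:
        names = list(self.borders)
        for upper, lower in zip(names, names[1:]):
            diff = self.borders[lower] - self.borders[upper]
            if diff.min() < 0:
                x, y = np.argwhere(diff < 0)[0]
                raise ValidationError(
                    f"border ordering violated at (x={x}, y={y}): "
                    f"{upper!r} (z={self.borders[upper][x, y]}) below "
                    f"{lower!r} (z={self.borders[lower][x, y]})"
                )

    @property
    def grid_shape(self) -> tuple[int, int]:
        first = next(iter(self.borders.values()))
        return first.shape

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.borders[name]
        except KeyError:
            raise KeyError(
                f"border {name!r} not present; have {list(self.borders)}"
            ) from None

    def validate_against(self, volume: OCTVolume) -> None:
        """Check grids match the volume's en-face shape and axial range."""
        X, Y, Z = volume.dims
        if self.grid_shape != (X, Y):
            raise ValidationError(
                f"surface grid shape {self.grid_shape} != volume en-face shape {(X, Y)}"
            )
        for name, grid in self.borders.items():
            if grid.max() > Z - 1:
                raise ValidationError(
                    f"border {name!r} exceeds axial range (max {grid.max()} > {Z - 1})"
                )


@dataclass
class FundusImage:
    """A 2D en-face scalar image (projection or reconstruction)."""

    pixels: np.ndarray
    pixel_pitch_mm: tuple[float, float]
    provenance: str = "external"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise ValidationError(f"fundus image must be 2D (or 2D+channels), got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("fundus image pixels must be finite")
        if len(self.pixel_pitch_mm) != 2 or any(p <= 0 for p in self.pixel_pitch_mm):
            raise ValidationError(f"pixel_pitch_mm must be 2 positive values, got {self.pixel_pitch_mm}")
        self.pixel_pitch_mm = tuple(float(p) for p in self.pixel_pitch_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass
class VesselMask:
    """Binary en-face vessel mask (1 = vessel)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValidationError(f"mask must be 2D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"mask values must be 0/1, got {vals[:5]}")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ProbabilityMap:
    """Per-pixel vessel probability in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(f"probability map must be 2D, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("probabilities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValidationError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
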