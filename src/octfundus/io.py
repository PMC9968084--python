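"""Readers and writers for volumes, layer surfaces, fundus images and masks.

On-disk formats
---------------
* Raw volume: flat binary of scalars plus a JSON sidecar (``<name>.json``)
  declaring dims (in file axis order), axis order, dtype, endianness and
  physical extent.
* B-scan stack: a directory of one grayscale TIFF or PNG per B-scan, each
  of shape ``(Z, X)`` (axial rows, fast-scan columns), ordered by filename.
* Layer surfaces: long-format CSV with columns ``border_name,x,y,z_index``.
* Fundus images and probability maps: PNG (8- or 16-bit) after a min–max
  stretch, with a JSON sidecar recording pixel pitch, provenance and the
  stretch interval; masks: 8-bit PNG with 0/255 coding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import (
    BORDER_NAMES,
    FormatError,
    FundusImage,
    LayerSurfaces,
    OCTVolume,
    ProbabilityMap,
    ValidationError,
    VesselMask,
)


@dataclass
class VolumeLayout:
    """Describes how a raw volume file maps onto canonical (x, y, z) axes.

    ``axis_order`` names the file's axes from slowest- to fastest-varying,
    e.g. ``"yzx"`` means the file stores ``[y][z][x]``.  ``dims`` are the
    sizes in that same file order.
    """

    dims: tuple[int, int, int]
    axis_order: str = "xyz"
    dtype: str = "float32"
    byteorder: str = "little"
    extent_mm: tuple[float, float, float] = (7.0, 7.0, 2.0)

    def __post_init__(self) -> None:
        if sorted(self.axis_order) != ["x", "y", "z"]:
            raise ValidationError(f"axis_order must be a permutation of 'xyz', got {self.axis_order!r}")
        if len(self.dims) != 3:
            raise ValidationError("dims must have 3 entries (file axis order)")

    @property
    def np_dtype(self) -> np.dtype:
        dt = np.dtype(self.dtype)
        return dt.newbyteorder("<" if self.byteorder == "little" else ">")

    def to_dict(self) -> dict:
        return {
            "dims": list(self.dims),
            "axis_order": self.axis_order,
            "dtype": self.dtype,
            "byteorder": self.byteorder,
            "extent_mm": list(self.extent_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeLayout":
        return cls(
            dims=tuple(d["dims"]),
            axis_order=d["axis_order"],
            dtype=d["dtype"],
            byteorder=d.get("byteorder", "little"),
            extent_mm=tuple(d.get("extent_mm", (7.0, 7.0, 2.0))),
        )


def _rescale_to_unit(arr: np.ndarray, dtype: np.dtype) -> np.ndarray:
    """Map source scalars into the canonical [0, 1] intensity range."""
    arr = np.asarray(arr)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return (arr.astype(np.float32) - info.min) / float(info.max - info.min)
    arr = arr.astype(np.float32)
    if arr.size and arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def load_volume(path: str | Path, layout: VolumeLayout | None = None) -> OCTVolume:
    """Load an OCT volume from a raw binary file or a B-scan image stack.

    For a raw file, ``layout`` may be omitted if a JSON sidecar
    ``<path>.json`` exists.  For a directory, each image is one B-scan of
    shape ``(Z, X)`` and ``layout.extent_mm`` (if given) sets the extent.
    """
    path = Path(path)
    if path.is_dir():
        return _load_stack(path, layout)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"no layout given and no sidecar {sidecar}")
        layout = VolumeLayout.from_dict(json.loads(sidecar.read_text()))
    n_expected = int(np.prod(layout.dims))
    raw = np.fromfile(path, dtype=layout.np_dtype)
    if raw.size != n_expected:
        raise FormatError(
            f"{path}: file holds {raw.size} scalars but layout declares "
            f"{n_expected} ({'x'.join(map(str, layout.dims))})"
        )
    arr = raw.reshape(layout.dims)
    # permute file axes into canonical (x, y, z)
    perm = [layout.axis_order.index(ax) for ax in "xyz"]
    arr = np.transpose(arr, perm)
    extent = layout.extent_mm
    return OCTVolume(_rescale_to_unit(arr, layout.np_dtype.base), extent)


def _load_stack(path: Path, layout: VolumeLayout | None) -> OCTVolume:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    if not files:
        raise FormatError(f"{path}: no TIFF/PNG B-scans found")
    slices = []
    for f in files:
        try:
            if f.suffix.lower() in (".tif", ".tiff"):
                img = tifffile.imread(f)
            else:
                img = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - re-raise with filename
            raise OSError(f"unreadable B-scan image {f}: {exc}") from exc
        if img.ndim != 2:
            raise FormatError(f"{f}: B-scan must be grayscale 2D, got {img.shape}")
        slices.append(img)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise FormatError(f"{path}: inconsistent B-scan shapes {shapes}")
    stack = np.stack(slices)  # (Y, Z, X)
    arr = np.transpose(stack, (2, 0, 1))  # -> (X, Y, Z)
    extent = layout.extent_mm if layout is not None else (7.0, 7.0, 2.0)
    return OCTVolume(_rescale_to_unit(arr, stack.dtype), extent)


def save_volume(volume: OCTVolume, path: str | Path) -> None:
    """Write a volume as raw little-endian float32 in (x, y, z) order plus sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    volume.intensities.astype("<f4").tofile(path)
    layout = VolumeLayout(
        dims=volume.dims, axis_order="xyz", dtype="float32",
        byteorder="little", extent_mm=volume.extent_mm,
    )
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(layout.to_dict()))


def save_volume_stack(volume: OCTVolume, path: str | Path) -> None:
    """Write a volume as a directory of per-B-scan float32 TIFFs of shape (Z, X)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X, Y, Z = volume.dims
    for y in range(Y):
        bscan = volume.intensities[:, y, :].T.astype(np.float32)  # (Z, X)
        tifffile.imwrite(path / f"bscan_{y:04d}.tiff", bscan)


def load_surfaces(path: str | Path) -> tuple[LayerSurfaces, dict]:
    """Load layer border surfaces from a long-format CSV.

    Returns the surfaces and a metadata dict listing any of the nine
    canonical borders absent from the file.
    """
    df = pd.read_csv(path)
    required = {"border_name", "x", "y", "z_index"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: surface CSV needs columns {sorted(required)}")
    X = int(df["x"].max()) + 1
    Y = int(df["y"].max()) + 1
    borders: dict[str, np.ndarray] = {}
    for name, grp in df.groupby("border_name", sort=False):
        if len(grp) != X * Y:
            raise ValidationError(
                f"border {name!r} covers {len(grp)} of {X * Y} (x, y) positions"
            )
        grid = np.full((X, Y), -1, dtype=np.int32)
        grid[grp["x"].to_numpy(), grp["y"].to_numpy()] = grp["z_index"].to_numpy()
        if (grid < 0).any():
            raise ValidationError(f"border {name!r} has duplicate or missing (x, y) entries")
        borders[name] = grid
    surfaces = LayerSurfaces({n: borders[n] for n in BORDER_NAMES if n in borders})
    missing = [n for n in BORDER_NAMES if n not in borders]
    return surfaces, {"missing_borders": missing}


def save_surfaces(surfaces: LayerSurfaces, path: str | Path) -> None:
    """Write layer border surfaces as long-format CSV (border_name, x, y, z_index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for name, grid in surfaces.borders.items():
        X, Y = grid.shape
        xs, ys = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
        frames.append(pd.DataFrame({
            "border_name": name,
            "x": xs.ravel(),
            "y": ys.ravel(),
            "z_index": grid.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_fundus(image: FundusImage, path: str | Path, bit_depth: int = 8) -> None:
    """Write a fundus image as PNG after a min–max stretch, with JSON sidecar.

    A constant image cannot be stretched; it is written as mid-gray with a
    warning so degenerate inputs do not abort batch runs.
    """
    if bit_depth not in (8, 16):
        raise ValidationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px = image.pixels
    vmin, vmax = float(px.min()), float(px.max())
    top = 2**bit_depth - 1
    if vmax > vmin:
        scaled = (px - vmin) / (vmax - vmin) * top
    else:
        warnings.warn(
            f"constant fundus image (value {vmin}); writing mid-gray", stacklevel=2
        )
        scaled = np.full_like(px, (top + 1) // 2, dtype=np.float64)
    out = np.round(scaled).astype(np.uint8 if bit_depth == 8 else np.uint16)
    iio.imwrite(path, out)
    sidecar = {
        "pixel_pitch_mm": list(image.pixel_pitch_mm),
        "provenance": image.provenance,
        "stretch": [vmin, vmax],
        "bit_depth": bit_depth,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_fundus(path: str | Path) -> FundusImage:
    """Load a PNG fundus image written by :func:`save_fundus`, undoing the stretch."""
    path = Path(path)
    arr = iio.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:
        meta = {"pixel_pitch_mm": [1.0, 1.0], "provenance": "external",
                "stretch": [0.0, 1.0], "bit_depth": 8 * arr.dtype.itemsize}
    top = 2 ** meta["bit_depth"] - 1
    vmin, vmax = meta["stretch"]
    px = arr.astype(np.float64) / top
    if vmax > vmin:
        px = px * (vmax - vmin) + vmin
    else:
        px = np.full_like(px, vmin)
    return FundusImage(px, tuple(meta["pixel_pitch_mm"]), meta["provenance"])


def save_mask(mask: VesselMask, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))


def load_mask(path: str | Path) -> VesselMask:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return VesselMask((arr > 127).astype(np.uint8))


def save_probability_map(prob: ProbabilityMap, path: str | Path) -> None:
    """Write a probability map as 16-bit PNG (fixed [0, 1] scale) with sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.round(prob.pixels * 65535).astype(np.uint16))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({"scale": [0.0, 1.0]}))


def load_probability_map(path: str | Path) -> ProbabilityMap:
    arr = iio.imread(path)
    return ProbabilityMap(arr.astype(np.float64) / 65535.0)
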