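"""File I/O: imzML ingestion, whole-slide images, and HDF5 cube caching."""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import h5py
import numpy as np
from PIL import Image

from .cubes import HFCube, MSICube
from .errors import FormatError, ValidationError

__all__ = ["read_imzml", "write_imzml", "read_wsi", "write_cube", "read_cube"]


def read_imzml(path: str | Path, pixel_size_um: float | None = None) -> MSICube:
    """Read an imzML(+ibd) file into a dense :class:`MSICube`.

    The grid spans the bounding box of the recorded 1-based pixel
    coordinates, converted to 0-based row-major indices.  Coordinates absent
    from the file (raster dropouts) become background pixels with zero
    intensities.  All spectra must share one m/z axis ("continuous" mode) or
    are binned onto the union axis for "processed" mode files whose axes agree.

    Parameters
    ----------
    path : path to the .imzML file (the .ibd companion must sit next to it).
    pixel_size_um : overrides the pixel size when the file metadata lacks one.
    """
    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FormatError(f"missing binary companion file {ibd}")
    try:
        from pyimzml.ImzMLParser import ImzMLParser
        parser = ImzMLParser(str(path))
    except FormatError:
        raise
    except Exception as exc:  # pyimzml raises bare Exceptions on bad XML
        raise FormatError(f"could not parse {path}: {exc}") from exc

    coords = [(x, y) for (x, y, _z) in parser.coordinates]
    if len(set(coords)) != len(coords):
        seen: set[tuple[int, int]] = set()
        for c in coords:
            if c in seen:
                raise FormatError(f"duplicate pixel coordinate {c} in {path}")
            seen.add(c)

    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    x0, y0 = min(xs), min(ys)
    rows = max(ys) - y0 + 1
    cols = max(xs) - x0 + 1

    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=np.float64)
    intensities = np.zeros((rows, cols, mz0.size))
    foreground = np.zeros((rows, cols), dtype=bool)
    for i, (x, y) in enumerate(coords):
        mz, inten = parser.getspectrum(i)
        if not np.array_equal(np.asarray(mz), mz0):
            raise FormatError(
                "per-spectrum m/z axes differ; convert to continuous imzML")
        r, c = y - y0, x - x0
        intensities[r, c] = inten
        foreground[r, c] = True

    if pixel_size_um is None:
        px = parser.imzmldict.get("pixel size x", None)
        pixel_size_um = float(px) if px else 1.0
    return MSICube((rows, cols), float(pixel_size_um), mz0, intensities,
                   foreground, meta={"source": str(path)})


def write_imzml(cube: MSICube, path: str | Path) -> Path:
    """Write a cube to continuous-mode imzML; foreground pixels only."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    with ImzMLWriter(str(path), mode="continuous") as writer:
        for r in range(cube.grid_shape[0]):
            for c in range(cube.grid_shape[1]):
                if cube.foreground_mask[r, c]:
                    # imzML coordinates are 1-based (x, y)
                    writer.addSpectrum(cube.mz_axis, cube.intensities[r, c],
                                       (c + 1, r + 1))
    return path


def read_wsi(path: str | Path, pixel_size_um: float) -> tuple[np.ndarray, dict]:
    """Read a flat TIFF/PNG whole-slide image as 8-bit RGB, no resampling.

    Returns ``(image, meta)`` where image is uint8 of shape (H, W, 3) and
    meta records the pixel size.  16-bit input is rescaled to 8-bit with a
    warning; grayscale or alpha-only input is rejected.
    """
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be positive")
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        raise FormatError(f"{path}: RGBA input not supported, flatten alpha")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected a 3-channel RGB image, got shape "
                          f"{arr.shape}")
    if arr.dtype == np.uint16:
        warnings.warn(f"{path}: 16-bit image rescaled to 8-bit")
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype}")
    return arr, {"pixel_size_um": float(pixel_size_um), "source": str(path)}


# ---------------------------------------------------------------------------
# HDF5 cube cache


def write_cube(cube: MSICube | HFCube, path: str | Path) -> Path:
    """Serialize a cube to HDF5 so stages can run from cached intermediates."""
    cube.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        if isinstance(cube, MSICube):
            f.attrs["kind"] = "msi"
            f.attrs["pixel_size_um"] = cube.pixel_size_um
            f.create_dataset("mz_axis", data=cube.mz_axis)
            f.create_dataset("data", data=cube.intensities)
            f.attrs["meta"] = json.dumps(cube.meta)
        else:
            f.attrs["kind"] = "hf"
            f.attrs["tile_size_px"] = cube.tile_size_px
            f.create_dataset("data", data=cube.features)
            f.attrs["meta"] = json.dumps(cube.provenance)
        f.attrs["grid_shape"] = cube.grid_shape
        f.create_dataset("foreground_mask", data=cube.foreground_mask)
    return path


def read_cube(path: str | Path) -> MSICube | HFCube:
    """Inverse of :func:`write_cube`."""
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        grid = tuple(int(v) for v in f.attrs["grid_shape"])
        mask = f["foreground_mask"][()].astype(bool)
        meta: dict[str, Any] = json.loads(f.attrs["meta"])
        data = f["data"][()]
        if kind == "msi":
            return MSICube(grid, float(f.attrs["pixel_size_um"]),
                           f["mz_axis"][()], data, mask, meta)
        return HFCube(grid, int(f.attrs["tile_size_px"]), data, mask, meta)
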