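"""Hyperspectral cube containers shared by every pipeline stage.

Both modalities are represented as a dense pixel grid carrying one vector per
grid cell: ion intensities over an m/z axis for MSI, or histomorphological
feature (HF) values over a feature axis for the tiled H&E image.  Coordinates
are 0-based and row-major throughout the package; file formats with other
conventions are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError


def _as_grid(name: str, arr: np.ndarray, grid_shape: tuple[int, int],
             depth: int) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    expected = (*grid_shape, depth)
    if arr.shape != expected:
        raise ValidationError(
            f"{name} has shape {arr.shape}, expected {expected}")
    return arr


@dataclass
class MSICube:
    """A mass spectrometry imaging dataset as a dense hyperspectral cube.

    Parameters
    ----------
    grid_shape : (rows, cols)
        Size of the acquisition raster.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    mz_axis : ndarray of shape (n_channels,)
        Strictly increasing m/z centroids in Da.
    intensities : ndarray of shape (rows, cols, n_channels)
        Ion abundances per pixel, arbitrary units, non-negative.
    foreground_mask : ndarray of bool, shape (rows, cols)
        True where the pixel lies on tissue.
    meta : dict
        Acquisition provenance strings.
    """

    grid_shape: tuple[int, int]
    pixel_size_um: float
    mz_axis: np.ndarray
    intensities: np.ndarray
    foreground_mask: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_shape = (int(self.grid_shape[0]), int(self.grid_shape[1]))
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64).ravel()
        self.intensities = _as_grid("intensities", self.intensities,
                                    self.grid_shape, self.mz_axis.size)
        self.foreground_mask = np.asarray(self.foreground_mask, dtype=bool)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.mz_axis.size == 0:
            raise ValidationError("mz_axis is empty")
        diffs = np.diff(self.mz_axis)
        if np.any(diffs <= 0):
            raise ValidationError("mz_axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain NaN or Inf")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        if self.foreground_mask.shape != self.grid_shape:
            raise ValidationError(
                f"foreground_mask shape {self.foreground_mask.shape} != "
                f"grid_shape {self.grid_shape}")

    # -- convenience -----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return int(self.mz_axis.size)

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.grid_shape))

    def spectra(self, foreground_only: bool = True) -> np.ndarray:
        """Pixel spectra as a 2-D matrix (pixels x channels)."""
        flat = self.intensities.reshape(-1, self.n_channels)
        if foreground_only:
            return flat[self.foreground_mask.ravel()]
        return flat

    def ion_image(self, mz: float, tol: float = 0.005) -> np.ndarray:
        """Single-ion image of the channel nearest to ``mz``.

        ``tol`` is relative: the match must lie within ``tol * mz`` Da.
        """
        idx = int(np.argmin(np.abs(self.mz_axis - mz)))
        if abs(self.mz_axis[idx] - mz) > tol * mz:
            raise ValidationError(f"no channel within {tol * mz:.3f} Da of {mz}")
        return self.intensities[:, :, idx]

    def copy(self) -> "MSICube":
        return MSICube(self.grid_shape, self.pixel_size_um,
                       self.mz_axis.copy(), self.intensities.copy(),
                       self.foreground_mask.copy(), dict(self.meta))


@dataclass
class HFCube:
    """Histomorphological-feature spectra on the MSI-matched tile grid.

    Each H&E tile (one per MSI pixel) is encoded as a vector of D features,
    min-max scaled to [0, 1] feature-wise over the foreground tiles.
    ``provenance`` records the extractor backend, the layer the features come
    from, and the scaling mode, so results can be traced to the exact encoder.
    """

    grid_shape: tuple[int, int]
    tile_size_px: int
    features: np.ndarray
    foreground_mask: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_shape = (int(self.grid_shape[0]), int(self.grid_shape[1]))
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 3 or self.features.shape[:2] != self.grid_shape:
            raise ValidationError(
                f"features shape {self.features.shape} incompatible with "
                f"grid {self.grid_shape}")
        self.foreground_mask = np.asarray(self.foreground_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.tile_size_px < 1:
            raise ValidationError("tile_size_px must be >= 1")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("features contain NaN or Inf")
        fg = self.features[self.foreground_mask]
        if fg.size and (fg.min() < -1e-9 or fg.max() > 1 + 1e-9):
            raise ValidationError("scaled feature values must lie in [0, 1]")
        if self.foreground_mask.shape != self.grid_shape:
            raise ValidationError(
                f"foreground_mask shape {self.foreground_mask.shape} != "
                f"grid_shape {self.grid_shape}")

    @property
    def n_features(self) -> int:
        return int(self.features.shape[2])

    @property
    def feature_axis(self) -> np.ndarray:
        return np.arange(self.n_features)

    def spectra(self, foreground_only: bool = True) -> np.ndarray:
        flat = self.features.reshape(-1, self.n_features)
        if foreground_only:
            return flat[self.foreground_mask.ravel()]
        return flat

    def copy(self) -> "HFCube":
        return HFCube(self.grid_shape, self.tile_size_px,
                      self.features.copy(), self.foreground_mask.copy(),
                      dict(self.provenance))
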