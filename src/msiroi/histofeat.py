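"""Whole-slide H&E image -> histomorphological-feature (HF) cube.

The slide is prepared (tissue detection + color normalization), split into
non-overlapping tiles whose physical size equals one MSI pixel, and each
tile with at least 90% tissue is encoded into an HF spectrum by a pluggable
feature extractor.  Feature-wise min-max scaling over the foreground tiles
assembles the result into an :class:`~msiroi.cubes.HFCube` on the MSI grid.

Two backends are provided.  ``densenet201`` resizes tiles to 224x224,
centers the channels with the ImageNet statistics, and pools the
``conv5_block32_concat`` tensor of DenseNet-201 into 1,920 features (see
:mod:`msiroi.densenet` for how kernels are supplied).  ``classical`` is a
fast deterministic descriptor of color and texture statistics used where a
convolutional forward pass would be wasteful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, feature, filters, morphology, transform

from .cubes import HFCube
from .errors import CapabilityError, PreparationError, ValidationError

__all__ = ["TileGrid", "prepare_wsi", "tile_image", "tile_foreground",
           "extract_hf", "scale_features", "CLASSICAL_DIM"]

#: length of the classical descriptor: 3x(mean,std) + 3x8-bin histogram
#: + 4 GLCM properties at 2 offsets + gradient (mean,std)
CLASSICAL_DIM = 40


@dataclass
class TileGrid:
    """Bookkeeping of the tiling of one whole-slide image."""

    tile_size_px: int
    grid_shape: tuple[int, int]
    tissue_fraction: np.ndarray          # (rows, cols) in [0, 1]
    foreground: np.ndarray | None = None  # (rows, cols) bool


def prepare_wsi(image: np.ndarray,
                reference: np.ndarray | None = None,
                min_object_px: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Tissue detection and color normalization for an 8-bit RGB slide.

    Tissue is found by Otsu thresholding the HSV saturation channel and
    removing small objects.  Colors are normalized by matching per-channel
    mean and standard deviation to ``reference``; with no reference (or the
    image itself) normalization is the identity.

    Returns ``(tissue_mask, normalized_image)``.
    """
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValidationError("expected an 8-bit RGB image")
    sat = color.rgb2hsv(image)[:, :, 1]
    if np.ptp(sat) == 0:
        raise PreparationError("saturation image is constant; no tissue found")
    mask = sat > filters.threshold_otsu(sat)
    mask = morphology.remove_small_objects(mask, min_size=min_object_px)
    mask = morphology.closing(mask, morphology.disk(2))
    if not mask.any():
        raise PreparationError("tissue mask is empty")

    if reference is None or reference is image:
        return mask, image.copy()
    img_f = image.astype(np.float64)
    ref_f = reference.astype(np.float64)
    out = np.empty_like(img_f)
    for ch in range(3):
        m, s = img_f[:, :, ch].mean(), img_f[:, :, ch].std()
        rm, rs = ref_f[:, :, ch].mean(), ref_f[:, :, ch].std()
        if s == 0:
            out[:, :, ch] = rm
        else:
            out[:, :, ch] = (img_f[:, :, ch] - m) / s * rs + rm
    return mask, np.clip(np.round(out), 0, 255).astype(np.uint8)


def tile_image(image: np.ndarray, he_pixel_um: float, msi_pixel_um: float,
               tissue_mask: np.ndarray) -> tuple[TileGrid, np.ndarray]:
    """Split the slide into tiles matching the MSI pixel size.

    One tile edge spans ``msi_pixel_um / he_pixel_um`` H&E pixels, which must
    be within 1% of an integer (e.g. 100 um MSI at 0.5 um H&E -> 200 px).
    Tiling starts at the top-left origin; partial edge tiles are dropped.

    Returns ``(TileGrid, tiles)`` with tiles of shape
    ``(rows, cols, tile, tile, 3)``.
    """
    ratio = msi_pixel_um / he_pixel_um
    tile = int(round(ratio))
    if tile < 1 or abs(ratio - tile) / tile >= 0.01:
        raise ValidationError(
            f"MSI/H&E pixel size ratio {ratio:.4f} is not integral "
            "within 1%; resample the slide first")
    rows = image.shape[0] // tile
    cols = image.shape[1] // tile
    if rows == 0 or cols == 0:
        raise ValidationError("image smaller than one tile")
    crop = image[: rows * tile, : cols * tile]
    tiles = crop.reshape(rows, tile, cols, tile, 3).transpose(0, 2, 1, 3, 4)
    mask_crop = tissue_mask[: rows * tile, : cols * tile]
    frac = mask_crop.reshape(rows, tile, cols, tile).mean(axis=(1, 3))
    return TileGrid(tile, (rows, cols), frac), np.ascontiguousarray(tiles)


def tile_foreground(grid: TileGrid,
                    min_tissue_fraction: float = 0.9) -> np.ndarray:
    """Flag tiles with tissue fraction >= the threshold (inclusive)."""
    grid.foreground = grid.tissue_fraction >= min_tissue_fraction
    return grid.foreground


def _classical_descriptor(tile: np.ndarray) -> np.ndarray:
    """Color + texture statistics of one RGB tile (length CLASSICAL_DIM)."""
    f: list[float] = []
    tf = tile.astype(np.float64)
    for ch in range(3):
        f.extend([tf[:, :, ch].mean(), tf[:, :, ch].std()])
    for ch in range(3):
        hist, _ = np.histogram(tile[:, :, ch], bins=8, range=(0, 256))
        f.extend(hist / hist.sum())
    gray = (color.rgb2gray(tile) * 31).astype(np.uint8)
    glcm = feature.graycomatrix(gray, distances=[1], angles=[0, np.pi / 2],
                                levels=32, symmetric=True, normed=True)
    for prop in ("contrast", "homogeneity", "energy", "correlation"):
        f.extend(feature.graycoprops(glcm, prop).ravel())
    gy, gx = np.gradient(color.rgb2gray(tile))
    gm = np.hypot(gx, gy)
    f.extend([gm.mean(), gm.std()])
    return np.asarray(f)


def extract_hf(tiles: np.ndarray, backend: str = "classical",
               weights: str | None = None, seed: int = 0) -> np.ndarray:
    """Encode a stack of RGB tiles into raw HF vectors.

    ``tiles`` is ``(n, h, w, 3)`` uint8.  Returns ``(n, D)`` with D = 1,920
    for ``densenet201`` and D = 40 for ``classical``.
    """
    tiles = np.asarray(tiles)
    if tiles.ndim != 4 or tiles.shape[3] != 3:
        raise ValidationError("tiles must be a stack of RGB images")
    if backend == "classical":
        return np.stack([_classical_descriptor(t) for t in tiles])
    if backend == "densenet201":
        from .densenet import DenseNet201Features
        net = DenseNet201Features(weights=weights, seed=seed)
        out = []
        for t in tiles:
            resized = transform.resize(t.astype(np.float64), (224, 224),
                                       order=1, preserve_range=True,
                                       anti_aliasing=False)
            out.append(net.forward(resized))
        return np.stack(out)
    raise CapabilityError(
        f"unknown backend {backend!r}; available: 'classical', 'densenet201'")


def scale_features(vectors: np.ndarray, grid: TileGrid,
                   provenance: dict | None = None) -> HFCube:
    """Feature-wise min-max scaling over foreground tiles -> HFCube.

    ``vectors`` holds one row per foreground tile, in row-major grid order.
    Constant features map to 0 and are flagged in the provenance.
    """
    if grid.foreground is None:
        raise ValidationError("run tile_foreground first")
    fg = grid.foreground
    n_fg = int(fg.sum())
    if n_fg < 2:
        raise ValidationError("need at least 2 foreground tiles to scale")
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.shape[0] != n_fg:
        raise ValidationError(
            f"got {vectors.shape[0]} vectors for {n_fg} foreground tiles")
    lo = vectors.min(axis=0)
    span = vectors.max(axis=0) - lo
    constant = span == 0
    span_safe = np.where(constant, 1.0, span)
    scaled = (vectors - lo) / span_safe
    scaled[:, constant] = 0.0

    rows, cols = grid.grid_shape
    cube_data = np.zeros((rows, cols, vectors.shape[1]))
    cube_data[fg] = scaled
    prov = dict(provenance or {})
    prov.setdefault("scaling", "feature-wise min-max over foreground tiles")
    prov["constant_features"] = np.flatnonzero(constant).tolist()
    return HFCube((rows, cols), grid.tile_size_px, cube_data, fg, prov)
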