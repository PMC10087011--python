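"""Confidence-masked ROI delineation and characteristic-ion ranking.

At the selected number of clusters, the MSI and histology labelings are
fused: pixels whose aligned labels agree are *confident* and form the ROIs
(colored solid); disagreeing pixels are *unconfident* and rendered
translucent.  Ions colocalizing with each ROI are ranked by the Pearson
correlation between their ion image and the ROI's binary mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cubes import MSICube
from .errors import ValidationError
from .segmentation import Labeling

__all__ = ["ROISet", "IonRanking", "PALETTE", "integrate_labels",
           "extract_rois", "rank_ions", "render_label_rgb", "render_overlay"]

#: fixed categorical palette keyed by (MSI) cluster id, mirroring the
#: red / blue / orange / green / magenta convention of the label maps
PALETTE = np.array([
    [230, 40, 40],     # 1 red
    [45, 80, 230],     # 2 blue
    [250, 160, 30],    # 3 orange
    [60, 180, 75],     # 4 green
    [220, 60, 220],    # 5 magenta
    [70, 200, 200],    # 6 teal
    [150, 110, 40],    # 7 brown
    [130, 130, 220],   # 8 periwinkle
    [160, 160, 40],    # 9 olive
], dtype=np.uint8)


@dataclass
class ROISet:
    """Disjoint confident-pixel region masks plus the unconfident mask.

    The domain is the intersection of the two modalities' foregrounds;
    everything else is background.  Region ids follow the MSI labeling.
    """

    region_masks: dict[int, np.ndarray]
    unconfident_mask: np.ndarray
    K: int
    grid_shape: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        cover = self.unconfident_mask.copy()
        for rid, m in self.region_masks.items():
            if m.shape != self.grid_shape:
                raise ValidationError(f"region {rid} has wrong shape")
            if np.any(cover & m):
                raise ValidationError("region masks overlap")
            cover |= m

    @property
    def confident_mask(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=bool)
        for m in self.region_masks.values():
            out |= m
        return out


@dataclass
class IonRanking:
    """Per-region ions sorted by descending Pearson r with the ROI mask."""

    rankings: dict[int, list[tuple[float, float]]]   # id -> [(m/z, r), ...]
    excluded_mz: list[float]

    def top_ion(self, region: int) -> tuple[float, float]:
        return self.rankings[region][0]

    def to_frame(self):
        import pandas as pd
        rows = [(rid, rank + 1, mz, r)
                for rid, pairs in self.rankings.items()
                for rank, (mz, r) in enumerate(pairs)]
        return pd.DataFrame(rows, columns=["region", "rank", "mz", "r"])


def integrate_labels(msi: Labeling, hf: Labeling,
                     permutation: tuple[int, ...]) -> ROISet:
    """Fuse the two labelings at K* into a confidence-masked ROI set.

    ``permutation`` is the label alignment from
    :func:`~msiroi.validation.align_labels`: ``permutation[i]`` is the MSI
    label id matching hf label ``i + 1``.  Confident pixels are those where
    the aligned labels agree.
    """
    if msi.K != hf.K:
        raise ValidationError("labelings disagree on K")
    if sorted(permutation) != list(range(1, msi.K + 1)):
        raise ValidationError(
            f"permutation {permutation} is not a bijection on 1..{msi.K}")
    if msi.foreground_mask.shape != hf.foreground_mask.shape:
        raise ValidationError("labelings live on different grids")
    shared = msi.foreground_mask & hf.foreground_mask
    mmap = msi.label_map()
    perm = np.concatenate([[0], np.asarray(permutation, dtype=int)])
    hmap_aligned = perm[hf.label_map()]
    agree = shared & (mmap == hmap_aligned)
    regions = {rid: agree & (mmap == rid) for rid in range(1, msi.K + 1)}
    roiset = ROISet(regions, shared & ~agree, msi.K, msi.foreground_mask.shape,
                    meta={"permutation": tuple(permutation)})
    roiset.validate()
    return roiset


def extract_rois(roiset: ROISet) -> dict[int, dict]:
    """Per-region masks with pixel counts and confident fractions.

    Empty regions are retained with a warning so downstream ids stay stable.
    """
    roiset.validate()
    n_domain = int(roiset.confident_mask.sum() +
                   roiset.unconfident_mask.sum())
    out = {}
    for rid, mask in sorted(roiset.region_masks.items()):
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"region {rid} has no confident pixel")
        out[rid] = {"mask": mask, "n_pixels": n,
                    "confident_fraction": n / n_domain if n_domain else 0.0}
    return out


def rank_ions(cube: MSICube, roiset: ROISet, top_n: int = 10) -> IonRanking:
    """Rank ions by Pearson correlation with each ROI's binary mask.

    Correlations are computed over the shared-foreground domain only
    (confident plus unconfident pixels).  Zero-variance ion images are
    excluded; empty regions are skipped with a warning.
    """
    if cube.grid_shape != roiset.grid_shape:
        raise ValidationError("cube and ROISet are on different grids")
    domain = roiset.confident_mask | roiset.unconfident_mask
    X = cube.intensities[domain]                     # (n_dom, channels)
    sd = X.std(axis=0)
    usable = sd > 0
    excluded = cube.mz_axis[~usable].tolist()
    Xc = X[:, usable] - X[:, usable].mean(axis=0)
    Xn = Xc / np.linalg.norm(Xc, axis=0)
    rankings: dict[int, list[tuple[float, float]]] = {}
    for rid, mask in sorted(roiset.region_masks.items()):
        if not mask.any():
            warnings.warn(f"region {rid} is empty; skipped")
            continue
        y = mask[domain].astype(float)
        yc = y - y.mean()
        yn = yc / np.linalg.norm(yc)
        r = Xn.T @ yn
        order = np.argsort(-r)[:top_n]
        rankings[rid] = [(float(cube.mz_axis[usable][i]), float(r[i]))
                         for i in order]
    return IonRanking(rankings, excluded)


def render_label_rgb(roiset: ROISet, alpha: float = 0.5,
                     background: tuple[int, int, int] = (255, 255, 255)
                     ) -> np.ndarray:
    """RGB rendering: solid color for confident pixels, translucent
    (blended toward the background at ``alpha``) for unconfident ones."""
    rows, cols = roiset.grid_shape
    out = np.full((rows, cols, 3), background, dtype=np.float64)
    palette = PALETTE[(np.arange(roiset.K)) % len(PALETTE)]
    for rid, mask in roiset.region_masks.items():
        out[mask] = palette[rid - 1]
    # unconfident pixels keep their MSI color but fade toward background
    if roiset.unconfident_mask.any() and "msi_label_map" in roiset.meta:
        lmap = roiset.meta["msi_label_map"]
        uc = roiset.unconfident_mask
        out[uc] = (alpha * palette[lmap[uc] - 1] +
                   (1 - alpha) * np.asarray(background, dtype=np.float64))
    elif roiset.unconfident_mask.any():
        gray = np.array([128, 128, 128], dtype=np.float64)
        uc = roiset.unconfident_mask
        out[uc] = alpha * gray + (1 - alpha) * np.asarray(background, float)
    return out.round().astype(np.uint8)


def render_overlay(layer: np.ndarray, he_image: np.ndarray,
                   upsample_factor: int, alpha: float = 0.5,
                   is_label_map: bool = False) -> np.ndarray:
    """Upsample a grid-resolution layer and blend it onto the H&E image.

    ``upsample_factor`` must equal the tile size so the upsampled layer
    matches the tiled extent of the slide.  Ion (continuous) layers use
    order-3 spline interpolation; label maps use nearest neighbour.
    """
    rows, cols = layer.shape[:2]
    he_rows = he_image.shape[0] // upsample_factor
    he_cols = he_image.shape[1] // upsample_factor
    if (rows, cols) != (he_rows, he_cols):
        raise ValidationError(
            f"upsample factor {upsample_factor} maps grid {(rows, cols)} to "
            f"{(rows * upsample_factor, cols * upsample_factor)}, but the "
            f"tiled H&E extent is {(he_rows * upsample_factor, he_cols * upsample_factor)}")
    he_crop = he_image[: rows * upsample_factor,
                       : cols * upsample_factor].astype(np.float64)
    order = 0 if is_label_map else 3
    if layer.ndim == 2:   # scalar map -> colorize with a hot colormap
        import matplotlib
        up = ndimage.zoom(layer.astype(np.float64), upsample_factor,
                          order=order, grid_mode=True, mode="nearest")
        span = np.ptp(up)
        norm = (up - up.min()) / span if span > 0 else np.zeros_like(up)
        rgb = matplotlib.colormaps["hot"](norm)[:, :, :3] * 255
    else:
        rgb = np.stack([ndimage.zoom(layer[:, :, ch].astype(np.float64),
                                     upsample_factor, order=order,
                                     grid_mode=True, mode="nearest")
                        for ch in range(3)], axis=2)
    blend = (1 - alpha) * he_crop + alpha * rgb
    return np.clip(blend.round(), 0, 255).astype(np.uint8)
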