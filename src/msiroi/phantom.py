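"""Paired MSI/H&E phantoms with known region structure.

The generator emulates the data regime of a serial-section experiment:
a tissue blob partitioned into ``K_true`` contiguous regions shared by both
modalities; region-specific mass-spectral peak signatures and HF feature
prototypes; per-pixel TIC variation, additive noise, and salt-and-pepper
mislabeled pixels on the MSI side; background-dominated ("noisy") ion
channels; a smooth nonlinear deformation between the two modality grids
mimicking serial-section mismatch; and, optionally, a spurious region
present in the MSI modality only.  The H&E side is emitted both as direct
feature prototypes (fast tests) and as a renderable procedural texture
image so the tiling/feature-extraction path can run end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .cubes import HFCube, MSICube
from .errors import ValidationError

__all__ = ["PhantomParams", "PhantomTruth", "Phantom", "generate_phantom",
           "inject_marker_ions", "label_agreement"]


@dataclass
class PhantomParams:
    """Generator settings; the defaults mirror a whole-organ case at
    desk scale: 4 anatomical regions, a 60x60 raster, ~1% scattered
    mislabeled pixels and a 2 px serial-section deformation."""

    K_true: int = 4
    grid_shape: tuple[int, int] = (60, 60)
    n_channels_msi: int = 120
    n_features_hf: int = 64
    msi_noise: float = 0.10       # additive noise, fraction of mean signal
    hf_noise: float = 0.05        # feature noise (features live in [0,1])
    hf_smooth: float = 0.06       # smooth within-region texture gradient
    tic_cv: float = 0.20          # per-pixel multiplicative TIC spread
    saltpepper_rate: float = 0.01
    deformation_px: float = 2.0   # max smooth warp magnitude
    translation_px: tuple[float, float] = (0.0, 0.0)  # (dy, dx) added
    spurious_region: bool = False
    n_noisy_channels: int = 10
    tile_size_px: int = 8
    msi_pixel_um: float = 100.0


@dataclass
class PhantomTruth:
    """Ground truth of one phantom realization."""

    labels_hf: np.ndarray          # (rows, cols), 0 = background
    labels_msi: np.ndarray         # after deformation (+ spurious region)
    marker_channels: dict[int, int]
    noisy_channels: list[int]
    deformation: np.ndarray        # (rows, cols, 2): msi(x) = hf(x + d(x))
    saltpepper_pixels: np.ndarray  # (n, 2) row/col on the MSI grid
    spurious_label: int | None
    seed: int
    params: PhantomParams = field(repr=False, default=None)


@dataclass
class Phantom:
    msi: MSICube
    hf: HFCube
    he_image: np.ndarray           # uint8 RGB at tile resolution
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# geometry


def _tissue_blob(shape: tuple[int, int], rng: np.random.Generator
                 ) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[:rows, :cols]
    cy, cx = (rows - 1) / 2, (cols - 1) / 2
    theta = np.arctan2(rr - cy, cc - cx)
    wobble = np.zeros_like(theta)
    for k in range(2, 5):
        wobble += rng.uniform(0.0, 0.06) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    radius = 0.40 * min(rows, cols) * (1.0 + wobble)
    return np.hypot(rr - cy, cc - cx) < radius


def _grow_regions(blob: np.ndarray, K: int, rng: np.random.Generator
                  ) -> np.ndarray:
    """Voronoi-style growth from K seeds with smoothly distorted metrics,
    giving contiguous irregular regions covering the blob."""
    coords = np.argwhere(blob)
    if coords.shape[0] < 25 * K:
        raise ValidationError(
            f"blob of {coords.shape[0]} pixels too small for {K} regions")
    min_d = 0.45 * np.sqrt(coords.shape[0] / K)
    seeds: list[np.ndarray] = []
    for _ in range(2000):
        cand = coords[rng.integers(coords.shape[0])]
        if all(np.hypot(*(cand - s)) >= min_d for s in seeds):
            seeds.append(cand)
        if len(seeds) == K:
            break
    if len(seeds) < K:
        raise ValidationError(f"could not place {K} region seeds")
    rows, cols = blob.shape
    rr, cc = np.mgrid[:rows, :cols]
    cost = np.empty((K, rows, cols))
    for k, (sy, sx) in enumerate(seeds):
        distort = ndimage.gaussian_filter(rng.standard_normal(blob.shape), 6)
        distort *= 3.0 / max(np.abs(distort).max(), 1e-12)
        cost[k] = np.hypot(rr - sy, cc - sx) + distort
    labels = np.where(blob, cost.argmin(axis=0) + 1, 0)
    for k in range(1, K + 1):   # distortion must not erase a region
        if not np.any(labels == k):
            sy, sx = seeds[k - 1]
            labels[sy, sx] = k
    return labels


def _smooth_field(shape: tuple[int, int], magnitude: float,
                  rng: np.random.Generator, sigma: float = 8.0) -> np.ndarray:
    d = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
                  for _ in range(2)], axis=-1)
    mag = np.hypot(d[..., 0], d[..., 1]).max()
    if mag > 0 and magnitude > 0:
        d *= magnitude / mag
    else:
        d[:] = 0.0
    return d


# ---------------------------------------------------------------------------
# spectra and textures


def _region_signatures(n_regions: int, n_channels: int,
                       reserved: np.ndarray, rng: np.random.Generator
                       ) -> np.ndarray:
    """Gaussian-peak mixture per region over the free channels."""
    free = np.setdiff1d(np.arange(n_channels), reserved)
    ch = np.arange(n_channels)
    sigs = np.full((n_regions + 1, n_channels), 0.02)   # row 0: background
    for k in range(1, n_regions + 1):
        centers = rng.choice(free, size=8, replace=False)
        amps = rng.uniform(2.0, 10.0, size=8)
        widths = rng.uniform(0.8, 2.0, size=8)
        sigs[k] += sum(a * np.exp(-0.5 * ((ch - c) / w) ** 2)
                       for a, c, w in zip(amps, centers, widths))
    return sigs


_HE_PALETTES = np.array([
    [199, 110, 161], [120, 66, 146], [226, 151, 189], [158, 84, 110],
    [183, 126, 200], [140, 96, 170], [210, 120, 140], [170, 100, 190],
], dtype=float)


def _render_texture(labels: np.ndarray, tile: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Procedural H&E-like texture image, one pattern per region."""
    rows, cols = labels.shape
    big = np.repeat(np.repeat(labels, tile, 0), tile, 1)
    H, W = big.shape
    yy, xx = np.mgrid[:H, :W]
    img = np.full((H, W, 3), 244.0)
    K = labels.max()
    for k in range(1, K + 1):
        base = _HE_PALETTES[(k - 1) % len(_HE_PALETTES)]
        mode = (k - 1) % 4
        if mode == 0:      # stripes
            mod = 0.55 + 0.45 * (((xx + yy) // 3) % 2)
        elif mode == 1:    # dots
            mod = np.where((yy % 6 < 3) & (xx % 6 < 3), 0.5, 1.0)
        elif mode == 2:    # checker
            mod = 0.6 + 0.4 * (((xx // 4) + (yy // 4)) % 2)
        else:              # granular
            mod = 0.75 + 0.25 * np.cos(0.9 * xx) * np.cos(0.9 * yy)
        sel = big == k
        img[sel] = base * mod[sel, None]
    img += rng.normal(0, 4.0, img.shape)
    return np.clip(img.round(), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# generator


def generate_phantom(params: PhantomParams | None = None,
                     seed: int = 0) -> Phantom:
    """Draw one paired phantom; bit-identical under a fixed seed."""
    params = params or PhantomParams()
    if params.K_true < 2:
        raise ValidationError("K_true must be >= 2")
    rows, cols = params.grid_shape
    if rows < 30 or cols < 30:
        raise ValidationError("grid must be at least 30x30")
    rng = np.random.default_rng(seed)

    blob = _tissue_blob(params.grid_shape, rng)
    labels_hf = _grow_regions(blob, params.K_true, rng)

    # spurious MSI-only region: a disc inside the largest true region
    labels_src = labels_hf.copy()
    spurious_label = None
    if params.spurious_region:
        spurious_label = params.K_true + 1
        # host the MSI-only insert in the smallest region that can hold it;
        # the largest region is where extra legitimate structure lives
        disc_r = 0.06 * min(rows, cols)
        need = 4 * np.pi * disc_r ** 2
        sizes = np.array([np.sum(labels_hf == k)
                          for k in range(1, params.K_true + 1)])
        candidates = np.flatnonzero(sizes >= need)
        if candidates.size == 0:
            candidates = np.array([int(np.argmax(sizes))])
        host = int(candidates[np.argmin(sizes[candidates])]) + 1
        hy, hx = np.argwhere(labels_hf == host).mean(axis=0)
        rr, cc = np.mgrid[:rows, :cols]
        disc = (np.hypot(rr - hy, cc - hx) < disc_r) & (labels_hf == host)
        labels_src[disc] = spurious_label

    # deformation: msi(x) samples the source labeling at x + d(x)
    disp = _smooth_field(params.grid_shape, params.deformation_px, rng)
    disp[..., 0] += params.translation_px[0]
    disp[..., 1] += params.translation_px[1]
    rr, cc = np.mgrid[:rows, :cols].astype(float)
    labels_msi = ndimage.map_coordinates(
        labels_src, [rr + disp[..., 0], cc + disp[..., 1]],
        order=0, mode="constant", cval=0)

    n_regions = params.K_true + (1 if spurious_label else 0)

    # channel roles: markers reserved per region, noisy channels planted
    n_ch = params.n_channels_msi
    marker_channels = {k: n_ch - params.K_true + (k - 1)
                       for k in range(1, params.K_true + 1)}
    reserved = np.array(sorted(marker_channels.values()))
    noisy = rng.choice(np.setdiff1d(np.arange(n_ch - params.K_true),
                                    reserved),
                       size=params.n_noisy_channels, replace=False)
    noisy = np.sort(noisy)
    sigs = _region_signatures(n_regions, n_ch,
                              np.concatenate([reserved, noisy]), rng)

    # salt-and-pepper: mislabeled pixels on the MSI side
    fg_idx = np.argwhere(labels_msi > 0)
    n_sp = int(round(params.saltpepper_rate * fg_idx.shape[0]))
    sp_sel = rng.choice(fg_idx.shape[0], size=n_sp, replace=False)
    sp_pixels = fg_idx[sp_sel]
    labels_spectral = labels_msi.copy()
    for (r, c) in sp_pixels:
        old = labels_spectral[r, c]
        others = [k for k in range(1, n_regions + 1) if k != old]
        labels_spectral[r, c] = rng.choice(others)

    mean_sig = sigs[1:, :].mean()
    tic_factor = np.exp(rng.normal(0.0, params.tic_cv, (rows, cols)))
    spectra = sigs[labels_spectral] * tic_factor[..., None]
    fg_msi = labels_msi > 0
    spectra[fg_msi] += np.abs(rng.normal(
        0.0, params.msi_noise * mean_sig, spectra[fg_msi].shape))
    # noisy channels: stronger in the background than in the tissue
    bg = ~fg_msi
    spectra[bg] = 0.0
    for ch in noisy:
        spectra[bg, ch] = rng.uniform(2.0, 4.0, int(bg.sum())) * mean_sig / 3
        spectra[fg_msi, ch] = rng.uniform(0.0, 0.4, int(fg_msi.sum()))

    msi = MSICube(params.grid_shape, params.msi_pixel_um,
                  np.arange(200.0, 200.0 + n_ch),   # synthetic m/z axis, Da
                  spectra, fg_msi,
                  meta={"phantom_seed": seed, "frame": "msi",
                        "centroided": True})

    # HF side: prototypes + noise, clipped to [0, 1]
    protos = rng.uniform(0.15, 0.85, (params.K_true + 1, params.n_features_hf))
    protos[0] = 0.0
    feats = protos[labels_hf] + rng.normal(
        0.0, params.hf_noise, (rows, cols, params.n_features_hf))
    if params.hf_smooth > 0:
        # spatially coherent texture gradient inside one region: real
        # histology varies smoothly within an anatomical region, and at
        # K_true + 1 the histology clustering splits along such structure.
        # The textured region is the largest one away from any MSI-only
        # spurious insert, mirroring the situation where histology finds
        # extra structure elsewhere than the molecular artifact.
        sizes = np.array([np.sum(labels_hf == k)
                          for k in range(1, params.K_true + 1)])
        if spurious_label is not None:
            sizes[host - 1] = -1
        textured = int(np.argmax(sizes)) + 1
        g = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 8.0)
        g /= max(np.abs(g).max(), 1e-12)
        direction = rng.normal(0.0, 1.0, params.n_features_hf)
        direction /= np.linalg.norm(direction)
        sel = labels_hf == textured
        feats[sel] += params.hf_smooth * g[sel, None] * direction
    feats = np.clip(feats, 0.0, 1.0)
    feats[labels_hf == 0] = 0.0
    hf = HFCube(params.grid_shape, params.tile_size_px, feats, labels_hf > 0,
                provenance={"backend": "phantom-prototypes",
                            "phantom_seed": seed})

    he_image = _render_texture(labels_hf, params.tile_size_px, rng)

    truth = PhantomTruth(labels_hf, labels_msi, marker_channels,
                         noisy.tolist(), disp, sp_pixels, spurious_label,
                         seed, params)
    return Phantom(msi, hf, he_image, truth)


def inject_marker_ions(cube: MSICube, truth: PhantomTruth,
                       noise_sigma: float, seed: int = 0) -> MSICube:
    """Set each region's marker channel to its region indicator plus
    Gaussian noise of the stated sigma (clipped at zero)."""
    if len(set(truth.marker_channels.values())) != len(truth.marker_channels):
        raise ValidationError("marker channel collision")
    frame = cube.meta.get("frame", "msi")
    labels = truth.labels_msi if frame == "msi" else truth.labels_hf
    if labels.shape != cube.grid_shape:
        raise ValidationError("truth labels do not match the cube grid")
    rng = np.random.default_rng(seed)
    out = cube.copy()
    for region, ch in truth.marker_channels.items():
        img = (labels == region).astype(float)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        out.intensities[:, :, ch] = np.clip(img, 0.0, None)
    return out


def label_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of shared-foreground pixels with identical ground-truth
    labels; a registration-free yardstick for phantom experiments."""
    shared = (labels_a > 0) & (labels_b > 0)
    if not shared.any():
        return 0.0
    return float(np.mean(labels_a[shared] == labels_b[shared]))


def phantom_params_dict(params: PhantomParams) -> dict:
    return asdict(params)
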