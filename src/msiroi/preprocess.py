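"""Mass-spectral preprocessing and pixel/ion foreground logic.

The stage order is fixed: TIC normalization, spectral smoothing, baseline
reduction, peak picking, peak alignment, peak binning, peak filtering —
the standard protocol for DESI/MALDI raster data.  Foreground pixels are
found by thresholding the summed intensity of tissue-specific ions, and ion
channels that are brighter off-tissue than on-tissue are dropped as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .cubes import MSICube
from .errors import PreprocessingError, ThresholdingError, ValidationError

__all__ = ["PreprocessParams", "tic_normalize", "peak_pipeline",
           "msi_foreground", "drop_noisy_ions"]


@dataclass
class PreprocessParams:
    """Tunable knobs of :func:`peak_pipeline`.

    smoothing_window : Savitzky-Golay window length (odd, in samples).
    snr : minimum peak height as a multiple of the robust noise level.
    alignment_tol : maximum m/z distance (Da) merged into one consensus bin.
    min_pixel_freq : drop bins seen in fewer than this fraction of
        foreground pixels.
    centroided : skip smoothing/baseline/picking and treat every nonzero
        channel entry as an already-picked centroid.
    """

    smoothing_window: int = 9
    smoothing_polyorder: int = 3
    snr: float = 3.0
    alignment_tol: float = 0.05
    min_pixel_freq: float = 0.01
    centroided: bool = False


def tic_normalize(cube: MSICube) -> MSICube:
    """Scale every foreground pixel to the mean foreground total ion count.

    Keeping the dataset-mean TIC (rather than 1) as the target leaves
    intensities in acquisition-like units.  Zero-TIC foreground pixels are
    left unchanged and listed under ``meta['zero_tic_pixels']``.
    """
    tic = cube.intensities.sum(axis=2)
    fg = cube.foreground_mask
    fg_tic = tic[fg]
    if fg_tic.size == 0 or not np.any(fg_tic > 0):
        raise PreprocessingError("no foreground pixel with positive TIC")
    target = fg_tic[fg_tic > 0].mean()
    scale = np.ones_like(tic)
    nonzero = fg & (tic > 0)
    scale[nonzero] = target / tic[nonzero]
    out = cube.copy()
    out.intensities = cube.intensities * scale[:, :, None]
    zero = np.argwhere(fg & (tic == 0))
    out.meta = {**cube.meta, "tic_target": float(target),
                "zero_tic_pixels": [tuple(map(int, rc)) for rc in zero]}
    return out


def _robust_noise(x: np.ndarray) -> float:
    # scale of the first-difference process; insensitive to peaks and baseline
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2)) if mad > 0 else float(d.std() + 1e-12)


def _pick_peaks(spectrum: np.ndarray, mz: np.ndarray,
                params: PreprocessParams) -> tuple[np.ndarray, np.ndarray]:
    """Smooth, de-baseline and centroid one profile spectrum."""
    if np.all(spectrum == 0):
        return np.empty(0), np.empty(0)
    win = min(params.smoothing_window, len(spectrum) // 2 * 2 - 1)
    sm = signal.savgol_filter(spectrum, win, params.smoothing_polyorder) \
        if win > params.smoothing_polyorder else spectrum.copy()
    # grey-opening baseline: running minimum followed by running maximum
    base = ndimage.grey_opening(sm, size=max(win * 5, 25))
    clean = np.clip(sm - base, 0, None)
    noise = _robust_noise(spectrum)
    idx, _props = signal.find_peaks(clean, height=params.snr * noise)
    return mz[idx], clean[idx]


def peak_pipeline(cube: MSICube, params: PreprocessParams | None = None
                  ) -> MSICube:
    """Run smoothing → baseline → picking → alignment → binning → filtering.

    Returns a centroided cube whose m/z axis holds the consensus bins (the
    mean of the contributing per-pixel centroids).  Raises
    :class:`PreprocessingError` with per-stage diagnostics when nothing
    survives.
    """
    params = params or PreprocessParams()
    if params.alignment_tol <= 0:
        raise ValidationError("alignment_tol must be positive")
    rows, cols = cube.grid_shape
    fg = cube.foreground_mask

    all_mz: list[np.ndarray] = []
    all_int: list[np.ndarray] = []
    pix_idx: list[np.ndarray] = []
    n_fg = 0
    for p, (r, c) in enumerate(np.argwhere(fg)):
        n_fg += 1
        spec = cube.intensities[r, c]
        if params.centroided:
            nz = spec > 0
            mzs, ints = cube.mz_axis[nz], spec[nz]
        else:
            mzs, ints = _pick_peaks(spec, cube.mz_axis, params)
        all_mz.append(mzs)
        all_int.append(ints)
        pix_idx.append(np.full(mzs.size, p))

    mz_cat = np.concatenate(all_mz) if all_mz else np.empty(0)
    if mz_cat.size == 0:
        raise PreprocessingError(
            f"peak picking found no peaks in {n_fg} foreground pixels "
            f"(snr={params.snr})")
    int_cat = np.concatenate(all_int)
    pix_cat = np.concatenate(pix_idx).astype(int)

    # alignment: greedy 1-D clustering of pooled centroids by gap > tol
    order = np.argsort(mz_cat)
    mz_sorted = mz_cat[order]
    breaks = np.flatnonzero(np.diff(mz_sorted) > params.alignment_tol) + 1
    groups = np.zeros(mz_sorted.size, dtype=int)
    groups[breaks] = 1
    groups = np.cumsum(groups)
    bin_of = np.empty(mz_cat.size, dtype=int)
    bin_of[order] = groups
    n_bins = groups[-1] + 1
    centers = np.array([mz_cat[bin_of == b].mean() for b in range(n_bins)])

    # binning: per-pixel summed intensity per consensus bin
    fg_lin = np.argwhere(fg)
    binned = np.zeros((n_fg, n_bins))
    np.add.at(binned, (pix_cat, bin_of), int_cat)

    # filtering: bins below the pixel-frequency floor are dropped
    freq = (binned > 0).mean(axis=0)
    keep = freq >= params.min_pixel_freq
    if not np.any(keep):
        raise PreprocessingError(
            f"all {n_bins} bins fell below the pixel-frequency floor "
            f"{params.min_pixel_freq} (max observed {freq.max():.3f})")
    centers, binned = centers[keep], binned[:, keep]
    order = np.argsort(centers)
    centers, binned = centers[order], binned[:, order]

    out = np.zeros((rows, cols, centers.size))
    out[fg_lin[:, 0], fg_lin[:, 1]] = binned
    meta = {**cube.meta, "centroided": True,
            "peak_pipeline": {"n_bins_raw": int(n_bins),
                              "n_bins_kept": int(centers.size)}}
    return MSICube(cube.grid_shape, cube.pixel_size_um, centers, out,
                   cube.foreground_mask, meta)


def msi_foreground(cube: MSICube, tissue_ions: np.ndarray | list[float],
                   threshold: str | float = "otsu") -> np.ndarray:
    """Foreground mask from the summed intensity of tissue-specific ions.

    The mask is True where the per-pixel sum over ``tissue_ions`` exceeds
    the threshold; with ``"otsu"`` the threshold is computed on that sum
    image.
    """
    tissue_ions = np.asarray(tissue_ions, dtype=float).ravel()
    idx = []
    for mz in tissue_ions:
        j = int(np.argmin(np.abs(cube.mz_axis - mz)))
        if abs(cube.mz_axis[j] - mz) > 1e-6 + 1e-6 * mz:
            raise ValidationError(f"tissue ion {mz} not on the m/z axis")
        idx.append(j)
    total = cube.intensities[:, :, idx].sum(axis=2)
    if threshold == "otsu":
        if np.ptp(total) == 0:
            raise ThresholdingError(
                "sum image is constant; Otsu undefined — pass a manual "
                "threshold value")
        from skimage.filters import threshold_otsu
        threshold = float(threshold_otsu(total))
    return total > float(threshold)


def drop_noisy_ions(cube: MSICube) -> MSICube:
    """Remove channels whose mean background intensity exceeds the mean
    foreground intensity; such ions carry no tissue information."""
    fg = cube.foreground_mask
    if not fg.any() or fg.all():
        raise ValidationError("need both foreground and background pixels")
    flat = cube.intensities.reshape(-1, cube.n_channels)
    fg_mean = flat[fg.ravel()].mean(axis=0)
    bg_mean = flat[~fg.ravel()].mean(axis=0)
    keep = bg_mean <= fg_mean
    if not keep.any():
        raise PreprocessingError("every channel is background-dominated")
    out = MSICube(cube.grid_shape, cube.pixel_size_um, cube.mz_axis[keep],
                  cube.intensities[:, :, keep], cube.foreground_mask,
                  {**cube.meta,
                   "dropped_noisy_ions": cube.mz_axis[~keep].tolist()})
    return out
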