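"""Cross-modal spatial registration via NMF score maps.

The MSI and HF cubes are each reduced by nonnegative matrix factorization to
a handful of spatial "score maps".  One matched pair of maps (manually
chosen, or automatically by cross-modal correlation) drives an
intensity-based registration: an affine transform followed by a B-spline
free-form deformation, both optimized under a mutual-information metric.
The fitted transform is then applied to every ion channel of the MSI cube,
bringing it onto the HF grid.  Direction: MSI is the moving image, HF the
fixed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import SimpleITK as sitk
from skimage import transform as sktransform

from .cubes import HFCube, MSICube
from .errors import QCError, RegistrationError, SelectionError, ValidationError

__all__ = ["ScoreMap", "SpatialTransform", "RegistrationParams",
           "nmf_scoremaps", "select_pair", "register_maps", "warp_cube",
           "registration_qc"]


@dataclass
class ScoreMap:
    """Spatial weights of one NMF component on one modality's grid."""

    values: np.ndarray            # (rows, cols), >= 0
    component: int                # 1-based ordinal of the NMF component
    modality: str                 # "msi" | "hf"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValidationError("score map values must be non-negative")


@dataclass
class RegistrationParams:
    """Hyperparameters of the two-stage mutual-information registration."""

    mi_bins: int = 32
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    affine_iterations: int = 300
    bspline_control_spacing_px: float = 8.0
    bspline_iterations: int = 100


@dataclass
class SpatialTransform:
    """Fitted moving(MSI) -> fixed(HF) spatial mapping (affine then FFD)."""

    transform: sitk.Transform
    fixed_shape: tuple[int, int]
    moving_shape: tuple[int, int]
    metric_initial: float = np.nan
    metric_final: float = np.nan
    metric_trace: list[float] = field(default_factory=list)

    def displacement_field(self) -> np.ndarray:
        """Displacement (dy, dx) at every fixed-grid pixel, in pixels."""
        rows, cols = self.fixed_shape
        out = np.empty((rows, cols, 2))
        for r in range(rows):
            for c in range(cols):
                x, y = self.transform.TransformPoint((float(c), float(r)))
                out[r, c] = (y - r, x - c)
        return out

    def mean_displacement(self, mask: np.ndarray | None = None) -> float:
        disp = self.displacement_field()
        mag = np.hypot(disp[:, :, 0], disp[:, :, 1])
        return float(mag[mask].mean() if mask is not None else mag.mean())

    def save(self, path: str) -> None:
        sitk.WriteTransform(self.transform, str(path))


def nmf_scoremaps(cube: MSICube | HFCube, rank: int = 8,
                  seed: int = 0) -> list[ScoreMap]:
    """Reduce a cube to ``rank`` spatial score maps by NMF.

    Background pixels contribute all-zero rows and therefore receive zero
    scores.  Deterministic under a fixed seed (NNDSVD-A initialization).
    """
    from sklearn.decomposition import NMF

    if rank < 2:
        raise ValidationError("rank must be >= 2")
    X = cube.spectra(foreground_only=False)
    X = np.where(cube.foreground_mask.ravel()[:, None], X, 0.0)
    if np.any(X < 0):
        raise ValidationError("NMF requires non-negative values")
    if rank > min(X.shape):
        raise ValidationError(
            f"rank {rank} exceeds min(pixels, channels) = {min(X.shape)}")
    model = NMF(n_components=rank, init="nndsvda", random_state=seed,
                max_iter=500, tol=1e-5)
    W = model.fit_transform(X)
    modality = "msi" if isinstance(cube, MSICube) else "hf"
    rows, cols = cube.grid_shape
    return [ScoreMap(W[:, k].reshape(rows, cols), k + 1, modality)
            for k in range(rank)]


def select_pair(msi_maps: list[ScoreMap], hf_maps: list[ScoreMap],
                mode: str = "auto",
                manual_choice: tuple[int, int] | None = None,
                floor: float = 0.3,
                coarse_shape: tuple[int, int] = (32, 32)
                ) -> tuple[ScoreMap, ScoreMap]:
    """Pick the (fixed HF, moving MSI) score-map pair to register.

    Manual mode takes 1-based component ordinals ``(hf, msi)``.  Auto mode
    rescales every cross-modal pair to a common coarse grid and returns the
    pair with the largest absolute Pearson correlation, requiring it to
    exceed ``floor``.
    """
    if not msi_maps or not hf_maps:
        raise ValidationError("both score-map lists must be non-empty")
    if mode == "manual":
        if manual_choice is None:
            raise ValidationError("manual mode needs manual_choice=(hf, msi)")
        hf_i, msi_i = manual_choice
        hf_sel = next((m for m in hf_maps if m.component == hf_i), None)
        msi_sel = next((m for m in msi_maps if m.component == msi_i), None)
        if hf_sel is None or msi_sel is None:
            raise ValidationError(f"component pair {manual_choice} not found")
        return hf_sel, msi_sel
    if mode != "auto":
        raise ValidationError(f"unknown selection mode {mode!r}")

    def coarse(m: ScoreMap) -> np.ndarray:
        return sktransform.resize(m.values, coarse_shape, order=1,
                                  anti_aliasing=True).ravel()

    best, best_pair = -1.0, None
    for hf_m, msi_m in product(hf_maps, msi_maps):
        a, b = coarse(hf_m), coarse(msi_m)
        if a.std() == 0 or b.std() == 0:
            continue
        r = abs(float(np.corrcoef(a, b)[0, 1]))
        if r > best:
            best, best_pair = r, (hf_m, msi_m)
    if best_pair is None or best < floor:
        raise SelectionError(
            f"best cross-modal |r| = {best:.3f} < floor {floor}; choose the "
            "score-map pair manually")
    return best_pair


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise RegistrationError("score map is constant; cannot register")
    return ((img - lo) / (hi - lo)).astype(np.float64)


def register_maps(fixed: ScoreMap, moving: ScoreMap,
                  params: RegistrationParams | None = None,
                  seed: int = 0) -> SpatialTransform:
    """Two-stage (affine, then B-spline FFD) mutual-information registration.

    Both maps are min-max rescaled to [0, 1] first so they share an
    intensity range.  The affine result initializes the FFD stage.  Raises
    :class:`RegistrationError` with the metric trace if the optimizer ends
    worse than it started.
    """
    params = params or RegistrationParams()
    f_img = sitk.GetImageFromArray(_minmax(fixed.values))
    m_img = sitk.GetImageFromArray(_minmax(moving.values))
    trace: list[float] = []

    def _stage(initial, transform, iterations, optimizer):
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(
            numberOfHistogramBins=params.mi_bins)
        reg.SetMetricSamplingStrategy(reg.NONE)
        reg.SetInterpolator(sitk.sitkLinear)
        if optimizer == "affine":
            reg.SetOptimizerAsRegularStepGradientDescent(
                learningRate=2.0, minStep=1e-4,
                numberOfIterations=iterations, relaxationFactor=0.5,
                gradientMagnitudeTolerance=1e-8)
            reg.SetOptimizerScalesFromPhysicalShift()
        else:
            reg.SetOptimizerAsRegularStepGradientDescent(
                learningRate=1.0, minStep=1e-3,
                numberOfIterations=iterations, relaxationFactor=0.5,
                gradientMagnitudeTolerance=1e-6)
            reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(list(params.shrink_factors))
        reg.SetSmoothingSigmasPerLevel(list(params.smoothing_sigmas))
        reg.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)
        if initial is not None:
            reg.SetMovingInitialTransform(initial)
        reg.SetInitialTransform(transform, inPlace=True)
        reg.AddCommand(sitk.sitkIterationEvent,
                       lambda: trace.append(reg.GetMetricValue()))
        reg.Execute(f_img, m_img)
        return transform, reg.GetMetricValue()

    metric_initial = _evaluate_mi(f_img, m_img,
                                  sitk.Transform(2, sitk.sitkIdentity),
                                  params.mi_bins)

    # Degrees-of-freedom pyramid: bulk translation first (phase
    # cross-correlation — MI's capture range is too small for sparse
    # blob-like maps), then the full affine seeded with it, then the FFD.
    # MI can reward spurious warps once the histograms match, so every
    # stage must also not hurt the plain cross-correlation of the warped
    # maps or it is rolled back.
    from skimage.registration import phase_cross_correlation
    ncc_id = _warped_ncc(f_img, m_img,
                         sitk.Transform(2, sitk.sitkIdentity))
    pcshift, _err, _dp = phase_cross_correlation(
        sitk.GetArrayFromImage(f_img), sitk.GetArrayFromImage(m_img),
        upsample_factor=10, normalization=None)
    shift = sitk.TranslationTransform(2)
    ncc_shift = ncc_id
    for sgn in (-1.0, 1.0):   # resolve the sampling-direction convention
        cand = sitk.TranslationTransform(2)
        cand.SetOffset((sgn * float(pcshift[1]), sgn * float(pcshift[0])))
        ncc_cand = _warped_ncc(f_img, m_img, cand)
        if ncc_cand > ncc_shift + 1e-6:
            shift, ncc_shift = cand, ncc_cand

    affine = sitk.AffineTransform(2)
    affine.SetTranslation(shift.GetOffset())
    affine, _ = _stage(None, affine, params.affine_iterations, "affine")
    ncc_affine = _warped_ncc(f_img, m_img, affine)
    if ncc_affine < ncc_shift - 1e-6:
        affine = sitk.AffineTransform(2)
        affine.SetTranslation(shift.GetOffset())
        ncc_affine = ncc_shift

    mesh = [max(1, int(round(s / params.bspline_control_spacing_px)))
            for s in f_img.GetSize()]
    bspline = sitk.BSplineTransformInitializer(f_img, mesh, order=3)
    bspline, _ = _stage(affine, bspline, params.bspline_iterations,
                        "bspline")

    composite = sitk.CompositeTransform([affine, bspline])
    if _warped_ncc(f_img, m_img, composite) < ncc_affine - 1e-6:
        composite = sitk.CompositeTransform([affine])
    metric_final = _evaluate_mi(f_img, m_img, composite, params.mi_bins)
    if metric_final > metric_initial + 1e-4:   # Mattes MI: lower is better
        raise RegistrationError(
            f"registration diverged: metric {metric_initial:.4f} -> "
            f"{metric_final:.4f}; trace={trace[-5:]}")
    return SpatialTransform(composite,
                            fixed_shape=fixed.values.shape,
                            moving_shape=moving.values.shape,
                            metric_initial=metric_initial,
                            metric_final=metric_final,
                            metric_trace=trace)


def _warped_ncc(f_img: sitk.Image, m_img: sitk.Image,
                transform: sitk.Transform) -> float:
    warped = sitk.GetArrayFromImage(
        sitk.Resample(m_img, f_img, transform, sitk.sitkLinear, 0.0))
    fixed = sitk.GetArrayFromImage(f_img)
    a = fixed.ravel() - fixed.mean()
    b = warped.ravel() - warped.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else -1.0


def _evaluate_mi(f_img: sitk.Image, m_img: sitk.Image,
                 transform: sitk.Transform, bins: int) -> float:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(transform, inPlace=False)
    return float(reg.MetricEvaluate(f_img, m_img))


def warp_cube(cube: MSICube, transform: SpatialTransform,
              target_grid: tuple[int, int]) -> MSICube:
    """Resample every ion channel of the moving cube onto the fixed grid.

    Intensities use linear interpolation; the foreground mask uses nearest
    neighbour.  The m/z axis and channel count are unchanged.
    """
    if tuple(cube.grid_shape) != tuple(transform.moving_shape):
        raise ValidationError(
            f"cube grid {cube.grid_shape} does not match the transform's "
            f"moving domain {transform.moving_shape}")
    rows, cols = target_grid
    ref = sitk.Image(cols, rows, sitk.sitkFloat64)
    out = np.zeros((rows, cols, cube.n_channels))
    for ch in range(cube.n_channels):
        img = sitk.GetImageFromArray(cube.intensities[:, :, ch])
        res = sitk.Resample(img, ref, transform.transform, sitk.sitkLinear,
                            0.0, sitk.sitkFloat64)
        out[:, :, ch] = np.clip(sitk.GetArrayFromImage(res), 0, None)
    mimg = sitk.GetImageFromArray(cube.foreground_mask.astype(np.uint8))
    mres = sitk.Resample(mimg, sitk.Cast(ref, sitk.sitkUInt8),
                         transform.transform, sitk.sitkNearestNeighbor, 0)
    mask = sitk.GetArrayFromImage(mres).astype(bool)
    return MSICube(target_grid, cube.pixel_size_um, cube.mz_axis, out, mask,
                   {**cube.meta, "warped": True})


def registration_qc(hf_mask: np.ndarray, warped_msi_mask: np.ndarray
                    ) -> dict[str, float | np.ndarray]:
    """Dice/Jaccard overlap of the two tissue masks plus an overlay image."""
    hf_mask = np.asarray(hf_mask, dtype=bool)
    warped_msi_mask = np.asarray(warped_msi_mask, dtype=bool)
    if hf_mask.shape != warped_msi_mask.shape:
        raise ValidationError("masks must share one grid")
    if not hf_mask.any() or not warped_msi_mask.any():
        raise QCError("empty tissue mask")
    inter = np.logical_and(hf_mask, warped_msi_mask).sum()
    union = np.logical_or(hf_mask, warped_msi_mask).sum()
    dice = 2.0 * inter / (hf_mask.sum() + warped_msi_mask.sum())
    overlay = np.zeros((*hf_mask.shape, 3), dtype=np.uint8)
    overlay[hf_mask] = (0, 160, 0)
    overlay[warped_msi_mask] = (160, 0, 160)
    overlay[np.logical_and(hf_mask, warped_msi_mask)] = (220, 220, 0)
    return {"dice": float(dice), "jaccard": float(inter / union),
            "overlay": overlay}
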