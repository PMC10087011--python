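"""Cross-modal consistency scoring and cluster-number selection.

The central quantity is Cohen's kappa (CKS) between the MSI and histology
segmentations: kappa = (p_o - p_e) / (1 - p_e), where p_o is the observed
per-pixel agreement and p_e the agreement expected by chance from the two
labelings' marginal proportions.  Because cluster ids are arbitrary, kappa
is maximized over all label permutations of one input before comparison.
The number of clusters whose aligned kappa is largest is selected.

Two single-modality baselines are provided for comparison: a
Pearson-correlation (PC) criterion correlating Canny edges of the
segmentation map with edges of a nonlinear-embedding RGB rendering of the
spectra, and the Davies-Bouldin index (DBI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .cubes import HFCube, MSICube
from .errors import CriterionError, ValidationError
from .segmentation import Labeling, SegmentParams, prepare_features

__all__ = ["ContingencyTable", "ConsistencyCurve", "CriterionResult",
           "cohen_kappa", "align_labels", "cks_curve_select",
           "pc_criterion", "dbi_criterion"]

EXHAUSTIVE_K_MAX = 9


@dataclass
class ContingencyTable:
    """K x K pixel counts over the shared foreground, with kappa terms."""

    counts: np.ndarray
    p_o: float
    p_e: float
    kappa: float

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class ConsistencyCurve:
    """Aligned kappa per candidate K and the selected K*."""

    ks: list[int]
    kappas: list[float]
    permutations: list[tuple[int, ...]]
    shared_pixels: list[int]
    best_k: int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "K": self.ks, "kappa": self.kappas,
            "permutation": [" ".join(map(str, p)) for p in self.permutations],
            "shared_pixels": self.shared_pixels})


@dataclass
class CriterionResult:
    """Per-K values of one internal validity criterion."""

    name: str                      # "PC" | "DBI"
    ks: list[int]
    values: list[float]
    dispersion: list[float] | None
    best_k: int                    # argmax for PC, argmin for DBI


def _shared_labels(a: Labeling | np.ndarray, b: Labeling | np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel label vectors of the two inputs on their shared domain."""
    if isinstance(a, Labeling) and isinstance(b, Labeling):
        if a.foreground_mask.shape != b.foreground_mask.shape:
            raise ValidationError("labelings live on different grids")
        shared = a.foreground_mask & b.foreground_mask
        if not shared.any():
            raise ValidationError("no shared foreground pixel")
        return a.label_map()[shared], b.label_map()[shared]
    av = np.asarray(a, dtype=int).ravel()
    bv = np.asarray(b, dtype=int).ravel()
    if av.size != bv.size:
        raise ValidationError("label vectors differ in length")
    if av.size == 0:
        raise ValidationError("no shared foreground pixel")
    return av, bv


def _table(av: np.ndarray, bv: np.ndarray, K: int) -> np.ndarray:
    C = np.zeros((K, K))
    np.add.at(C, (av - 1, bv - 1), 1)
    return C


def _kappa_from_table(C: np.ndarray) -> tuple[float, float, float]:
    n = C.sum()
    p_o = float(np.trace(C) / n)
    row = C.sum(axis=1) / n
    col = C.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        warnings.warn("both labelings constant and equal; kappa defined as 1")
        return p_o, p_e, 1.0
    return p_o, p_e, (p_o - p_e) / (1.0 - p_e)


def cohen_kappa(a: Labeling | np.ndarray, b: Labeling | np.ndarray,
                K: int | None = None) -> tuple[float, ContingencyTable]:
    """Cohen's kappa between two labelings over their shared pixels.

    Accepts :class:`Labeling` objects (the shared domain is the intersection
    of the two foreground masks) or plain 1..K label vectors of equal
    length.  Chance agreement p_e is the product of the marginal label
    proportions.
    """
    av, bv = _shared_labels(a, b)
    if K is None:
        K = int(max(av.max(), bv.max()))
    C = _table(av, bv, K)
    p_o, p_e, kappa = _kappa_from_table(C)
    return kappa, ContingencyTable(C, p_o, p_e, kappa)


def align_labels(a: Labeling | np.ndarray, b: Labeling | np.ndarray
                 ) -> tuple[tuple[int, ...], float]:
    """Relabeling of ``b`` that maximizes kappa against ``a``.

    Since the chance term p_e depends on how the marginals are paired,
    kappa itself (not merely the observed agreement) is maximized: for
    K <= 9 exhaustively over all K! permutations, with ties broken by the
    lexicographically smallest permutation.  For larger K a
    Hungarian-initialized pairwise-swap search is used and a suboptimality
    warning issued.

    Returns ``(permutation, kappa)`` where ``permutation[i]`` is the new
    label given to b's label ``i + 1``.
    """
    Ka = a.K if isinstance(a, Labeling) else int(np.max(a))
    Kb = b.K if isinstance(b, Labeling) else int(np.max(b))
    if Ka != Kb:
        raise ValidationError(f"labelings have different K: {Ka} != {Kb}")
    K = Ka
    av, bv = _shared_labels(a, b)
    C = _table(av, bv, K)
    n = C.sum()
    row = C.sum(axis=1) / n          # marginals of a (fixed)
    col = C.sum(axis=0) / n          # marginals of b (permuted)

    if K <= EXHAUSTIVE_K_MAX:
        # kappa for permutation s (0-based, b-label j -> s[j]):
        #   p_o = sum_j C[s[j], j] / n ;  p_e = sum_j row[s[j]] * col[j]
        perms = np.array(list(permutations(range(K))), dtype=np.intp)
        j = np.arange(K)
        p_o = C[perms, j].sum(axis=1) / n
        p_e = (row[perms] * col).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            kappas = np.where(p_e >= 1.0 - 1e-15, 1.0,
                              (p_o - p_e) / (1.0 - p_e))
        best = int(np.argmax(kappas))   # first max = lexicographically least
        perm0 = perms[best]
        return tuple(int(v) + 1 for v in perm0), float(kappas[best])

    warnings.warn(f"K={K} > {EXHAUSTIVE_K_MAX}: falling back to "
                  "Hungarian-initialized local search; result may be "
                  "suboptimal")
    from scipy.optimize import linear_sum_assignment
    ri, ci = linear_sum_assignment(-C)   # maximize agreement as the seed
    perm = np.empty(K, dtype=int)
    perm[ci] = ri

    def kappa_of(p: np.ndarray) -> float:
        p_o = C[p, np.arange(K)].sum() / n
        p_e = float(row[p] @ col)
        return 1.0 if p_e >= 1.0 - 1e-15 else (p_o - p_e) / (1.0 - p_e)

    improved = True
    while improved:
        improved = False
        base = kappa_of(perm)
        for i in range(K):
            for j in range(i + 1, K):
                perm[i], perm[j] = perm[j], perm[i]
                if kappa_of(perm) > base + 1e-15:
                    improved = True
                    base = kappa_of(perm)
                else:
                    perm[i], perm[j] = perm[j], perm[i]
    return tuple(int(v) + 1 for v in perm), float(kappa_of(perm))


def cks_curve_select(msi_labelings: list[Labeling],
                     hf_labelings: list[Labeling]) -> ConsistencyCurve:
    """Aligned kappa per K over two matched sweeps; K* = argmax.

    Ties are resolved toward the smallest K (parsimony).
    """
    if not msi_labelings or not hf_labelings:
        raise ValidationError("empty sweep")
    ks_msi = [l.K for l in msi_labelings]
    ks_hf = [l.K for l in hf_labelings]
    if ks_msi != ks_hf:
        raise ValidationError(f"sweeps cover different K: {ks_msi} vs {ks_hf}")
    kappas, perms, shared = [], [], []
    for m, h in zip(msi_labelings, hf_labelings):
        perm, kappa = align_labels(m, h)
        kappas.append(kappa)
        perms.append(perm)
        if isinstance(m, Labeling):
            shared.append(int((m.foreground_mask & h.foreground_mask).sum()))
        else:
            shared.append(len(np.ravel(m)))
    best_k = ks_msi[int(np.argmax(kappas))]
    return ConsistencyCurve(ks_msi, kappas, perms, shared, best_k)


# ---------------------------------------------------------------------------
# Internal (single-modality) baselines


def _edge_image(rgb: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Union of per-channel Canny edges of an RGB float image."""
    from skimage.feature import canny
    edges = np.zeros(rgb.shape[:2], dtype=bool)
    for ch in range(rgb.shape[2]):
        chan = rgb[:, :, ch]
        if np.ptp(chan) > 0:
            edges |= canny(chan, sigma=sigma)
    return edges


def embedding_rgb(cube: MSICube | HFCube, seed: int = 0,
                  params: SegmentParams | None = None,
                  method: str = "umap") -> np.ndarray:
    """3-component nonlinear embedding of the spectra rendered as RGB.

    Each embedding component is min-max scaled to one color channel;
    background pixels are black.
    """
    X = prepare_features(cube, params)
    if method == "umap":
        import umap
        emb = umap.UMAP(n_components=3, random_state=seed).fit_transform(X)
    elif method == "pca":
        emb = X[:, :3]
    else:
        raise ValidationError(f"unknown embedding method {method!r}")
    rgb = np.zeros((*cube.grid_shape, 3))
    for ch in range(3):
        comp = emb[:, ch]
        span = np.ptp(comp)
        rgb[cube.foreground_mask, ch] = \
            (comp - comp.min()) / span if span > 0 else 0.0
    return rgb


def pc_criterion(cube: MSICube | HFCube, labelings: list[Labeling],
                 runs: int = 5, seed: int = 0,
                 params: SegmentParams | None = None,
                 embedding: np.ndarray | None = None,
                 embed_method: str = "umap") -> CriterionResult:
    """Edge-correlation criterion on randomly colored segmentation maps.

    A 3-component nonlinear embedding of the spectra is rendered as an RGB
    overview image; each segmentation map is rendered with region colors
    drawn at random per run.  The Pearson correlation between the two
    binary Canny edge images is averaged over ``runs`` and its standard
    deviation reported; the argmax K is the criterion's choice.
    """
    if not labelings:
        raise ValidationError("need at least one labeling")
    if embedding is None:
        embedding = embedding_rgb(cube, seed=seed, params=params,
                                  method=embed_method)
    ref_edges = _edge_image(embedding)
    if not ref_edges.any():
        raise CriterionError("embedding image has no edges")
    ref_flat = ref_edges.ravel().astype(float)
    rng = np.random.default_rng(seed)
    means, stds = [], []
    for lab in labelings:
        lmap = lab.label_map()
        rs = []
        for _ in range(runs):
            colors = rng.random((lab.K + 1, 3))
            colors[0] = 0.0
            seg_rgb = colors[lmap]
            seg_edges = _edge_image(seg_rgb)
            seg_flat = seg_edges.ravel().astype(float)
            if seg_flat.std() == 0 or ref_flat.std() == 0:
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(ref_flat, seg_flat)[0, 1]))
        means.append(float(np.mean(rs)))
        stds.append(float(np.std(rs)))
    ks = [l.K for l in labelings]
    return CriterionResult("PC", ks, means, stds, ks[int(np.argmax(means))])


def dbi_criterion(cube: MSICube | HFCube, labelings: list[Labeling],
                  params: SegmentParams | None = None,
                  features: np.ndarray | None = None) -> CriterionResult:
    """Davies-Bouldin index per K on the prepared feature vectors.

    Lower is better; the argmin K is the criterion's choice.  ``features``
    overrides the standard preparation (used to score raw coordinates).
    """
    from sklearn.metrics import davies_bouldin_score

    if not labelings:
        raise ValidationError("need at least one labeling")
    X = prepare_features(cube, params) if features is None else features
    values = []
    for lab in labelings:
        if np.unique(lab.labels).size < lab.K:
            raise CriterionError(f"K={lab.K}: a cluster is empty")
        values.append(float(davies_bouldin_score(X, lab.labels)))
    ks = [l.K for l in labelings]
    return CriterionResult("DBI", ks, values, None,
                           ks[int(np.argmin(values))])
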