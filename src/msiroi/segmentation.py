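"""Spectral clustering of foreground pixel spectra for either modality.

Pixel spectra (ion intensities or HF values) are standardized, reduced by
PCA, turned into a k-nearest-neighbour affinity graph, embedded with the
normalized graph Laplacian, and partitioned by k-means.  Cluster ids are
reassigned in decreasing order of cluster size so the output is invariant
to the arbitrary label permutation of k-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
from scipy.sparse.csgraph import connected_components

from .cubes import HFCube, MSICube
from .errors import ClusteringError, ValidationError

__all__ = ["Labeling", "SegmentParams", "prepare_features",
           "spectral_segment", "sweep_k"]


@dataclass
class SegmentParams:
    """Feature preparation and graph construction knobs.

    ``connect`` controls what happens when the k-NN affinity graph is
    disconnected (tight, well-separated clusters routinely produce this):
    ``"mst"`` bridges the components with the minimum-spanning-tree edges of
    the pairwise distances, ``"error"`` raises instead.
    """

    n_pca: int = 50          # cap on retained principal components
    n_neighbors: int = 15    # k of the affinity graph
    kmeans_restarts: int = 10
    connect: str = "mst"


@dataclass
class Labeling:
    """Cluster assignment of one modality's foreground pixels at one K."""

    labels: np.ndarray                 # (n_foreground,), ids in 1..K
    K: int
    modality: str
    seed: int
    foreground_mask: np.ndarray        # (rows, cols) bool
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if uniq.min() < 1 or uniq.max() > self.K:
            raise ValidationError(
                f"label ids {uniq.min()}..{uniq.max()} outside 1..{self.K}")
        if self.labels.size != int(self.foreground_mask.sum()):
            raise ValidationError(
                "one label per foreground pixel is required")

    def label_map(self) -> np.ndarray:
        """Dense (rows, cols) map; 0 marks background."""
        out = np.zeros(self.foreground_mask.shape, dtype=int)
        out[self.foreground_mask] = self.labels
        return out

    def to_frame(self):
        import pandas as pd
        rr, cc = np.nonzero(self.foreground_mask)
        return pd.DataFrame({"row": rr, "col": cc, "label": self.labels})


def prepare_features(cube: MSICube | HFCube,
                     params: SegmentParams | None = None) -> np.ndarray:
    """Standardize foreground spectra and reduce them by PCA.

    Shared by the K sweep and by the internal validity criteria so that all
    of them see the same feature space.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    params = params or SegmentParams()
    X = cube.spectra(foreground_only=True)
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 foreground pixels")
    X = StandardScaler().fit_transform(X)
    n_comp = min(params.n_pca, X.shape[1], X.shape[0] - 1)
    if n_comp < X.shape[1]:
        X = PCA(n_components=n_comp, random_state=0).fit_transform(X)
    return X


def _cluster_embedding(X: np.ndarray, K: int, seed: int,
                       params: SegmentParams) -> np.ndarray:
    from sklearn.cluster import KMeans
    from sklearn.manifold import spectral_embedding
    from sklearn.neighbors import kneighbors_graph

    k_nn = min(params.n_neighbors, X.shape[0] - 1)
    graph = kneighbors_graph(X, n_neighbors=k_nn, mode="connectivity",
                             include_self=False)
    affinity = 0.5 * (graph + graph.T)
    n_comp, _ = connected_components(affinity, directed=False)
    if n_comp > 1:
        if params.connect != "mst":
            raise ClusteringError(
                f"affinity graph has {n_comp} components; increase "
                f"n_neighbors (currently {k_nn})")
        # bridge the components with the MST edges of the full distance graph
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import squareform, pdist
        mst = minimum_spanning_tree(csr_matrix(squareform(pdist(X))))
        bridge = ((mst + mst.T) > 0).astype(affinity.dtype)
        # weak bridges: enough for connectivity, too light to drag the
        # bridged pixels' embedding coordinates across clusters
        affinity = affinity.maximum(bridge * 0.01)
    emb = spectral_embedding(affinity, n_components=K, random_state=seed,
                             drop_first=False)
    km = KMeans(n_clusters=K, n_init=params.kmeans_restarts,
                random_state=seed)
    return km.fit_predict(emb)


def _relabel_by_size(raw: np.ndarray, K: int) -> np.ndarray:
    """Map raw k-means ids to 1..K by decreasing cluster size (ties: by
    first raw id), removing the arbitrary permutation of k-means output."""
    sizes = np.bincount(raw, minlength=K)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(1, K + 1)
    return remap[raw]


def spectral_segment(cube: MSICube | HFCube, K: int, seed: int = 0,
                     params: SegmentParams | None = None,
                     features: np.ndarray | None = None) -> Labeling:
    """Cluster the cube's foreground pixels into K groups.

    ``features`` may pass in the output of :func:`prepare_features` to share
    preparation across a sweep.
    """
    params = params or SegmentParams()
    if K < 2:
        raise ValidationError("K must be >= 2")
    n_fg = int(cube.foreground_mask.sum())
    if K >= n_fg:
        raise ValidationError(f"K={K} must be < foreground count {n_fg}")
    X = prepare_features(cube, params) if features is None else features
    raw = _cluster_embedding(X, K, seed, params)
    labels = _relabel_by_size(raw, K)
    modality = "msi" if isinstance(cube, MSICube) else "hf"
    return Labeling(labels, K, modality, seed, cube.foreground_mask.copy(),
                    provenance={"n_pca": params.n_pca,
                                "n_neighbors": params.n_neighbors})


def sweep_k(cube: MSICube | HFCube, k_range: Iterable[int] = range(2, 9),
            seed: int = 0,
            params: SegmentParams | None = None) -> list[Labeling]:
    """One labeling per K over ``k_range`` with shared feature preparation."""
    params = params or SegmentParams()
    ks = list(k_range)
    if not ks:
        raise ValidationError("k_range is empty")
    X = prepare_features(cube, params)
    out = []
    for K in ks:
        try:
            out.append(spectral_segment(cube, K, seed, params, features=X))
        except (ValidationError, ClusteringError) as exc:
            raise type(exc)(f"K={K}: {exc}") from exc
    return out
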