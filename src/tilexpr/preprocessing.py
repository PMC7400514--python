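"""Gene filtering, log normalization, tissue-tile selection, tile
subsampling and supertile construction.

Supertiles cluster tiles by their slide location only (never by feature
content) and average the member features, reducing a slide to K x d.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .types import ExpressionMatrix, SuperTileBag, TileBag

__all__ = [
    "filter_genes_nonzero_median",
    "log_normalize",
    "select_tissue_tiles",
    "subsample_tiles",
    "make_supertiles",
    "mean_pool_bag",
]


class FeatureBackend:
    """Interface for turning slide pixel data into per-tile feature vectors.

    Real pipelines would plug a pretrained-CNN extractor in here; this
    package ships only the synthetic backend (bags generated directly in
    feature space), so the interface is declared but deliberately minimal.
    """

    feature_dim: int

    def extract(self, slide_pixels, tile_coords) -> "TileBag":
        raise NotImplementedError


def filter_genes_nonzero_median(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Keep exactly the genes whose median raw value across samples is > 0.

    The median is taken on raw (pre-log) values; column order is preserved.
    An empty result raises rather than returning silently.
    """
    medians = mat.raw.median(axis=0)
    keep = medians[medians > 0].index.tolist()
    if not keep:
        raise ValueError("no gene has nonzero median expression")
    return ExpressionMatrix(mat.raw.loc[:, keep])


def log_normalize(a):
    """log10(1 + a); rejects negative input."""
    arr = np.asarray(a, dtype=float)
    if (arr < 0).any():
        raise ValueError("log_normalize requires non-negative input")
    out = np.log10(1.0 + arr)
    return out if arr.shape else float(out)


def select_tissue_tiles(thumbnail: np.ndarray, background: str = "light"
                        ) -> np.ndarray:
    """Boolean tissue mask over a grayscale thumbnail grid.

    Otsu's threshold splits the intensity histogram; tiles falling on the
    background side are masked out.  ``background`` states which polarity is
    background ("light" for the usual white slide background).
    A constant image yields an all-foreground mask with a warning.
    """
    img = np.asarray(thumbnail, dtype=float)
    if background not in ("light", "dark"):
        raise ValueError("background must be 'light' or 'dark'")
    if np.unique(img).size < 2:
        warnings.warn("constant thumbnail: keeping every tile as foreground")
        return np.ones(img.shape, dtype=bool)
    thr = threshold_otsu(img)
    return img <= thr if background == "light" else img > thr


def subsample_tiles(bag: TileBag, max_tiles: int, seed: int) -> TileBag:
    """Uniform without-replacement subsample down to ``max_tiles`` tiles.

    Identity when the bag already fits; coords and features stay aligned.
    """
    if max_tiles < 1:
        raise ValueError("max_tiles must be >= 1")
    if bag.n_tiles <= max_tiles:
        return bag
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(bag.n_tiles, size=max_tiles, replace=False))
    return TileBag(bag.slide_id, bag.patient_id, bag.cohort,
                   bag.coords[idx], bag.features[idx])


def make_supertiles(bag: TileBag, n_clusters: int, seed: int) -> SuperTileBag:
    """Spatial k-means over tile coordinates with feature averaging.

    K = min(n_clusters, n_tiles).  The supertile feature is the unweighted
    mean of member-tile features; features never enter the clustering.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    k = min(n_clusters, bag.n_tiles)
    coords = np.asarray(bag.coords, dtype=float)
    if k == bag.n_tiles:
        assign = np.arange(bag.n_tiles)
    else:
        km = KMeans(n_clusters=k, n_init=10, max_iter=300, tol=1e-4,
                    random_state=seed)
        assign = km.fit_predict(coords)
        # k-means can return empty clusters only pathologically; relabel to
        # the occupied set so every cluster is nonempty
        occupied = np.unique(assign)
        if occupied.size < k:
            remap = {c: i for i, c in enumerate(occupied)}
            assign = np.array([remap[c] for c in assign])
            k = occupied.size
    feats = np.zeros((k, bag.feature_dim))
    sizes = np.bincount(assign, minlength=k)
    for j in range(k):
        feats[j] = bag.features[assign == j].mean(axis=0)
    return SuperTileBag(bag.slide_id, bag.patient_id, bag.cohort,
                        cluster_of_tile=assign, features=feats, sizes=sizes)


def mean_pool_bag(bag: TileBag) -> np.ndarray:
    """Column-wise mean of the bag's features (the one-supertile case)."""
    return bag.features.mean(axis=0)
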