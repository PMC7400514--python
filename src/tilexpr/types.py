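"""Core data containers shared across the pipeline.

A slide is represented as a bag of tiles: a grid-coordinate array plus a
feature matrix, one row per tile.  Expression is a samples x genes table of
non-negative values together with its log10(1 + a) view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TileBag:
    """One slide as a bag of tile feature vectors.

    coords are 0-based tile-grid indices (column, row), top-left origin,
    unique within a slide.  features is an ``n_tiles x d`` float matrix.
    """

    slide_id: str
    patient_id: str
    cohort: str
    coords: np.ndarray
    features: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (n_tiles x d)")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{self.features.shape[0]} tiles"
            )
        if self.n_tiles < 1:
            raise ValueError("a bag needs at least one tile")
        if not np.isfinite(self.features).all():
            raise ValueError(f"non-finite features in slide {self.slide_id}")
        uniq = {tuple(c) for c in self.coords.tolist()}
        if len(uniq) != self.n_tiles:
            raise ValueError(f"duplicate tile coords in slide {self.slide_id}")

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]


@dataclass
class SuperTileBag:
    """A slide reduced to K spatial clusters with averaged features."""

    slide_id: str
    patient_id: str
    cohort: str
    cluster_of_tile: np.ndarray  # n_tiles, cluster id of each original tile
    features: np.ndarray         # K x d within-cluster feature means
    sizes: np.ndarray            # K, tile count per cluster

    def __post_init__(self) -> None:
        self.cluster_of_tile = np.asarray(self.cluster_of_tile, dtype=np.int64)
        self.features = np.asarray(self.features, dtype=np.float64)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.features.shape[0] != self.sizes.shape[0]:
            raise ValueError("features and sizes disagree on cluster count")
        if (self.sizes < 1).any():
            raise ValueError("empty supertile cluster")
        if self.sizes.sum() != self.cluster_of_tile.shape[0]:
            raise ValueError("cluster sizes do not sum to n_tiles")

    @property
    def n_clusters(self) -> int:
        return self.features.shape[0]

    @property
    def n_tiles(self) -> int:
        return int(self.cluster_of_tile.shape[0])

    def as_bag(self) -> TileBag:
        """View the supertiles as a bag (cluster index used as coordinate)."""
        k = self.n_clusters
        coords = np.stack([np.arange(k), np.zeros(k, dtype=int)], axis=1)
        return TileBag(self.slide_id, self.patient_id, self.cohort,
                       coords, self.features)


class ExpressionMatrix:
    """Samples x genes matrix of non-negative expression values.

    Holds the raw values and exposes the log10(1 + a) view used for
    regression.  Backed by a pandas DataFrame (rows = samples).
    """

    def __init__(self, raw: pd.DataFrame):
        values = raw.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite expression values")
        if (values < 0).any():
            raise ValueError("expression values must be non-negative")
        self.raw = raw.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def n_samples(self) -> int:
        return self.raw.shape[0]

    @property
    def n_genes(self) -> int:
        return self.raw.shape[1]

    @property
    def log(self) -> pd.DataFrame:
        return np.log10(1.0 + self.raw)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.raw.loc[:, list(genes)])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.raw.loc[list(samples)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.raw.equals(other.raw)


@dataclass
class PredictionBundle:
    """Per-tile score matrix and its per-slide aggregation for one slide."""

    slide_id: str
    gene_ids: list[str]
    tile_scores: np.ndarray       # n_tiles x n_genes
    slide_prediction: np.ndarray  # n_genes
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tile_scores = np.asarray(self.tile_scores, dtype=np.float64)
        self.slide_prediction = np.asarray(self.slide_prediction, dtype=np.float64)
        if self.tile_scores.shape[1] != len(self.gene_ids):
            raise ValueError("tile_scores width inconsistent with gene list")
        if self.slide_prediction.shape != (len(self.gene_ids),):
            raise ValueError("slide_prediction length inconsistent with gene list")
        if not (np.isfinite(self.tile_scores).all()
                and np.isfinite(self.slide_prediction).all()):
            raise ValueError("non-finite predictions")


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic cohort (see synthetic module)."""

    tile_types: dict[str, np.ndarray]               # slide_id -> per-tile type id
    compositions: dict[str, np.ndarray]             # slide_id -> type fractions
    gene_links: dict[str, tuple[int, float]]        # signal gene -> (type, coef)
    label_logit_weights: np.ndarray                 # over tile types
    true_label: dict[str, int] = field(default_factory=dict)  # patient -> 0/1
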