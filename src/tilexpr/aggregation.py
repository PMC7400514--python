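"""Top-k aggregation of per-tile scores into per-slide predictions.

Training uses a stochastic top-k mean: at each optimizer step a single k is
drawn from a fixed list L, and for every gene the slide prediction is the
mean of that gene's k highest tile scores.  Inference averages the top-k
means over every k in L, which is equivalent to a fixed weighted mean of
the rank-ordered tile scores (see ``compute_tile_weights``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AggregationSpec",
    "SUPERTILE_L",
    "FULL_SCALE_L",
    "aggregate_train",
    "aggregate_train_with_indices",
    "aggregate_inference",
    "compute_tile_weights",
]

SUPERTILE_L = (1, 2, 5, 10, 20, 50, 100)
FULL_SCALE_L = (10, 20, 50, 100, 200, 500, 1000, 2000, 5000)


@dataclass
class AggregationSpec:
    """The list L of k values and the preprocessing mode it belongs to."""

    mode: str = "supertile"          # "supertile" or "full_scale"
    L: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mode not in ("supertile", "full_scale"):
            raise ValueError("mode must be 'supertile' or 'full_scale'")
        if self.L is None:
            self.L = SUPERTILE_L if self.mode == "supertile" else FULL_SCALE_L
        self.L = tuple(int(k) for k in self.L)
        if not self.L:
            raise ValueError("L must be nonempty")
        if any(k < 1 for k in self.L):
            raise ValueError("all k in L must be positive")
        if any(b <= a for a, b in zip(self.L, self.L[1:])):
            raise ValueError("L must be strictly increasing")


def _sorted_desc(tile_scores: np.ndarray) -> np.ndarray:
    # stable sort on negated scores = descending with ties broken by tile index
    return -np.sort(-tile_scores, axis=0, kind="stable")


def aggregate_train(tile_scores: np.ndarray, k: int) -> np.ndarray:
    """Per gene, the mean of the k highest tile scores (k capped at n_tiles)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = tile_scores.shape[0]
    k = min(k, n)
    return _sorted_desc(tile_scores)[:k].mean(axis=0)


def aggregate_train_with_indices(tile_scores: np.ndarray, k: int
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """As ``aggregate_train`` but also return the k x n_genes index matrix of
    selected tiles, for gradient routing during training."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = tile_scores.shape[0]
    k = min(k, n)
    order = np.argsort(-tile_scores, axis=0, kind="stable")
    idx = order[:k]
    top = np.take_along_axis(tile_scores, idx, axis=0)
    return top.mean(axis=0), idx


def aggregate_inference(tile_scores: np.ndarray,
                        agg: AggregationSpec) -> np.ndarray:
    """Mean over k in L of the top-k means; each k is capped at n_tiles."""
    n = tile_scores.shape[0]
    srt = _sorted_desc(tile_scores)
    csum = np.cumsum(srt, axis=0)
    ks = np.array([min(k, n) for k in agg.L])
    means = csum[ks - 1] / ks[:, None]
    return means.mean(axis=0)


def compute_tile_weights(n_tiles: int, L) -> np.ndarray:
    """Rank-weight profile of the inference aggregation.

    The weight of the rank-i tile (i = 1 the highest score) is
    ``(1/|L|) * sum over k in L with min(k, n) >= i of 1/min(k, n)``;
    the weights sum to 1 and are non-increasing in rank.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    L = tuple(L)
    if not L:
        raise ValueError("L must be nonempty")
    w = np.zeros(n_tiles)
    for k in L:
        kc = min(int(k), n_tiles)
        w[:kc] += 1.0 / kc
    return w / len(L)
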