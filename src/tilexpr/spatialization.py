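"""Virtual spatialization: per-tile score maps and their validation.

A score map averages the per-tile predicted log expression over a gene
set.  Validation metrics: tile-level Pearson correlation against counts,
rank-based AUCs at percentile thresholds, top-k tile summaries, and
per-slide tumor/healthy overlap AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .types import PredictionBundle

__all__ = [
    "TileScoreMap", "score_map", "tile_count_correlation",
    "tile_threshold_auc", "top_tiles_report", "region_overlap_auc",
    "render_heatmap", "read_heatmap_tsv",
]


@dataclass
class TileScoreMap:
    """Per-tile mean predicted log expression over a gene set."""

    slide_id: str
    genes: list[str]
    scores: np.ndarray  # n_tiles
    coords: np.ndarray  # n_tiles x 2

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.coords = np.asarray(self.coords)
        if self.scores.ndim != 1 or self.coords.shape != (self.scores.size, 2):
            raise ValueError("scores and coords shapes inconsistent")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite tile scores")


def score_map(bundle: PredictionBundle, genes: list[str]) -> TileScoreMap:
    """Mean of the per-tile score columns for the listed genes."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene subset")
    missing = [g for g in genes if g not in bundle.gene_ids]
    if missing:
        raise ValueError(f"genes not in bundle: {missing}")
    cols = [bundle.gene_ids.index(g) for g in genes]
    if bundle.coords is None:
        raise ValueError("bundle carries no tile coordinates")
    return TileScoreMap(bundle.slide_id, genes,
                        bundle.tile_scores[:, cols].mean(axis=1),
                        bundle.coords)


def tile_count_correlation(smap: TileScoreMap,
                           counts: np.ndarray) -> tuple[float, float]:
    """Pearson R over tiles and its two-tailed t-test p-value."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != smap.scores.shape:
        raise ValueError("counts not aligned with tiles")
    if counts.size < 3:
        raise ValueError("need at least 3 tiles")
    if np.std(counts) == 0 or np.std(smap.scores) == 0:
        raise ValueError("zero variance in scores or counts")
    r, p = stats.pearsonr(smap.scores, counts)
    return float(r), float(p)


def tile_threshold_auc(smap: TileScoreMap, counts: np.ndarray,
                       percentiles=(75, 90, 95, 99)) -> dict[float, float]:
    """AUC for detecting tiles whose count exceeds each percentile cutoff.

    Labels are ``count > percentile(counts, q)``; midrank tie handling.
    Degenerate labels (one class) are reported as NaN, never as 0.5.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != smap.scores.shape:
        raise ValueError("counts not aligned with tiles")
    out: dict[float, float] = {}
    for q in percentiles:
        thr = np.percentile(counts, q)
        labels = counts > thr
        if labels.all() or not labels.any():
            out[q] = np.nan
            continue
        out[q] = float(roc_auc_score(labels, smap.scores))
    return out


def top_tiles_report(smap: TileScoreMap, truth: np.ndarray,
                     k: int = 100) -> dict:
    """The k highest-scoring tiles, median truth among them vs overall."""
    truth = np.asarray(truth, dtype=float)
    if truth.shape != smap.scores.shape:
        raise ValueError("truth not aligned with tiles")
    if k > smap.scores.size:
        raise ValueError("k exceeds number of tiles")
    order = np.argsort(-smap.scores, kind="stable")
    top = order[:k]
    return {
        "top_indices": top,
        "median_top": float(np.median(truth[top])),
        "median_all": float(np.median(truth)),
        "n_tiles": int(smap.scores.size),
        "k": int(k),
    }


def region_overlap_auc(maps: dict[str, TileScoreMap],
                       region_flags: dict[str, np.ndarray]) -> dict:
    """Per-slide AUC for separating flagged (tumor) from unflagged tiles.

    Slides with a single class are excluded with a warning.  Also returns
    the slide-level aggregated score (mean tile score) for downstream
    slide classification.
    """
    per_slide = {}
    slide_scores = {}
    for slide_id, smap in maps.items():
        flags = np.asarray(region_flags[slide_id]).astype(bool)
        if flags.shape != smap.scores.shape:
            raise ValueError(f"flags not aligned for slide {slide_id}")
        slide_scores[slide_id] = float(smap.scores.mean())
        if flags.all() or not flags.any():
            warnings.warn(f"slide {slide_id} has a single region class; "
                          "excluded from the AUC summary")
            continue
        per_slide[slide_id] = float(roc_auc_score(flags, smap.scores))
    aucs = np.array(list(per_slide.values()))
    return {
        "per_slide": per_slide,
        "mean_auc": float(aucs.mean()) if aucs.size else np.nan,
        "median_auc": float(np.median(aucs)) if aucs.size else np.nan,
        "slide_scores": slide_scores,
    }


# --------------------------------------------------------------- rendering

def render_heatmap(smap: TileScoreMap, png_path, tsv_path,
                   block: int = 8) -> None:
    """Write the map as TSV (x, y, score) and a raster PNG.

    Each tile becomes one ``block x block`` pixel square, colored on a
    per-slide min-max normalized linear scale; empty grid cells are
    transparent.  Overlapping coordinates are rejected.
    """
    from PIL import Image
    from matplotlib import cm

    coords = np.asarray(smap.coords, dtype=int)
    if len({tuple(c) for c in coords.tolist()}) != coords.shape[0]:
        raise ValueError("overlapping tile coordinates")
    pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1],
                  "score": smap.scores}).to_csv(tsv_path, sep="\t",
                                                index=False)
    xs, ys = coords[:, 0], coords[:, 1]
    w, h = int(xs.max()) + 1, int(ys.max()) + 1
    lo, hi = smap.scores.min(), smap.scores.max()
    norm = (smap.scores - lo) / (hi - lo) if hi > lo \
        else np.ones_like(smap.scores)
    rgba = np.zeros((h, w, 4), dtype=np.uint8)
    colors = (np.asarray(cm.viridis(norm)) * 255).astype(np.uint8)
    rgba[ys, xs] = colors
    img = Image.fromarray(rgba, mode="RGBA").resize(
        (w * block, h * block), Image.NEAREST)
    img.save(png_path)


def read_heatmap_tsv(tsv_path, slide_id: str = "slide",
                     genes: list[str] | None = None) -> TileScoreMap:
    """Round-trip reader for the heatmap TSV."""
    df = pd.read_csv(tsv_path, sep="\t")
    return TileScoreMap(slide_id, genes or [],
                        df["score"].to_numpy(),
                        df[["x", "y"]].to_numpy())
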