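"""Synthetic cohort generator.

Produces desk-scale cohorts of slide bags, an expression matrix, tile-level
ground truth and per-patient binary labels with the statistical structure the
downstream stages assume:

* each tile carries a latent type drawn from a spatially smoothed random
  field, so tile types form coherent regions on the slide grid;
* tile features are orthogonal type prototypes plus isotropic noise, which
  keeps the signal linearly recoverable;
* each signal gene is tied to exactly one tile type and scales with the
  fraction of that type on the slide; noise genes are log-normal and
  independent of composition;
* the per-patient binary label is Bernoulli in the logistic of a linear
  functional of the patient's average tile-type composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .types import ExpressionMatrix, GroundTruth, TileBag

__all__ = ["SyntheticConfig", "generate_cohorts"]

CountOrRange = int | tuple[int, int]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator."""

    n_cohorts: int = 1
    patients_per_cohort: int = 20
    slides_per_patient: CountOrRange = 2
    tiles_per_slide: CountOrRange = (64, 100)
    feature_dim: int = 32
    n_tile_types: int = 4
    n_signal_genes: int = 5
    n_noise_genes: int = 50
    signal_strength: float = 100.0
    feature_noise_sd: float = 0.25
    expression_noise_sd: float = 0.1
    label_weights: np.ndarray | None = None
    field_smoothing: float = 2.0
    label_logit_scale: float = 8.0
    n_nuisance: int = 0
    nuisance_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "patients_per_cohort", "feature_dim",
                     "n_tile_types", "n_signal_genes", "n_noise_genes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.feature_dim < self.n_tile_types:
            raise ValueError("feature_dim must be >= n_tile_types "
                             "(orthogonal prototypes)")
        if self.feature_noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.signal_strength <= 0:
            raise ValueError("signal_strength must be positive")
        for name in ("slides_per_patient", "tiles_per_slide"):
            v = getattr(self, name)
            if isinstance(v, (tuple, list)):
                v = tuple(int(x) for x in v)
                if len(v) != 2 or v[0] > v[1]:
                    raise ValueError(f"{name} range must be (lo, hi)")
                setattr(self, name, v)
            else:
                v = (int(v),)
            if v[0] < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_nuisance < 0 or self.nuisance_sd < 0:
            raise ValueError("nuisance settings must be >= 0")
        if self.label_weights is not None:
            w = np.asarray(self.label_weights, dtype=float)
            if w.shape != (self.n_tile_types,):
                raise ValueError("label_weights must have one entry per tile type")
            self.label_weights = w

    def validate_for_folds(self, n_folds: int) -> None:
        if self.patients_per_cohort < n_folds:
            raise ValueError(
                f"each cohort has {self.patients_per_cohort} patients, fewer "
                f"than the {n_folds} requested CV folds")


def _draw_count(rng: np.random.Generator, v: CountOrRange) -> int:
    if isinstance(v, tuple):
        return int(rng.integers(v[0], v[1] + 1))
    return int(v)


def _grid_shape(n_tiles: int) -> tuple[int, int]:
    h = int(np.ceil(np.sqrt(n_tiles)))
    w = int(np.ceil(n_tiles / h))
    return h, w


def _smoothed_type_field(rng: np.random.Generator, shape: tuple[int, int],
                         n_types: int, bias: np.ndarray,
                         smoothing: float) -> np.ndarray:
    """Per-pixel tile type = argmax over smoothed per-type Gaussian fields."""
    fields = rng.standard_normal((n_types,) + shape)
    if smoothing > 0:
        fields = np.stack([gaussian_filter(f, smoothing) for f in fields])
        # restore unit scale lost to smoothing so the bias stays comparable
        sd = fields.std(axis=(1, 2), keepdims=True)
        sd[sd == 0] = 1.0
        fields = fields / sd
    fields = fields + bias[:, None, None]
    return np.argmax(fields, axis=0)


def generate_cohorts(
    cfg: SyntheticConfig,
) -> tuple[list[TileBag], ExpressionMatrix, GroundTruth, pd.DataFrame]:
    """Generate bags, expression, ground truth and patient labels.

    Returns ``(bags, expression, truth, labels)`` where ``labels`` is a
    DataFrame with columns (patient_id, cohort, label) and ``expression``
    has one row per slide (sample = slide).  Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_types = cfg.n_tile_types

    # orthogonal unit prototypes: scaled standard-basis rows
    prototypes = np.eye(n_types, cfg.feature_dim)

    # slide-level nuisance factors: high-variance feature directions shared
    # by all tiles of a slide, independent of composition and label (stand-in
    # for expression-irrelevant technical variation between slides)
    # separate stream so enabling nuisance leaves all other draws unchanged
    rng_nui = np.random.default_rng(cfg.seed + 977)
    if cfg.n_nuisance > 0 and cfg.nuisance_sd > 0:
        nuisance_dirs = rng_nui.standard_normal(
            (cfg.n_nuisance, cfg.feature_dim))
        nuisance_dirs /= np.linalg.norm(nuisance_dirs, axis=1, keepdims=True)
    else:
        nuisance_dirs = None

    # gene -> (type, coefficient) links, types assigned round-robin
    gene_links: dict[str, tuple[int, float]] = {}
    signal_genes = [f"SIG{i:03d}" for i in range(cfg.n_signal_genes)]
    noise_genes = [f"NSE{i:03d}" for i in range(cfg.n_noise_genes)]
    for i, g in enumerate(signal_genes):
        coef = float(rng.uniform(0.5, 1.5))
        gene_links[g] = (i % n_types, coef)

    if cfg.label_weights is not None:
        label_w = cfg.label_weights
    else:
        label_w = rng.standard_normal(n_types)
        label_w = label_w - label_w.mean()

    bags: list[TileBag] = []
    tile_types: dict[str, np.ndarray] = {}
    compositions: dict[str, np.ndarray] = {}
    expr_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    manifest_rows: list[dict] = []
    patient_comps: dict[str, list[np.ndarray]] = {}
    patient_cohort: dict[str, str] = {}

    for c in range(cfg.n_cohorts):
        cohort = f"cohort{c}"
        for p in range(cfg.patients_per_cohort):
            patient = f"{cohort}_P{p:03d}"
            patient_cohort[patient] = cohort
            n_slides = _draw_count(rng, cfg.slides_per_patient)
            # patient-level composition bias shared by the patient's slides
            patient_bias = rng.normal(0.0, 1.0, size=n_types)
            for s in range(n_slides):
                slide = f"{patient}_S{s}"
                n_tiles = _draw_count(rng, cfg.tiles_per_slide)
                h, w = _grid_shape(n_tiles)
                type_grid = _smoothed_type_field(
                    rng, (h, w), n_types, patient_bias, cfg.field_smoothing)
                ys, xs = np.divmod(np.arange(n_tiles), w)
                coords = np.stack([xs, ys], axis=1)
                ttypes = type_grid[ys, xs]

                comp = np.bincount(ttypes, minlength=n_types) / n_tiles
                feats = prototypes[ttypes]
                if cfg.feature_noise_sd > 0:
                    feats = feats + rng.normal(
                        0.0, cfg.feature_noise_sd, size=feats.shape)
                if nuisance_dirs is not None:
                    z = rng_nui.normal(0.0, cfg.nuisance_sd,
                                       size=cfg.n_nuisance)
                    feats = feats + z @ nuisance_dirs

                bag = TileBag(slide, patient, cohort, coords, feats)
                bags.append(bag)
                tile_types[slide] = ttypes
                compositions[slide] = comp
                patient_comps.setdefault(patient, []).append(comp)

                row = np.empty(cfg.n_signal_genes + cfg.n_noise_genes)
                for i, g in enumerate(signal_genes):
                    t, coef = gene_links[g]
                    eps = rng.normal(0.0, cfg.expression_noise_sd)
                    row[i] = cfg.signal_strength * coef * comp[t] * np.exp(eps)
                row[cfg.n_signal_genes:] = np.exp(
                    rng.normal(np.log(cfg.signal_strength / 4.0), 1.0,
                               size=cfg.n_noise_genes))
                expr_rows.append(row)
                sample_ids.append(slide)
                manifest_rows.append(
                    {"slide_id": slide, "patient_id": patient, "cohort": cohort})

    expression = ExpressionMatrix(pd.DataFrame(
        np.asarray(expr_rows), index=sample_ids,
        columns=signal_genes + noise_genes))

    true_label: dict[str, int] = {}
    label_rows = []
    for patient, comps in patient_comps.items():
        mean_comp = np.mean(comps, axis=0)
        centered = mean_comp - 1.0 / n_types
        logit = cfg.label_logit_scale * float(label_w @ centered)
        prob = 1.0 / (1.0 + np.exp(-logit))
        lab = int(rng.random() < prob)
        true_label[patient] = lab
        label_rows.append({"patient_id": patient,
                           "cohort": patient_cohort[patient], "label": lab})
    labels = pd.DataFrame(label_rows)

    if labels["label"].nunique() < 2 and len(labels) > 1:
        warnings.warn("synthetic labels are single-class; downstream "
                      "classification tasks will be degenerate")

    truth = GroundTruth(tile_types=tile_types, compositions=compositions,
                        gene_links=gene_links, label_logit_weights=label_w,
                        true_label=true_label)
    return bags, expression, truth, labels


def manifest_from_bags(bags: list[TileBag]) -> pd.DataFrame:
    """Slide manifest table (slide_id, patient_id, cohort)."""
    return pd.DataFrame(
        [{"slide_id": b.slide_id, "patient_id": b.patient_id,
          "cohort": b.cohort} for b in bags])
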