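"""Multi-task expression regression from tile bags.

A single MLP is applied to every tile of a slide (weight sharing across
tiles), producing one score per gene and per tile.  Training aggregates the
tile scores into a slide prediction with a stochastic top-k mean (one k
drawn per optimizer step from the list L) and minimizes mean squared error
on log expression.  Inference averages the top-k means over all k in L.

Supports a coarse phase on supertile bags followed by fine-tuning on
full-scale bags, patient-grouped cross-validation, and early stopping on a
per-cohort mean of per-gene validation correlations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import (AggregationSpec, aggregate_inference,
                          aggregate_train_with_indices)
from .nn import MLP, Adam, build_mlp
from .preprocessing import filter_genes_nonzero_median
from .types import ExpressionMatrix, PredictionBundle, SuperTileBag, TileBag

__all__ = [
    "ModelSpec", "TrainConfig", "RegressionModel",
    "forward_tiles", "train_model", "finetune_full_scale",
    "predict_slide", "cross_validate", "save_model", "load_model",
]


@dataclass
class ModelSpec:
    """Architecture of the per-tile regression MLP."""

    input_dim: int
    n_genes: int
    hidden: tuple[int, ...] = (1024, 256)
    dropout: float = 0.25
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.hidden = tuple(int(h) for h in self.hidden)
        if self.input_dim < 1 or self.n_genes < 1:
            raise ValueError("input_dim and n_genes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    """Optimization settings (Adam, MSE on log expression)."""

    learning_rate: float = 3e-4
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 50
    val_fraction: float = 0.10
    metric_order: str = "cohort_then_gene"  # or "gene_then_cohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience >= self.max_epochs and self.max_epochs > 0:
            warnings.warn("patience >= max_epochs: early stopping inactive")
        if self.metric_order not in ("cohort_then_gene", "gene_then_cohort"):
            raise ValueError("unknown metric_order")


class RegressionModel:
    """A trained (or freshly initialized) per-tile regression model."""

    def __init__(self, spec: ModelSpec, agg: AggregationSpec, seed: int = 0):
        self.spec = spec
        self.agg = agg
        self._rng = np.random.default_rng(seed)
        self.mlp: MLP = build_mlp(
            spec.input_dim, spec.hidden, spec.n_genes, self._rng,
            activation=spec.activation, dropout=spec.dropout)
        self.gene_ids: list[str] | None = None
        self.history: dict = {}

    def tile_scores(self, features: np.ndarray, train: bool = False
                    ) -> np.ndarray:
        if features.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"feature width {features.shape[1]} does not match model "
                f"input width {self.spec.input_dim}")
        return self.mlp.forward(features, train=train)


def forward_tiles(features: np.ndarray, model: RegressionModel) -> np.ndarray:
    """Apply the shared MLP to every tile row (inference mode)."""
    return model.tile_scores(np.asarray(features, dtype=float), train=False)


def predict_slide(bag: TileBag | SuperTileBag,
                  model: RegressionModel) -> PredictionBundle:
    """Per-tile scores plus the deterministic multi-k slide aggregation."""
    if isinstance(bag, SuperTileBag):
        bag = bag.as_bag()
    scores = forward_tiles(bag.features, model)
    pred = aggregate_inference(scores, model.agg)
    genes = model.gene_ids or [f"g{j}" for j in range(model.spec.n_genes)]
    return PredictionBundle(slide_id=bag.slide_id, gene_ids=list(genes),
                            tile_scores=scores, slide_prediction=pred,
                            coords=np.asarray(bag.coords))


# ------------------------------------------------------------------ train

def _as_bags(bags) -> list[TileBag]:
    return [b.as_bag() if isinstance(b, SuperTileBag) else b for b in bags]


def _targets(expression: ExpressionMatrix, bags: list[TileBag],
             genes: list[str]) -> np.ndarray:
    logv = expression.log
    missing = [b.slide_id for b in bags if b.slide_id not in logv.index]
    if missing:
        raise ValueError(f"no expression row for slides: {missing[:5]}")
    return logv.loc[[b.slide_id for b in bags], genes].to_numpy()


def _val_metric(model: RegressionModel, bags: list[TileBag], y: np.ndarray,
                order: str) -> float:
    """Mean per-gene Pearson R on a validation split, combined per cohort."""
    cohorts = np.array([b.cohort for b in bags])
    preds = np.stack([aggregate_inference(
        forward_tiles(b.features, model), model.agg) for b in bags])
    per_cohort = []
    for cohort in np.unique(cohorts):
        m = cohorts == cohort
        if m.sum() < 2:
            warnings.warn(f"cohort {cohort} has <2 validation samples; "
                          "excluded from the early-stopping metric")
            continue
        p, t = preds[m], y[m]
        with np.errstate(invalid="ignore", divide="ignore"):
            pc = p - p.mean(axis=0)
            tc = t - t.mean(axis=0)
            denom = np.sqrt((pc ** 2).sum(axis=0) * (tc ** 2).sum(axis=0))
            r = np.where(denom > 0, (pc * tc).sum(axis=0) / denom, np.nan)
        per_cohort.append(r)
    if not per_cohort:
        return np.nan
    rmat = np.stack(per_cohort)  # cohorts x genes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if order == "cohort_then_gene":
            return float(np.nanmean(np.nanmean(rmat, axis=1)))
        return float(np.nanmean(np.nanmean(rmat, axis=0)))


def _fit(model: RegressionModel, bags: list[TileBag], y: np.ndarray,
         cfg: TrainConfig, max_epochs: int, rng: np.random.Generator) -> dict:
    """Optimize in place; returns the training history."""
    n = len(bags)
    n_genes = y.shape[1]
    L = model.agg.L

    # patient-grouped 10% validation carve-out
    patients = np.array([b.patient_id for b in bags])
    uniq = np.unique(patients)
    rng_split = np.random.default_rng(cfg.seed + 1)
    perm = rng_split.permutation(uniq)
    n_val_pat = max(1, int(round(cfg.val_fraction * len(uniq)))) \
        if len(uniq) > 1 else 0
    val_pat = set(perm[:n_val_pat])
    val_idx = np.array([i for i in range(n) if patients[i] in val_pat])
    tr_idx = np.array([i for i in range(n) if patients[i] not in val_pat])
    if tr_idx.size == 0:
        raise ValueError("validation carve-out left no training slides")

    opt = Adam(model.mlp.params, lr=cfg.learning_rate)
    best_metric = -np.inf
    best_weights = model.mlp.get_weights()
    since_best = 0
    history: dict = {"train_loss": [], "val_metric": []}

    for epoch in range(max_epochs):
        order = rng.permutation(tr_idx)
        epoch_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            k = int(L[rng.integers(len(L))])  # one k per optimizer step
            model.mlp.zero_grads()
            for i in batch:
                X = bags[i].features
                scores = model.mlp.forward(X, train=True)
                S, idx = aggregate_train_with_indices(scores, k)
                err = S - y[i]
                epoch_loss += float((err ** 2).mean())
                dS = 2.0 * err / (n_genes * batch.size)
                dscores = np.zeros_like(scores)
                np.put_along_axis(
                    dscores, idx,
                    np.broadcast_to(dS / idx.shape[0], idx.shape), axis=0)
                model.mlp.backward(dscores)
            opt.step(model.mlp.grads)
        epoch_loss /= max(1, tr_idx.size)
        if not np.isfinite(epoch_loss):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch} "
                f"(lr={cfg.learning_rate}, batch={cfg.batch_size})")

        if val_idx.size >= 1:
            metric = _val_metric(model, [bags[i] for i in val_idx],
                                 y[val_idx], cfg.metric_order)
        else:
            metric = -epoch_loss
        if np.isnan(metric):
            metric = -epoch_loss
        history["train_loss"].append(epoch_loss)
        history["val_metric"].append(metric)

        if metric > best_metric:
            best_metric = metric
            best_weights = model.mlp.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    model.mlp.set_weights(best_weights)
    history["best_metric"] = best_metric
    history["n_epochs"] = len(history["train_loss"])
    return history


def train_model(bags, expression: ExpressionMatrix, spec: ModelSpec,
                agg: AggregationSpec, cfg: TrainConfig,
                genes: list[str] | None = None) -> RegressionModel:
    """Train from scratch on the given bags (supertile or full-scale)."""
    bags = _as_bags(bags)
    genes = list(genes) if genes is not None else expression.gene_ids
    if spec.n_genes != len(genes):
        spec = ModelSpec(spec.input_dim, len(genes), spec.hidden,
                         spec.dropout, spec.activation)
    y = _targets(expression, bags, genes)
    model = RegressionModel(spec, agg, seed=cfg.seed)
    model.gene_ids = genes
    rng = np.random.default_rng(cfg.seed + 2)
    model.history = _fit(model, bags, y, cfg, cfg.max_epochs, rng)
    return model


def finetune_full_scale(model: RegressionModel, full_bags,
                        expression: ExpressionMatrix, cfg: TrainConfig,
                        epochs: int = 100,
                        agg: AggregationSpec | None = None) -> RegressionModel:
    """Resume optimization on full-scale (per-tile) bags.

    Switches the aggregation list to the full-scale L (unless one is
    given); ``epochs == 0`` leaves the weights unchanged.
    """
    full_bags = _as_bags(full_bags)
    if full_bags and full_bags[0].feature_dim != model.spec.input_dim:
        raise ValueError(
            f"feature width {full_bags[0].feature_dim} does not match the "
            f"pretrained input width {model.spec.input_dim}")
    model.agg = agg if agg is not None else AggregationSpec(mode="full_scale")
    if epochs == 0:
        return model
    y = _targets(expression, full_bags, model.gene_ids)
    rng = np.random.default_rng(cfg.seed + 3)
    hist = _fit(model, full_bags, y, cfg, epochs, rng)
    model.history = {"coarse": model.history, "fine": hist}
    return model


# --------------------------------------------------------- cross-validation

def cross_validate(bags, expression: ExpressionMatrix, spec: ModelSpec,
                   agg: AggregationSpec, cfg: TrainConfig,
                   fold_of_patient: dict[str, int],
                   filter_genes: bool = True
                   ) -> tuple[pd.DataFrame, pd.Series, list[RegressionModel]]:
    """Patient-grouped CV: train on the complement of each fold, predict the
    held-out fold.

    Gene filtering (nonzero median) is fit on the training folds only and
    the retained list applied to the held-out fold.  Returns the held-out
    prediction table (slides x genes, NaN where a gene was filtered out in
    that fold), the fold id per slide, and the per-fold models.
    """
    bags = _as_bags(bags)
    folds = sorted(set(fold_of_patient.values()))
    for b in bags:
        if b.patient_id not in fold_of_patient:
            raise ValueError(f"patient {b.patient_id} has no fold assignment")
    pred = pd.DataFrame(np.nan, index=[b.slide_id for b in bags],
                        columns=expression.gene_ids, dtype=float)
    fold_of_slide = pd.Series(
        {b.slide_id: fold_of_patient[b.patient_id] for b in bags})
    models = []
    for f in folds:
        tr = [b for b in bags if fold_of_patient[b.patient_id] != f]
        te = [b for b in bags if fold_of_patient[b.patient_id] == f]
        if not tr or not te:
            warnings.warn(f"fold {f} empty on one side; skipped")
            continue
        tr_expr = expression.subset_samples([b.slide_id for b in tr])
        genes = (filter_genes_nonzero_median(tr_expr).gene_ids
                 if filter_genes else tr_expr.gene_ids)
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + 101 * f})
        m = train_model(tr, tr_expr, spec, agg, fold_cfg, genes=genes)
        models.append(m)
        for b in te:
            bundle = predict_slide(b, m)
            pred.loc[b.slide_id, bundle.gene_ids] = bundle.slide_prediction
    return pred, fold_of_slide, models


# ------------------------------------------------------------- checkpoints

def save_model(model: RegressionModel, path: str | Path) -> None:
    """Single-file checkpoint: JSON manifest plus weight arrays."""
    manifest = {
        "model_spec": asdict(model.spec),
        "aggregation": {"mode": model.agg.mode, "L": list(model.agg.L)},
        "gene_ids": model.gene_ids,
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.mlp.get_weights())}
    np.savez(path, manifest=np.bytes_(json.dumps(manifest)), **arrays)


def load_model(path: str | Path) -> RegressionModel:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        n = len([k for k in data.files if k.startswith("w")])
        weights = [data[f"w{i}"] for i in range(n)]
    ms = manifest["model_spec"]
    spec = ModelSpec(ms["input_dim"], ms["n_genes"], tuple(ms["hidden"]),
                     ms["dropout"], ms["activation"])
    agg = AggregationSpec(mode=manifest["aggregation"]["mode"],
                          L=tuple(manifest["aggregation"]["L"]))
    model = RegressionModel(spec, agg)
    model.mlp.set_weights(weights)
    model.gene_ids = manifest["gene_ids"]
    return model
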