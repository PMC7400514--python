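"""Two-hospital transfer experiment.

Hospital A trains a mean-pooled expression regressor whose 256-unit
penultimate layer is the "transcriptomic representation"; hospital B trains
small binary classifiers on either the raw pooled features, that
representation, or autoencoder bottlenecks (baselines).  A bootstrap split
harness sweeps the A/B patient ratio and collects patient-level AUCs.

Information firewall: hospital-A routines never see labels; hospital-B
routines never see hospital-A expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .nn import MLP, Adam, Dense, ReLU, Sigmoid
from .types import ExpressionMatrix

__all__ = [
    "TransferExperimentConfig", "RepresentationModel", "train_representation",
    "train_classifier_raw", "train_classifier_repr",
    "train_autoencoder_baseline", "hospital_split_harness",
    "compare_auc_distributions",
]


@dataclass
class TransferExperimentConfig:
    b_fractions: tuple[float, ...] = (0.25,)
    n_bootstrap: int = 50
    n_folds: int = 3
    n_cv_repeats: int = 10
    epochs: int = 50
    learning_rate: float = 3e-4
    clf_epochs: int | None = None        # fall back to epochs
    clf_learning_rate: float | None = None  # fall back to learning_rate
    weight_decay: float = 0.0            # decoupled L2, all transfer models
    repr_hidden: tuple[int, ...] = (1024, 256)
    clf_raw_hidden: tuple[int, ...] = (256, 128)
    clf_repr_hidden: tuple[int, ...] = (128,)
    ae_hidden: tuple[int, ...] = (1024, 256, 1024)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 < f <= 1.0 for f in self.b_fractions):
            raise ValueError("b_fractions must lie in (0, 1]")
        if self.n_bootstrap < 1 or self.n_folds < 2:
            raise ValueError("n_bootstrap >= 1 and n_folds >= 2 required")

    @property
    def repr_dim(self) -> int:
        return self.repr_hidden[-1]

    @property
    def eff_clf_epochs(self) -> int:
        return self.clf_epochs if self.clf_epochs is not None else self.epochs

    @property
    def eff_clf_lr(self) -> float:
        return (self.clf_learning_rate if self.clf_learning_rate is not None
                else self.learning_rate)


# ------------------------------------------------------------ small models

def _train_loop(mlp: MLP, X: np.ndarray, grad_fn, epochs: int, lr: float,
                rng: np.random.Generator, batch_size: int = 16,
                weight_decay: float = 0.0) -> list[float]:
    """Minibatch Adam over ``epochs``; grad_fn(idx, out) -> (loss, dout)."""
    opt = Adam(mlp.params, lr=lr, weight_decay=weight_decay)
    losses = []
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            mlp.zero_grads()
            out = mlp.forward(X[idx], train=True)
            loss, dout = grad_fn(idx, out)
            epoch_loss += loss * idx.size
            mlp.backward(dout)
            opt.step(mlp.grads)
        losses.append(epoch_loss / n)
    return losses


class RepresentationModel:
    """Mean-pooled expression regressor with sigmoid hidden layers.

    ``represent`` returns the activations of the last hidden layer.
    """

    def __init__(self, input_dim: int, n_genes: int,
                 hidden: tuple[int, ...] = (1024, 256), seed: int = 0):
        rng = np.random.default_rng(seed)
        enc_layers: list = []
        d = input_dim
        for h in hidden:
            enc_layers += [Dense(d, h, rng), Sigmoid()]
            d = h
        self.encoder = MLP(enc_layers)
        self.head = MLP([Dense(d, n_genes, rng)])
        self.full = MLP(enc_layers + list(self.head.layers))
        self.repr_dim = d

    def represent(self, X: np.ndarray) -> np.ndarray:
        return self.encoder.forward(np.asarray(X, float), train=False)

    def fit(self, X: np.ndarray, Y: np.ndarray, epochs: int, lr: float,
            rng: np.random.Generator,
            weight_decay: float = 0.0) -> list[float]:
        def grad(idx, out):
            err = out - Y[idx]
            return float((err ** 2).mean()), 2.0 * err / err.size
        return _train_loop(self.full, X, grad, epochs, lr, rng,
                           weight_decay=weight_decay)


class _BinaryMLP:
    """Sigmoid-activated MLP classifier trained with binary cross-entropy."""

    def __init__(self, input_dim: int, hidden: tuple[int, ...], seed: int = 0):
        rng = np.random.default_rng(seed)
        layers: list = []
        d = input_dim
        for h in hidden:
            layers += [Dense(d, h, rng), Sigmoid()]
            d = h
        layers += [Dense(d, 1, rng)]  # logits; sigmoid applied in the loss
        self.mlp = MLP(layers)

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int, lr: float,
            rng: np.random.Generator,
            weight_decay: float = 0.0) -> list[float]:
        y = y.reshape(-1, 1).astype(float)

        def grad(idx, logits):
            p = 1.0 / (1.0 + np.exp(-np.clip(logits, -500, 500)))
            eps = 1e-12
            loss = float(-(y[idx] * np.log(p + eps)
                           + (1 - y[idx]) * np.log(1 - p + eps)).mean())
            return loss, (p - y[idx]) / idx.size
        return _train_loop(self.mlp, X, grad, epochs, lr, rng,
                           weight_decay=weight_decay)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.mlp.forward(np.asarray(X, float), train=False)
        return 1.0 / (1.0 + np.exp(-logits[:, 0]))


class _Autoencoder:
    """ReLU autoencoder; the middle hidden layer is the bottleneck."""

    def __init__(self, input_dim: int, hidden: tuple[int, ...], seed: int = 0):
        if len(hidden) % 2 == 0:
            raise ValueError("hidden must have an odd length (bottleneck "
                             "in the middle)")
        rng = np.random.default_rng(seed)
        mid = len(hidden) // 2
        enc_layers: list = []
        d = input_dim
        for i, h in enumerate(hidden[:mid + 1]):
            enc_layers.append(Dense(d, h, rng))
            if i < mid:
                enc_layers.append(ReLU())
            d = h  # bottleneck itself is linear
        dec_layers: list = []
        for h in hidden[mid + 1:]:
            dec_layers += [ReLU(), Dense(d, h, rng)]
            d = h
        dec_layers += [ReLU(), Dense(d, input_dim, rng)]
        self.encoder = MLP(enc_layers)
        self.full = MLP(enc_layers + dec_layers)
        self.bottleneck_dim = hidden[mid]

    def fit(self, X: np.ndarray, epochs: int, lr: float,
            rng: np.random.Generator,
            weight_decay: float = 0.0) -> list[float]:
        def grad(idx, out):
            err = out - X[idx]
            return float((err ** 2).mean()), 2.0 * err / err.size
        return _train_loop(self.full, X, grad, epochs, lr, rng,
                           weight_decay=weight_decay)

    def represent(self, X: np.ndarray) -> np.ndarray:
        return self.encoder.forward(np.asarray(X, float), train=False)


# ------------------------------------------------------------- fold helper

def _grouped_stratified_folds(patients: np.ndarray, labels: np.ndarray,
                              n_folds: int,
                              rng: np.random.Generator) -> dict[str, int]:
    """Patient-level folds with both classes spread across folds."""
    assign: dict[str, int] = {}
    offset = 0
    for cls in np.unique(labels):
        pats = patients[labels == cls]
        perm = rng.permutation(pats)
        for i, p in enumerate(perm):
            assign[str(p)] = int((i + offset) % n_folds)
        offset += pats.size
    return assign


# ------------------------------------------------------------ hospital A

def train_representation(pooled_a: pd.DataFrame, expression_a: ExpressionMatrix,
                         patient_of_sample: pd.Series,
                         cfg: TransferExperimentConfig,
                         b_samples: pd.DataFrame | None = None
                         ) -> tuple[list[RepresentationModel], pd.DataFrame | None]:
    """Fit the hospital-A regressors in a patient-grouped 3-fold CV.

    Never touches labels.  When ``b_samples`` (pooled features of hospital-B
    samples) is given, returns their representation as the mean of the
    fold models' encoder outputs; patients overlapping between A and B
    abort.
    """
    a_samples = list(pooled_a.index)
    a_patients = patient_of_sample.loc[a_samples]
    if b_samples is not None:
        b_pat = set(patient_of_sample.loc[list(b_samples.index)])
        if b_pat & set(a_patients):
            raise ValueError("patient overlap between hospitals A and B")
    X = pooled_a.to_numpy(dtype=float)
    Y = expression_a.log.loc[a_samples].to_numpy()
    rng = np.random.default_rng(cfg.seed)
    uniq = a_patients.unique()
    fold_of = {str(p): i % cfg.n_folds
               for i, p in enumerate(rng.permutation(uniq))}
    models = []
    for f in range(cfg.n_folds):
        m = np.array([fold_of[str(p)] != f for p in a_patients])
        if m.sum() < 2:
            raise ValueError("too few hospital-A samples for CV training")
        model = RepresentationModel(X.shape[1], Y.shape[1],
                                    hidden=cfg.repr_hidden,
                                    seed=cfg.seed + 31 * f)
        model.fit(X[m], Y[m], cfg.epochs, cfg.learning_rate,
                  np.random.default_rng(cfg.seed + 97 * f),
                  weight_decay=cfg.weight_decay)
        models.append(model)
    reps = None
    if b_samples is not None:
        Xb = b_samples.to_numpy(dtype=float)
        reps = pd.DataFrame(
            np.mean([mo.represent(Xb) for mo in models], axis=0),
            index=b_samples.index)
    return models, reps


# ------------------------------------------------------------ hospital B

def _classifier_cv_auc(X: pd.DataFrame, labels: pd.Series,
                       patient_of_sample: pd.Series,
                       hidden: tuple[int, ...],
                       cfg: TransferExperimentConfig,
                       seed: int) -> float:
    """Patient-grouped stratified 3-fold CV, repeated ``n_cv_repeats`` times
    with fresh fold draws; per-patient mean prediction; returns the mean
    patient-level out-of-fold AUC over the repeats."""
    samples = list(X.index)
    pats = patient_of_sample.loc[samples].to_numpy()
    uniq_pats = np.unique(pats)
    pat_label = labels.loc[uniq_pats].to_numpy()
    if np.unique(pat_label).size < 2:
        raise ValueError("hospital-B subset has a single label class")
    Xv = X.to_numpy(dtype=float)
    yv = labels.loc[pats].to_numpy(dtype=float)
    aucs = []
    for rep in range(cfg.n_cv_repeats):
        rep_seed = seed + 1013 * rep
        rng = np.random.default_rng(rep_seed)
        fold_of = _grouped_stratified_folds(uniq_pats, pat_label,
                                            cfg.n_folds, rng)
        sample_pred = np.full(len(samples), np.nan)
        for f in range(cfg.n_folds):
            te = np.array([fold_of[str(p)] == f for p in pats])
            tr = ~te
            if not te.any():
                continue
            if np.unique(yv[tr]).size < 2:
                raise ValueError(f"training fold {f} is single-class; redraw "
                                 "the hospital split")
            clf = _BinaryMLP(Xv.shape[1], hidden, seed=rep_seed + 11 * f)
            clf.fit(Xv[tr], yv[tr], cfg.eff_clf_epochs, cfg.eff_clf_lr,
                    np.random.default_rng(rep_seed + 13 * f),
                    weight_decay=cfg.weight_decay)
            sample_pred[te] = clf.predict_proba(Xv[te])
        pat_pred = np.array([sample_pred[pats == p].mean()
                             for p in uniq_pats])
        aucs.append(roc_auc_score(pat_label, pat_pred))
    return float(np.mean(aucs))


def train_classifier_raw(pooled_b: pd.DataFrame, labels: pd.Series,
                         patient_of_sample: pd.Series,
                         cfg: TransferExperimentConfig,
                         seed: int | None = None) -> float:
    """CV AUC of the classifier on raw mean-pooled tile features."""
    return _classifier_cv_auc(pooled_b, labels, patient_of_sample,
                              cfg.clf_raw_hidden, cfg,
                              cfg.seed if seed is None else seed)


def train_classifier_repr(repr_b: pd.DataFrame, labels: pd.Series,
                          patient_of_sample: pd.Series,
                          cfg: TransferExperimentConfig,
                          seed: int | None = None) -> float:
    """CV AUC of the classifier on transferred representations (same
    architecture minus the first hidden layer)."""
    return _classifier_cv_auc(repr_b, labels, patient_of_sample,
                              cfg.clf_repr_hidden, cfg,
                              cfg.seed if seed is None else seed)


def train_autoencoder_baseline(pooled: pd.DataFrame,
                               cfg: TransferExperimentConfig,
                               seed: int | None = None) -> _Autoencoder:
    """Unsupervised bottleneck baseline on one hospital's pooled vectors."""
    seed = cfg.seed if seed is None else seed
    ae = _Autoencoder(pooled.shape[1], cfg.ae_hidden, seed=seed)
    ae.losses = ae.fit(pooled.to_numpy(dtype=float), cfg.epochs,
                       cfg.learning_rate, np.random.default_rng(seed + 5),
                       weight_decay=cfg.weight_decay)
    return ae


# --------------------------------------------------------------- harness

METHODS = ("raw", "transcriptomic", "ae_hospital_a", "ae_hospital_b")


def hospital_split_harness(pooled: pd.DataFrame, expression: ExpressionMatrix,
                           labels: pd.Series, patient_of_sample: pd.Series,
                           cfg: TransferExperimentConfig) -> pd.DataFrame:
    """Bootstrap A/B splits at each B-fraction and run every method.

    Returns a long table (fraction, bootstrap, method, auc).  Splits are
    patient-level and stratified by label so small B subsets keep both
    classes.  ``labels`` is indexed by patient.
    """
    samples = list(pooled.index)
    pats = patient_of_sample.loc[samples]
    uniq_pats = np.unique(pats.to_numpy())
    pat_label = labels.loc[uniq_pats].to_numpy()
    rows = []
    for frac in cfg.b_fractions:
        n_b = int(round(frac * uniq_pats.size))
        if n_b < 2 * cfg.n_folds:
            raise ValueError(
                f"B-fraction {frac} leaves {n_b} patients, fewer than "
                f"{2 * cfg.n_folds} needed for stratified {cfg.n_folds}-fold CV")
        for boot in range(cfg.n_bootstrap):
            rng = np.random.default_rng(cfg.seed + 1009 * boot
                                        + int(frac * 1e6))
            b_pats: list = []
            for cls in np.unique(pat_label):
                cls_p = uniq_pats[pat_label == cls]
                take = max(1, int(round(frac * cls_p.size)))
                b_pats.extend(rng.choice(cls_p, size=take, replace=False))
            b_set = set(map(str, b_pats))
            a_set = {str(p) for p in uniq_pats} - b_set
            in_b = pats.map(lambda p: str(p) in b_set).to_numpy()
            pooled_b = pooled.loc[np.array(samples)[in_b]]
            seed_b = cfg.seed + 7 * boot
            aucs = {}
            aucs["raw"] = _classifier_cv_auc(
                pooled_b, labels, patient_of_sample, cfg.clf_raw_hidden,
                cfg, seed_b)
            if a_set:
                pooled_a = pooled.loc[np.array(samples)[~in_b]]
                expr_a = expression.subset_samples(list(pooled_a.index))
                _, reps_b = train_representation(
                    pooled_a, expr_a, patient_of_sample,
                    replace(cfg, seed=seed_b), b_samples=pooled_b)
                aucs["transcriptomic"] = _classifier_cv_auc(
                    reps_b, labels, patient_of_sample, cfg.clf_repr_hidden,
                    cfg, seed_b)
                ae_a = train_autoencoder_baseline(pooled_a, cfg, seed_b)
                aucs["ae_hospital_a"] = _classifier_cv_auc(
                    pd.DataFrame(ae_a.represent(pooled_b.to_numpy()),
                                 index=pooled_b.index),
                    labels, patient_of_sample, cfg.clf_repr_hidden, cfg,
                    seed_b)
            else:
                warnings.warn("empty hospital A: representation and "
                              "A-side autoencoder unavailable")
            ae_b = train_autoencoder_baseline(pooled_b, cfg, seed_b + 1)
            aucs["ae_hospital_b"] = _classifier_cv_auc(
                pd.DataFrame(ae_b.represent(pooled_b.to_numpy()),
                             index=pooled_b.index),
                labels, patient_of_sample, cfg.clf_repr_hidden, cfg, seed_b)
            for method, auc in aucs.items():
                rows.append({"fraction": frac, "bootstrap": boot,
                             "method": method, "auc": auc})
    return pd.DataFrame(rows)


# --------------------------------------------------------------- Wilcoxon

def compare_auc_distributions(aucs_x, aucs_y) -> float:
    """Two-tailed Wilcoxon signed-rank p for paired score distributions.

    Zero differences are dropped; exact null distribution (rank-sum
    counting) for n <= 25, normal approximation with continuity correction
    beyond.  All-zero differences give p = 1.
    """
    x = np.asarray(aucs_x, dtype=float)
    y = np.asarray(aucs_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        # exact: distribution of the positive-rank sum over all 2^n sign
        # assignments, via subset-sum counting on doubled (integer) ranks
        r2 = np.round(ranks * 2).astype(int)
        total = r2.sum()
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[:total + 1 - r].copy()
        w2 = int(round(w_pos * 2))
        probs = counts / counts.sum()
        p_le = probs[:w2 + 1].sum()
        p_ge = probs[w2:].sum()
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = n * (n + 1) / 4.0
    # variance with midrank tie correction
    var = ranks @ ranks / 4.0
    z = (abs(w_pos - mean) - 0.5) / np.sqrt(var)
    from scipy.stats import norm
    return float(min(1.0, 2.0 * norm.sf(z)))
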