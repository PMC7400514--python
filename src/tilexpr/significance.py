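"""Per-gene evaluation and statistical machinery.

Patient-grouped, cohort-stratified fold assignment; per-gene Pearson
correlations on held-out folds; an empirical null built from untrained
models of identical architecture; Holm-Sidak and Benjamini-Hochberg
corrections applied per cohort; and a pathway-vs-random-gene-lists
resampling test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aggregation import AggregationSpec, aggregate_inference
from .model import ModelSpec, RegressionModel, forward_tiles, _as_bags
from .types import ExpressionMatrix

__all__ = [
    "make_folds", "per_gene_correlation", "build_null", "NullDistribution",
    "empirical_pvalue", "holm_sidak", "benjamini_hochberg",
    "significance_table", "pathway_test", "PathwayResult",
]


# ------------------------------------------------------------------- folds

def make_folds(manifest: pd.DataFrame, n_folds: int = 5,
               seed: int = 0) -> dict[str, int]:
    """Patient-level fold assignment, stratified by cohort.

    Every slide of a patient shares the patient's fold; within each cohort
    the per-fold patient counts differ by at most one.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cohort, grp in manifest.groupby("cohort", sort=True):
        patients = sorted(grp["patient_id"].unique())
        if len(patients) < n_folds:
            raise ValueError(
                f"cohort {cohort} has {len(patients)} patients, fewer than "
                f"{n_folds} folds")
        perm = rng.permutation(patients)
        fold_order = rng.permutation(n_folds)
        for i, p in enumerate(perm):
            assignment[str(p)] = int(fold_order[i % n_folds])
    return assignment


# ------------------------------------------------------------ correlations

def _pearson_by_gene(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Column-wise Pearson R; NaN where either side has zero variance."""
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = pred - pred.mean(axis=0)
        tc = truth - truth.mean(axis=0)
        denom = np.sqrt((pc ** 2).sum(axis=0) * (tc ** 2).sum(axis=0))
        return np.where(denom > 0, (pc * tc).sum(axis=0) / denom, np.nan)


def per_gene_correlation(predictions: pd.DataFrame, truth: pd.DataFrame,
                         fold_of_slide: pd.Series,
                         cohort_of_slide: pd.Series) -> pd.DataFrame:
    """Pearson R per (gene, cohort, fold) on held-out samples, averaged over
    folds.  Returns a cohorts x genes table of mean R.

    Folds where prediction or truth has zero variance for a gene are
    skipped (with a warning summarised per call).
    """
    genes = [g for g in predictions.columns if g in truth.columns]
    slides = predictions.index
    rows = {}
    n_skipped = 0
    for cohort in sorted(cohort_of_slide.unique()):
        fold_rs = []
        for f in sorted(fold_of_slide.unique()):
            m = (cohort_of_slide.loc[slides] == cohort) & \
                (fold_of_slide.loc[slides] == f)
            sel = slides[m.to_numpy()]
            if len(sel) < 2:
                continue
            r = _pearson_by_gene(predictions.loc[sel, genes].to_numpy(),
                                 truth.loc[sel, genes].to_numpy())
            n_skipped += int(np.isnan(r).sum())
            fold_rs.append(r)
        if not fold_rs:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[cohort] = np.nanmean(np.stack(fold_rs), axis=0)
    if n_skipped:
        warnings.warn(f"{n_skipped} (gene, cohort, fold) cells had zero "
                      "variance and were skipped")
    return pd.DataFrame(rows, index=genes).T


# -------------------------------------------------------------------- null

@dataclass
class NullDistribution:
    """Pooled (or per-gene) correlations from untrained model replicates."""

    values: dict[str, np.ndarray]   # cohort -> pooled R values
    per_gene: dict[str, pd.DataFrame]  # cohort -> replicates x genes
    n_replicates: int


def build_null(spec: ModelSpec, agg: AggregationSpec, bags,
               truth: ExpressionMatrix, cohort_of_slide: pd.Series,
               n_replicates: int = 100, seed: int = 0) -> NullDistribution:
    """Correlation null from untrained models.

    Each replicate draws fresh random weights for the same architecture,
    runs the full inference path on every bag, and computes per-gene
    correlations within each cohort; values are pooled across genes and
    replicates per cohort.
    """
    bags = _as_bags(bags)
    slides = [b.slide_id for b in bags]
    y = truth.log.loc[slides].to_numpy()
    genes = truth.gene_ids
    cohorts = cohort_of_slide.loc[slides].to_numpy()
    pooled: dict[str, list[np.ndarray]] = {}
    per_gene: dict[str, list[np.ndarray]] = {}
    for rep in range(n_replicates):
        model = RegressionModel(spec, agg, seed=seed + 7919 * rep)
        preds = np.stack([aggregate_inference(
            forward_tiles(b.features, model), agg) for b in bags])
        for cohort in np.unique(cohorts):
            m = cohorts == cohort
            if m.sum() < 2:
                continue
            r = _pearson_by_gene(preds[m], y[m])
            pooled.setdefault(cohort, []).append(r[~np.isnan(r)])
            per_gene.setdefault(cohort, []).append(r)
    return NullDistribution(
        values={c: np.concatenate(v) for c, v in pooled.items()},
        per_gene={c: pd.DataFrame(np.stack(v), columns=genes)
                  for c, v in per_gene.items()},
        n_replicates=n_replicates)


def empirical_pvalue(observed: float, null_values: np.ndarray) -> float:
    """One-sided add-one empirical p: (1 + #{null >= observed}) / (1 + N)."""
    null_values = np.asarray(null_values)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + (null_values >= observed).sum())
                 / (1 + null_values.size))


# ------------------------------------------------------------- corrections

def holm_sidak(pvals) -> np.ndarray:
    """Step-down Sidak adjustment (family-wise error control)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH adjustment (false-discovery-rate control)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------- significance table

def significance_table(mean_r: pd.DataFrame, null: NullDistribution,
                       alpha: float = 0.05,
                       null_mode: str = "pooled") -> pd.DataFrame:
    """Gene-level significance calls per cohort.

    For each (gene, cohort): one-sided empirical p against the untrained
    null, Holm-Sidak and BH corrections applied separately per cohort,
    ``well_predicted`` when the HS-corrected p is below ``alpha``.  Also
    reports ``R_sign``, the smallest observed R among the cohort's
    well-predicted genes (NaN when none).
    """
    if null_mode not in ("pooled", "per_gene"):
        raise ValueError("null_mode must be 'pooled' or 'per_gene'")
    frames = []
    for cohort in mean_r.index:
        r = mean_r.loc[cohort]
        genes = r.index[~r.isna()]
        if null_mode == "pooled":
            nv = null.values[cohort]
            p_emp = np.array([empirical_pvalue(r[g], nv) for g in genes])
        else:
            ng = null.per_gene[cohort]
            p_emp = np.array([
                empirical_pvalue(r[g], ng[g].dropna().to_numpy())
                for g in genes])
        p_hs = holm_sidak(p_emp)
        p_bh = benjamini_hochberg(p_emp)
        well = p_hs < alpha
        r_obs = r[genes].to_numpy()
        r_sign = float(r_obs[well].min()) if well.any() else np.nan
        frames.append(pd.DataFrame({
            "gene": genes, "cohort": cohort, "R": r_obs,
            "p_empirical": p_emp, "p_holm_sidak": p_hs,
            "p_benjamini_hochberg": p_bh, "well_predicted": well,
            "R_sign": r_sign,
        }))
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------ pathway test

@dataclass
class PathwayResult:
    pathway: str
    genes: list[str]
    dropped: list[str]
    R_p: float
    f_p: float
    R_0: float
    p_R: float
    p_f: float
    n_random_lists: int
    significant: bool


def pathway_test(signif: pd.DataFrame, pathway_genes: list[str],
                 n_random: int = 10_000, seed: int = 0,
                 pathway_name: str = "pathway",
                 exhaustive: bool = False) -> PathwayResult:
    """Compare a pathway's mean R and well-predicted fraction against
    same-length random gene lists drawn from the evaluated universe.

    ``signif`` is one cohort's slice of the significance table.  p-values
    use the add-one rule; with ``exhaustive=True`` every possible list is
    enumerated instead (feasible only for tiny universes) and the p-value
    is the exact fraction of lists at least as extreme.
    """
    universe = signif["gene"].tolist()
    r_of = signif.set_index("gene")["R"]
    wp_of = signif.set_index("gene")["well_predicted"].astype(float)
    present = [g for g in pathway_genes if g in set(universe)]
    dropped = [g for g in pathway_genes if g not in set(universe)]
    if dropped:
        warnings.warn(f"{len(dropped)} pathway genes missing from the "
                      f"universe were dropped: {dropped[:5]}")
    if not present:
        raise ValueError("no pathway gene present in the evaluated universe")

    m = len(present)
    r_p = float(r_of[present].mean())
    f_p = float(wp_of[present].mean())
    r_all = r_of[universe].to_numpy()
    wp_all = wp_of[universe].to_numpy()

    if exhaustive:
        from itertools import combinations
        r_draws, f_draws = [], []
        for combo in combinations(range(len(universe)), m):
            idx = list(combo)
            r_draws.append(r_all[idx].mean())
            f_draws.append(wp_all[idx].mean())
        r_draws = np.array(r_draws)
        f_draws = np.array(f_draws)
        n_lists = r_draws.size
        p_r = float((r_draws >= r_p).sum() / n_lists)
        p_f = float((f_draws >= f_p).sum() / n_lists)
    else:
        rng = np.random.default_rng(seed)
        n_lists = n_random
        # vectorized sampling without replacement: random-key argsort
        keys = rng.random((n_random, len(universe)))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        r_draws = r_all[idx].mean(axis=1)
        f_draws = wp_all[idx].mean(axis=1)
        p_r = float((1 + (r_draws >= r_p).sum()) / (1 + n_random))
        p_f = float((1 + (f_draws >= f_p).sum()) / (1 + n_random))

    return PathwayResult(
        pathway=pathway_name, genes=present, dropped=dropped,
        R_p=r_p, f_p=f_p, R_0=float(r_draws.mean()),
        p_R=p_r, p_f=p_f, n_random_lists=n_lists,
        significant=bool(p_r < 0.05))


def tile_count_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson R with two-tailed t-test p (used by spatialization)."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)
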