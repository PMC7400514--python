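import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tilexpr.aggregation import AggregationSpec
from tilexpr.model import ModelSpec
from tilexpr.significance import (NullDistribution, benjamini_hochberg,
                                  build_null, empirical_pvalue, holm_sidak,
                                  make_folds, pathway_test,
                                  per_gene_correlation, significance_table)
from tilexpr.types import ExpressionMatrix


def holm_sidak_oracle(p):
    """Direct step-down Sidak with running maximum (hand formula)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


def bh_oracle(p):
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        idx = order[i]
        running = min(running, p[idx] * m / (i + 1))
        adj[idx] = running
    return adj


class TestMakeFolds:
    def test_even_split(self):
        manifest = pd.DataFrame({
            "slide_id": [f"s{i}" for i in range(10)],
            "patient_id": [f"p{i}" for i in range(10)],
            "cohort": ["c0"] * 10})
        folds = make_folds(manifest, 5, seed=0)
        counts = pd.Series(folds).value_counts()
        assert (counts == 2).all()

    def test_patient_grouping(self):
        manifest = pd.DataFrame({
            "slide_id": ["a1", "a2", "a3", "b1", "c1", "d1", "e1"],
            "patient_id": ["pa", "pa", "pa", "pb", "pc", "pd", "pe"],
            "cohort": ["c0"] * 7})
        folds = make_folds(manifest, 2, seed=1)
        # the patient has one fold id; slides inherit it by construction
        assert len(folds) == 5

    def test_stratified_pigeonhole(self):
        rows = []
        for i in range(7):
            rows.append({"slide_id": f"x{i}", "patient_id": f"px{i}",
                         "cohort": "cA"})
        for i in range(8):
            rows.append({"slide_id": f"y{i}", "patient_id": f"py{i}",
                         "cohort": "cB"})
        folds = make_folds(pd.DataFrame(rows), 5, seed=3)
        df = pd.DataFrame({"p": list(folds), "f": list(folds.values())})
        df["cohort"] = df["p"].str[1]
        for _, grp in df.groupby("cohort"):
            counts = grp["f"].value_counts().reindex(range(5), fill_value=0)
            assert counts.max() - counts.min() <= 1

    def test_small_cohort_rejected(self):
        manifest = pd.DataFrame({"slide_id": ["s0"], "patient_id": ["p0"],
                                 "cohort": ["c0"]})
        with pytest.raises(ValueError):
            make_folds(manifest, 5, seed=0)

    def test_deterministic(self):
        manifest = pd.DataFrame({
            "slide_id": [f"s{i}" for i in range(12)],
            "patient_id": [f"p{i}" for i in range(12)],
            "cohort": ["c0"] * 12})
        assert make_folds(manifest, 4, 9) == make_folds(manifest, 4, 9)


class TestPerGeneCorrelation:
    def _frame(self, pred, truth):
        slides = [f"s{i}" for i in range(len(pred))]
        p = pd.DataFrame({"g": pred}, index=slides)
        t = pd.DataFrame({"g": truth}, index=slides)
        fold = pd.Series(0, index=slides)
        cohort = pd.Series("c0", index=slides)
        return p, t, fold, cohort

    def test_perfect(self):
        r = per_gene_correlation(*self._frame([1, 2, 3], [1, 2, 3]))
        assert r.loc["c0", "g"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        r = per_gene_correlation(*self._frame([3, 2, 1], [1, 2, 3]))
        assert r.loc["c0", "g"] == pytest.approx(-1.0)

    def test_hand_value(self):
        # pearson([1,1,2,2], [0,1,1,2]) = 0.7071...
        r = per_gene_correlation(*self._frame([1, 1, 2, 2], [0, 1, 1, 2]))
        assert r.loc["c0", "g"] == pytest.approx(np.sqrt(0.5), rel=1e-6)

    def test_mean_over_folds(self):
        slides = [f"s{i}" for i in range(6)]
        pred = pd.DataFrame({"g": [1, 2, 3, 3, 2, 1]}, index=slides)
        truth = pd.DataFrame({"g": [1, 2, 3, 1, 2, 3]}, index=slides)
        fold = pd.Series([0, 0, 0, 1, 1, 1], index=slides)
        cohort = pd.Series("c0", index=slides)
        r = per_gene_correlation(pred, truth, fold, cohort)
        assert r.loc["c0", "g"] == pytest.approx(0.0)  # (1 + -1) / 2

    def test_zero_variance_fold_skipped(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r = per_gene_correlation(*self._frame([1.0, 1.0, 1.0], [1, 2, 3]))
        assert np.isnan(r.loc["c0", "g"])


class TestEmpiricalPvalue:
    def test_add_one_floor(self):
        null = np.linspace(-0.5, 0.5, 999)
        assert empirical_pvalue(0.9, null) == pytest.approx(1 / 1000)

    def test_median(self):
        null = np.linspace(-1, 1, 999)
        assert empirical_pvalue(0.0, null) == pytest.approx(0.5, abs=0.01)

    def test_below_all(self):
        null = np.linspace(0.1, 0.9, 99)
        assert empirical_pvalue(-0.5, null) == pytest.approx(1.0)

    def test_empty_null(self):
        with pytest.raises(ValueError):
            empirical_pvalue(0.1, np.array([]))


class TestCorrections:
    def test_single_test_unchanged(self):
        np.testing.assert_allclose(holm_sidak([0.03]), [0.03])
        np.testing.assert_allclose(benjamini_hochberg([0.03]), [0.03])

    def test_hs_hand_value(self):
        # m=2: adj_(1) = 1 - (1-0.01)^2 = 0.0199; adj_(2) = max(0.04, ...)
        np.testing.assert_allclose(holm_sidak([0.01, 0.04]), [0.0199, 0.04],
                                   rtol=1e-10)

    def test_bh_hand_value(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], rtol=1e-12)

    def test_hs_matches_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(holm_sidak(p), holm_sidak_oracle(p),
                                       rtol=1e-10)

    def test_bh_matches_oracle_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p),
                                       rtol=1e-10)

    def test_hs_conservative(self):
        rng = np.random.default_rng(2)
        p = rng.random(20)
        assert (holm_sidak(p) >= p - 1e-12).all()

    def test_bh_no_less_powerful_than_hs(self):
        # BH (FDR) is essentially never more conservative than the
        # family-wise HS correction; the lone exception is the smallest
        # p-value, where 1-(1-p)^m < m*p makes HS marginally sharper.
        rng = np.random.default_rng(3)
        worse = 0
        for _ in range(1000):
            p = rng.random(10) ** 2
            n_bh = (benjamini_hochberg(p) < 0.05).sum()
            n_hs = (holm_sidak(p) < 0.05).sum()
            worse += n_bh < n_hs
        assert worse <= 10

    def test_range_validation(self):
        with pytest.raises(ValueError):
            holm_sidak([0.1, 1.5])


class TestBuildNull:
    def _setup(self, n_patients=20, seed=0):
        from tilexpr.synthetic import SyntheticConfig, generate_cohorts, \
            manifest_from_bags
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bags, expr, _, _ = generate_cohorts(SyntheticConfig(
                patients_per_cohort=n_patients, slides_per_patient=1,
                tiles_per_slide=25, feature_dim=8, n_tile_types=2,
                n_signal_genes=1, n_noise_genes=10, seed=seed))
        cohort = manifest_from_bags(bags).set_index("slide_id")["cohort"]
        spec = ModelSpec(input_dim=8, n_genes=expr.n_genes, hidden=(8,),
                         dropout=0.0)
        return bags, expr, cohort, spec

    def test_centered_near_zero(self):
        bags, expr, cohort, spec = self._setup(n_patients=40)
        null = build_null(spec, AggregationSpec(L=(1, 5, 25)), bags, expr,
                         cohort, n_replicates=20, seed=0)
        assert abs(null.values["cohort0"].mean()) < 0.1

    def test_gene_permutation_invariance(self):
        # untrained outputs are exchangeable across genes, so permuting the
        # truth's gene columns leaves the pooled null invariant in
        # distribution (not entry-wise)
        bags, expr, cohort, spec = self._setup()
        null1 = build_null(spec, AggregationSpec(L=(1, 5)), bags, expr,
                           cohort, n_replicates=30, seed=0)
        perm_raw = expr.raw[expr.raw.columns[::-1]]
        null2 = build_null(spec, AggregationSpec(L=(1, 5)), bags,
                           ExpressionMatrix(perm_raw), cohort,
                           n_replicates=30, seed=0)
        v1, v2 = null1.values["cohort0"], null2.values["cohort0"]
        assert abs(v1.mean() - v2.mean()) < 0.05
        assert abs(v1.std() - v2.std()) < 0.05

    def test_spread_shrinks_with_n(self):
        b20 = self._setup(n_patients=20, seed=1)
        b80 = self._setup(n_patients=80, seed=1)
        n20 = build_null(b20[3], AggregationSpec(L=(1, 5)), b20[0], b20[1],
                         b20[2], n_replicates=10, seed=0)
        n80 = build_null(b80[3], AggregationSpec(L=(1, 5)), b80[0], b80[1],
                         b80[2], n_replicates=10, seed=0)
        assert n80.values["cohort0"].std() < n20.values["cohort0"].std()


class TestSignificanceTable:
    def test_well_predicted_consistent(self):
        mean_r = pd.DataFrame({"g0": [0.9], "g1": [0.0], "g2": [-0.2]},
                              index=["c0"])
        null = NullDistribution(
            values={"c0": np.random.default_rng(0).normal(0, 0.1, 2000)},
            per_gene={}, n_replicates=1)
        table = significance_table(mean_r, null)
        by_gene = table.set_index("gene")
        assert bool(by_gene.loc["g0", "well_predicted"])
        assert not bool(by_gene.loc["g1", "well_predicted"])
        assert (table["well_predicted"]
                == (table["p_holm_sidak"] < 0.05)).all()
        assert by_gene.loc["g0", "R_sign"] == pytest.approx(0.9)


class TestPathwayTest:
    def _signif(self, rs):
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(len(rs))],
            "R": rs, "well_predicted": [r > 0.5 for r in rs]})

    def test_top_genes_floor(self):
        # pathway = top genes by R in a large universe: no random list can
        # match it, so p sits at the add-one floor
        rng = np.random.default_rng(0)
        rs = np.sort(rng.random(100))[::-1]
        rs[:3] += 1.0
        res = pathway_test(self._signif(list(rs)), ["g0", "g1", "g2"],
                           n_random=199, seed=0)
        assert res.p_R == pytest.approx(1 / 200)

    def test_exhaustive_six_gene_example(self):
        rs = [0.9, 0.8, 0.1, 0.1, 0.1, 0.1]
        res = pathway_test(self._signif(rs), ["g0", "g1"], exhaustive=True)
        # enumeration oracle: of the 15 two-gene lists only the pathway
        # itself reaches mean R >= 0.85
        n_ge = sum(np.mean([rs[i], rs[j]]) >= 0.85
                   for i, j in combinations(range(6), 2))
        assert n_ge == 1
        assert res.p_R == pytest.approx(1 / 15)

    def test_sampled_close_to_exhaustive(self):
        rs = [0.9, 0.8, 0.1, 0.1, 0.1, 0.1]
        res = pathway_test(self._signif(rs), ["g0", "g1"], n_random=4999,
                           seed=1)
        assert res.p_R == pytest.approx(1 / 15, rel=0.35)

    def test_missing_genes_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            res = pathway_test(self._signif([0.5, 0.4]), ["g0", "gX"],
                               n_random=9, seed=0)
        assert res.dropped == ["gX"]

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                pathway_test(self._signif([0.5]), ["nope"], n_random=9, seed=0)

    def test_null_calibration(self):
        # random pathways: rejection rate at 0.05 within [0.03, 0.07]
        rng = np.random.default_rng(5)
        rs = rng.normal(0, 0.3, 40)
        signif = self._signif(rs)
        rejections = 0
        n_trials = 400
        for trial in range(n_trials):
            genes = [f"g{i}" for i in rng.choice(40, size=5, replace=False)]
            res = pathway_test(signif, genes, n_random=499, seed=trial)
            rejections += res.p_R < 0.05
        assert 0.02 <= rejections / n_trials <= 0.08
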