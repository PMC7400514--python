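import warnings
from itertools import product

import numpy as np
import pandas as pd
import pytest

from tilexpr.preprocessing import mean_pool_bag
from tilexpr.synthetic import SyntheticConfig, generate_cohorts, \
    manifest_from_bags
from tilexpr.transfer import (RepresentationModel, TransferExperimentConfig,
                              _Autoencoder, compare_auc_distributions,
                              hospital_split_harness, train_autoencoder_baseline,
                              train_classifier_raw, train_representation)
from tilexpr.types import ExpressionMatrix


def wilcoxon_signflip_oracle(x, y):
    """Exhaustive sign-flip enumeration of the signed-rank statistic."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = (ws <= w_obs).mean()
    p_ge = (ws >= w_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


@pytest.fixture(scope="module")
def transfer_cohort():
    cfg = SyntheticConfig(patients_per_cohort=24, slides_per_patient=1,
                          tiles_per_slide=(16, 25), feature_dim=16,
                          n_tile_types=3, n_signal_genes=4, n_noise_genes=6,
                          label_logit_scale=12.0, seed=21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bags, expr, truth, labels = generate_cohorts(cfg)
    pooled = pd.DataFrame({b.slide_id: mean_pool_bag(b) for b in bags}).T
    pos = manifest_from_bags(bags).set_index("slide_id")["patient_id"]
    lab = labels.set_index("patient_id")["label"]
    return pooled, expr, pos, lab


class TestConfig:
    def test_default_repr_dim_is_256(self):
        assert TransferExperimentConfig().repr_dim == 256

    def test_default_architectures(self):
        cfg = TransferExperimentConfig()
        assert cfg.repr_hidden == (1024, 256)
        assert cfg.clf_raw_hidden == (256, 128)
        assert cfg.clf_repr_hidden == (128,)
        assert cfg.ae_hidden == (1024, 256, 1024)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            TransferExperimentConfig(b_fractions=(1.5,))

    def test_invalid_bootstrap(self):
        with pytest.raises(ValueError):
            TransferExperimentConfig(n_bootstrap=0)


class TestRepresentationModel:
    def test_default_width_256(self):
        m = RepresentationModel(16, 5)
        assert m.repr_dim == 256
        assert m.represent(np.zeros((3, 16))).shape == (3, 256)

    def test_identical_inputs_identical_repr(self):
        m = RepresentationModel(8, 3, hidden=(16, 4), seed=0)
        x = np.random.default_rng(0).standard_normal(8)
        reps = m.represent(np.stack([x, x]))
        np.testing.assert_array_equal(reps[0], reps[1])

    def test_firewall_patient_overlap_aborts(self, transfer_cohort):
        pooled, expr, pos, lab = transfer_cohort
        cfg = TransferExperimentConfig(epochs=1, repr_hidden=(8, 4))
        with pytest.raises(ValueError, match="overlap"):
            train_representation(pooled, expr, pos, cfg, b_samples=pooled)

    def test_never_sees_labels(self, transfer_cohort):
        # API-level firewall: labels cannot even be passed in, and the
        # expression object is the only hospital-A data touched
        import inspect
        sig = inspect.signature(train_representation)
        assert "labels" not in sig.parameters

    def test_representation_transfer(self, transfer_cohort):
        pooled, expr, pos, lab = transfer_cohort
        a = list(pooled.index[:16])
        b = list(pooled.index[16:])
        cfg = TransferExperimentConfig(epochs=30, learning_rate=1e-3,
                                       repr_hidden=(16, 8), seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models, reps = train_representation(
                pooled.loc[a], expr.subset_samples(a), pos, cfg,
                b_samples=pooled.loc[b])
        assert len(models) == cfg.n_folds
        assert reps.shape == (len(b), 8)
        assert list(reps.index) == b


class TestClassifiers:
    def test_separable_labels_high_auc(self, transfer_cohort):
        pooled, expr, pos, lab = transfer_cohort
        # construct perfectly separable labels from a feature column
        sep = (pooled.iloc[:, 0] > pooled.iloc[:, 0].median()).astype(int)
        sep_pat = sep.groupby(pos.loc[sep.index]).max()
        cfg = TransferExperimentConfig(epochs=150, clf_learning_rate=1e-2,
                                       n_cv_repeats=2, seed=0)
        auc = train_classifier_raw(pooled, sep_pat, pos, cfg)
        assert auc >= 0.9

    def test_shuffled_labels_near_chance(self, transfer_cohort):
        pooled, expr, pos, lab = transfer_cohort
        rng = np.random.default_rng(0)
        aucs = []
        for trial in range(8):
            shuffled = pd.Series(rng.permutation(lab.to_numpy()),
                                 index=lab.index)
            if shuffled.nunique() < 2:
                continue
            cfg = TransferExperimentConfig(epochs=40, n_cv_repeats=2,
                                           clf_learning_rate=1e-2, seed=trial)
            aucs.append(train_classifier_raw(pooled, shuffled, pos, cfg,
                                             seed=trial))
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_deterministic(self, transfer_cohort):
        pooled, expr, pos, lab = transfer_cohort
        cfg = TransferExperimentConfig(epochs=20, n_cv_repeats=2, seed=5)
        a1 = train_classifier_raw(pooled, lab, pos, cfg)
        a2 = train_classifier_raw(pooled, lab, pos, cfg)
        assert a1 == a2

    def test_single_class_rejected(self, transfer_cohort):
        pooled, expr, pos, lab = transfer_cohort
        ones = pd.Series(1, index=lab.index)
        cfg = TransferExperimentConfig(epochs=2)
        with pytest.raises(ValueError, match="single label class"):
            train_classifier_raw(pooled, ones, pos, cfg)


class TestAutoencoder:
    def test_bottleneck_width_default_256(self):
        ae = _Autoencoder(32, (1024, 256, 1024))
        assert ae.bottleneck_dim == 256

    def test_loss_decreases(self, transfer_cohort):
        pooled, *_ = transfer_cohort
        cfg = TransferExperimentConfig(epochs=10, learning_rate=1e-3,
                                       ae_hidden=(32, 8, 32))
        ae = train_autoencoder_baseline(pooled, cfg)
        assert ae.losses[-1] < ae.losses[0]

    def test_even_hidden_rejected(self):
        with pytest.raises(ValueError):
            _Autoencoder(8, (16, 4))


class TestHarness:
    def test_shape_contract(self, transfer_cohort):
        pooled, expr, pos, lab = transfer_cohort
        cfg = TransferExperimentConfig(
            b_fractions=(0.5,), n_bootstrap=2, n_cv_repeats=1, epochs=5,
            repr_hidden=(8, 4), ae_hidden=(8, 4, 8), clf_raw_hidden=(8,),
            clf_repr_hidden=(4,), seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = hospital_split_harness(pooled, expr, lab, pos, cfg)
        assert set(res["method"]) == {"raw", "transcriptomic",
                                      "ae_hospital_a", "ae_hospital_b"}
        assert len(res) == 2 * 4
        assert res["auc"].between(0, 1).all()

    def test_too_small_b_rejected(self, transfer_cohort):
        pooled, expr, pos, lab = transfer_cohort
        cfg = TransferExperimentConfig(b_fractions=(0.1,), n_bootstrap=1)
        with pytest.raises(ValueError, match="fewer than"):
            hospital_split_harness(pooled, expr, lab, pos, cfg)

    def test_full_b_yields_no_transfer_methods(self, transfer_cohort):
        pooled, expr, pos, lab = transfer_cohort
        cfg = TransferExperimentConfig(
            b_fractions=(1.0,), n_bootstrap=1, n_cv_repeats=1, epochs=3,
            repr_hidden=(8, 4), ae_hidden=(8, 4, 8), clf_raw_hidden=(8,),
            clf_repr_hidden=(4,), seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.warns(UserWarning, match="empty hospital A"):
                res = hospital_split_harness(pooled, expr, lab, pos, cfg)
        assert set(res["method"]) == {"raw", "ae_hospital_b"}


class TestWilcoxon:
    def test_identical_samples(self):
        x = np.arange(10.0)
        assert compare_auc_distributions(x, x) == 1.0

    def test_constant_shift_floor(self):
        x = np.arange(10.0)
        p = compare_auc_distributions(x + 1.0, x)
        assert p == pytest.approx(2 / 1024)

    def test_matches_signflip_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            assert compare_auc_distributions(x, y) == pytest.approx(
                wilcoxon_signflip_oracle(x, y), rel=1e-10)

    def test_matches_oracle_with_ties(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        y = np.array([0.0, 1.0, 2.0, 5.0, 4.0])  # |d| = 1,1,1,1,2
        assert compare_auc_distributions(x, y) == pytest.approx(
            wilcoxon_signflip_oracle(x, y), rel=1e-10)

    def test_large_n_normal_approx(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60)
        y = x + 0.8 + 0.1 * rng.standard_normal(60)
        p = compare_auc_distributions(x, y)
        from scipy.stats import wilcoxon as scipy_wilcoxon
        ref = scipy_wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=0.05)
        assert p < 1e-6

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_auc_distributions([1.0], [1.0, 2.0])
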