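"""Reference desk-scale experiment configurations.

These presets pin the synthetic-cohort and training settings used by the
built-in validation experiments (parameter/spatial recovery, family-wise
error calibration, and the two-hospital transfer comparison) so that tests,
scripts and documentation all run the same, tuned configuration.
"""

from __future__ import annotations

from .aggregation import AggregationSpec
from .model import ModelSpec, TrainConfig
from .synthetic import SyntheticConfig
from .transfer import TransferExperimentConfig

__all__ = [
    "recovery_cohort_config", "recovery_model_spec", "recovery_train_config",
    "noise_cohort_config", "transfer_cohort_config", "transfer_config",
    "RECOVERY_N_CLUSTERS",
]

RECOVERY_N_CLUSTERS = 20


def recovery_cohort_config(seed: int) -> SyntheticConfig:
    """40-slide cohort with 5 signal and 50 noise genes."""
    return SyntheticConfig(
        patients_per_cohort=20, slides_per_patient=2,
        tiles_per_slide=(64, 100), feature_dim=32, n_tile_types=4,
        n_signal_genes=5, n_noise_genes=50, feature_noise_sd=0.25,
        seed=seed)


def noise_cohort_config(seed: int) -> SyntheticConfig:
    """Pure-noise variant: one vestigial signal gene with zero strength
    contribution is avoided by linking nothing — use 50 noise genes only."""
    return SyntheticConfig(
        patients_per_cohort=20, slides_per_patient=2,
        tiles_per_slide=(64, 100), feature_dim=32, n_tile_types=4,
        n_signal_genes=1, n_noise_genes=50, signal_strength=1e-6,
        feature_noise_sd=0.25, seed=seed)


def recovery_model_spec(n_genes: int) -> ModelSpec:
    return ModelSpec(input_dim=32, n_genes=n_genes, hidden=(32,),
                     dropout=0.0)


def recovery_train_config(seed: int, max_epochs: int = 400,
                          patience: int = 100) -> TrainConfig:
    return TrainConfig(learning_rate=1e-3, batch_size=4,
                       max_epochs=max_epochs, patience=patience,
                       val_fraction=0.25, seed=seed)


def recovery_agg() -> AggregationSpec:
    return AggregationSpec(mode="supertile")


def transfer_cohort_config(seed: int) -> SyntheticConfig:
    """150 single-slide patients; composition-linked label; slide-level
    nuisance variation that dominates feature variance but is independent
    of expression and label."""
    return SyntheticConfig(
        patients_per_cohort=150, slides_per_patient=1,
        tiles_per_slide=(25, 36), feature_dim=128, n_tile_types=4,
        n_signal_genes=20, n_noise_genes=35, feature_noise_sd=0.5,
        label_logit_scale=12.0, n_nuisance=80, nuisance_sd=0.35, seed=seed)


def transfer_config(seed: int, n_bootstrap: int = 50) -> TransferExperimentConfig:
    return TransferExperimentConfig(
        b_fractions=(0.2,), n_bootstrap=n_bootstrap, n_cv_repeats=3,
        epochs=250, learning_rate=1e-3, clf_epochs=200,
        clf_learning_rate=1e-2, repr_hidden=(256, 32),
        ae_hidden=(256, 32, 256), seed=seed)
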