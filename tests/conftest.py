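import warnings

import numpy as np
import pandas as pd
import pytest

from tilexpr.synthetic import SyntheticConfig, generate_cohorts, manifest_from_bags
from tilexpr.types import ExpressionMatrix, TileBag


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort shared by read-only tests (6 patients, 1 cohort)."""
    cfg = SyntheticConfig(patients_per_cohort=6, slides_per_patient=2,
                          tiles_per_slide=(25, 36), feature_dim=8,
                          n_tile_types=3, n_signal_genes=3, n_noise_genes=5,
                          seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bags, expr, truth, labels = generate_cohorts(cfg)
    return {"cfg": cfg, "bags": bags, "expression": expr, "truth": truth,
            "labels": labels, "manifest": manifest_from_bags(bags)}


@pytest.fixture
def random_bag():
    rng = np.random.default_rng(0)
    n = 30
    coords = np.stack([np.arange(n) % 6, np.arange(n) // 6], axis=1)
    return TileBag("s0", "p0", "c0", coords, rng.standard_normal((n, 5)))


@pytest.fixture
def small_expression():
    raw = pd.DataFrame(
        {"gA": [0.0, 0.0, 0.0, 5.0], "gB": [0.0, 1.0, 2.0, 3.0],
         "gC": [1.0, 2.0, 3.0, 4.0]},
        index=["s0", "s1", "s2", "s3"])
    return ExpressionMatrix(raw)
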