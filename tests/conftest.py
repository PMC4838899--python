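import warnings

import numpy as np
import pandas as pd
import pytest

from otomics import CohortConfig, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # clustering on tiny/degenerate fixtures emits advisory warnings by design
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """One study-shaped cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(seed=4))


@pytest.fixture(scope="session")
def clean_cohort():
    """Balanced 5-subtype cohort without controls/contamination/missingness."""
    cfg = CohortConfig(
        n_per_subtype=(24,) * 5,
        n_normal_controls=0,
        n_contaminated=0,
        missing_fraction={"mrna": 0.0, "mirna": 0.0, "methylation": 0.0},
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=features, columns=samples)
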