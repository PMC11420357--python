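import numpy as np
import pandas as pd
import pytest

from phenomap import synth


@pytest.fixture(scope="session")
def small_cohort():
    """Study-structured cohort, small enough for fast end-to-end runs."""
    cfg = synth.default_cohort_config(n_patients=600, seed=7)
    features, records, labels = synth.generate_cohort(cfg)
    return cfg, features, records, labels


@pytest.fixture(scope="session")
def separated_cohort():
    """Five well-separated circumplex groups (recovery fixture)."""
    cfg = synth.well_separated_config(seed=0)
    features, records, labels = synth.generate_cohort(cfg)
    return cfg, features, records, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_feature_frame(values, columns=None):
    arr = np.asarray(values, dtype=float)
    cols = columns or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)
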