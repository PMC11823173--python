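import numpy as np
import pytest

from colxnet import SimConfig, simulate_cohort, simulate_celltype_counts


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    cfg = SimConfig(seed=1)
    X, clin, truth = simulate_cohort(cfg)
    return cfg, X, clin, truth


@pytest.fixture(scope="session")
def celltype_data():
    cfg = SimConfig(seed=2)
    counts, labels, truth = simulate_celltype_counts(cfg)
    return cfg, counts, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
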