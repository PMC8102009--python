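import numpy as np
import pytest

from tsatwas import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_config():
    """A cheap multi-tissue scenario for structural tests."""
    return ScenarioConfig(n_tissues=3, m_eqtl=12, m_mt=8, m_null=10,
                          cor_tissue=0.6, r2_expr_trait=0.01,
                          n_total=450, n_eqtl_train=150, n_twas=300,
                          n_pairs=5, n_reps=1, seed=123)


@pytest.fixture
def default_config():
    return ScenarioConfig(n_tissues=5, m_mt=24, cor_tissue=0.8, seed=7)
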