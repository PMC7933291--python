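import numpy as np
import pytest

import crosspop as cp
from crosspop.pipeline import _simulate_polymorphic, _stack


@pytest.fixture(scope="session")
def small_dataset():
    """A modest two-population cohort shared by read-only tests."""
    model = cp.PopulationModel(n_pop1=300, n_pop2=300, m=500, fst_target=0.1,
                               ld_rho=0.5, ld_block_size=10, seed=42)
    arch = cp.TraitArchitecture(m_causal=150, rg_true=0.7, h2_pop1=0.5, h2_pop2=0.4)
    dataset, y = _simulate_polymorphic(model, arch)
    return dataset, y


def make_bivariate_model(dataset, y, grms, covariates=None):
    model, _ = _stack(dataset, y, grms, covariates)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
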