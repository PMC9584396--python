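import numpy as np
import pytest

import ibstriage as ib


@pytest.fixture(scope="session")
def default_config() -> ib.SimulationConfig:
    return ib.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return ib.simulate_cohort(default_config)


@pytest.fixture(scope="session")
def de_matrix(default_config, default_cohort):
    """2000-gene matrix with 200 planted effects (magnitudes 0.5-2.0 log2, noise 0.5)."""
    return ib.simulate_microarray(default_config, default_cohort)


@pytest.fixture(scope="session")
def null_matrix():
    """2000 genes, no planted effects: every positive is a false positive."""
    cfg = ib.SimulationConfig(seed=7, n_de_genes=0)
    cohort = ib.simulate_cohort(cfg)
    return cohort, ib.simulate_microarray(cfg, cohort)


@pytest.fixture(scope="session")
def case_mask(default_cohort) -> np.ndarray:
    return (default_cohort["classification"] == "case").to_numpy()
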