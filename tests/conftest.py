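import numpy as np
import pytest

from methnet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def low_noise_cohort():
    """Small cohort with clearly recoverable planted structure."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=4,
        unit_coupling=1.0,
        site_sd=0.01,
        expr_sd=0.05,
        missing_rate=0.0,
        n_null_sites_per_gene=10,
        n_reference_samples=4000,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = SimulationConfig(seed=7, n_genes=4, n_reference_samples=4000)
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
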