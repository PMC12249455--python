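import numpy as np
import pytest

from bimodalsurv import SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_cohort():
    """112-sample cohort with 10 planted prognostic bimodal genes among 300."""
    cfg = SimulationConfig(n_samples=112, n_genes=300, n_bimodal=10, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with bimodal structure but no survival effect (log_hr irrelevant)."""
    cfg = SimulationConfig(
        n_samples=112, n_genes=400, n_bimodal=30, n_prognostic=0, seed=7
    )
    return generate_cohort(cfg)
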