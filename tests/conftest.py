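import numpy as np
import pytest

from epioutlier import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort reused across tests (fixed seed)."""
    cfg = SimConfig(n_genes=300, n_silenced=10, n_up_outlier=10,
                    n_pathway=20, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
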