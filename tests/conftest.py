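import numpy as np
import pytest

from sdbexpr import SimulationConfig, simulate_all

COV_A = ["age", "sex", "site", "neut", "nk", "tcell", "bcell"]
COV_B = ["age", "sex", "neut", "nk", "tcell", "bcell"]


@pytest.fixture(scope="session")
def small_sim():
    """One moderate synthetic study bundle shared across read-only tests."""
    cfg = SimulationConfig(n_genes=150, n_planted=15)
    return cfg, simulate_all(cfg, 11)


@pytest.fixture(scope="session")
def null_sim():
    """A cohort pair with no planted effects (global null)."""
    cfg = SimulationConfig(n_genes=400, n_planted=0)
    return cfg, simulate_all(cfg, 17)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
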