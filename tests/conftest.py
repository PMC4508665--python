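import numpy as np
import pandas as pd
import pytest

from regressnet.datatypes import ExpressionDataset
from regressnet.synthetic import SimulationConfig, simulate_all


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """Deterministic 8-gene x 6-sample dataset with two clean blocks."""
    rng = np.random.default_rng(42)
    profile_a = np.array([1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
    profile_b = np.array([-2.0, 1.0, -1.0, 2.0, 0.5, -0.5])
    rows = []
    for i in range(4):
        rows.append(profile_a + 0.05 * rng.standard_normal(6))
    for i in range(4):
        rows.append(profile_b + 0.05 * rng.standard_normal(6))
    genes = [f"g{i}" for i in range(8)]
    samples = [f"s{i}" for i in range(6)]
    groups = pd.Series(
        ["responder"] * 2 + ["nonresponder"] * 2 + ["untreated"] * 2, index=samples
    )
    return ExpressionDataset(pd.DataFrame(rows, index=genes, columns=samples), groups)


@pytest.fixture(scope="session")
def default_artifacts():
    """One full simulation at the default study design (seed 1)."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small fast configuration for Monte-Carlo style checks."""
    return SimulationConfig(
        n_genes=60,
        n_modules=2,
        module_size=20,
        n_drugs=5,
        n_reversers=1,
        n_probes=300,
        n_decoy_regulators=4,
        seed=0,
    )
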