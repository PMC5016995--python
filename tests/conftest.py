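import numpy as np
import pandas as pd
import pytest

from prognosig import ExpressionMatrix, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Compact study with planted signal, contamination and censoring."""
    return simulate_study(SimulationConfig(
        n_genes=300, n_per_group=(20, 20), n_signal_genes=8,
        contamination_rate=0.05, seed=123))


@pytest.fixture(scope="session")
def clean_null_study():
    """No differential signal, no contamination."""
    return simulate_study(SimulationConfig(
        n_genes=400, n_per_group=(20, 20), n_signal_genes=0,
        effect_size=0.0, contamination_rate=0.0, seed=321))


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(7)
    vals = pd.DataFrame(
        rng.uniform(10, 1000, size=(50, 10)),
        index=[f"g{i}" for i in range(50)],
        columns=[f"s{i}" for i in range(10)],
    )
    return ExpressionMatrix(vals, state="raw")


@pytest.fixture()
def toy_survival():
    """Deterministic 20-sample survival set with two informative covariates."""
    rng = np.random.default_rng(3)
    n = 20
    x = rng.standard_normal((n, 2))
    eta = x @ np.array([0.5, -0.3])
    time = rng.exponential(np.exp(-eta)) * 24
    event = (rng.random(n) < 0.8).astype(int)
    from prognosig import SurvivalData

    return SurvivalData(time, event, pd.DataFrame(x, columns=["a", "b"]))
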