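import numpy as np
import pandas as pd
import pytest

from inosim import (
    PopulationSpec,
    SimulationConfig,
    calibrate,
    get_backend,
    sample_population,
    sigmoid,
)
from inosim.drug_block import DoseResponseTable
from inosim.io import load_calibration_ranges


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def backend():
    return get_backend("surrogate")


@pytest.fixture(scope="session")
def calibration_ranges():
    return load_calibration_ranges()


@pytest.fixture(scope="session")
def small_population(backend, config, calibration_ranges):
    """A compact calibrated population shared across tests (seed 7)."""
    models = sample_population(PopulationSpec(n_models=80, seed=7))
    return calibrate(models, calibration_ranges, backend, config)


def make_synthetic_table(truth, eftpc_max=0.1, n_replicates=323,
                         sigma=0.02, seed=0, multipliers=None,
                         name="synthetic") -> DoseResponseTable:
    """Dose-response observations drawn from a known sigmoid plus iid noise,
    mimicking a population run (same replicates at every concentration)."""
    m = 10.0 ** np.arange(-1.0, 2.01, 0.25) if multipliers is None \
        else np.asarray(multipliers, float)
    grid = m * eftpc_max
    rng = np.random.default_rng(seed)
    rows = []
    for c in grid:
        mu = sigmoid(c, truth)
        y = mu + rng.normal(0.0, sigma, size=n_replicates)
        rows.extend(
            {"model_id": i, "concentration": c, "multiplier": c / eftpc_max,
             "at_fraction": yy, "flagged": False}
            for i, yy in enumerate(y)
        )
    return DoseResponseTable(compound=name, eftpc_max=eftpc_max, grid=grid,
                             df=pd.DataFrame(rows))
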