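import numpy as np
import pytest

from lwfgsim import DemographicParams, ScenarioGrid, run_grid


@pytest.fixture(scope="session")
def default_params() -> DemographicParams:
    return DemographicParams()


@pytest.fixture(scope="session")
def small_grid_records():
    """A reduced sweep (coarse offtake axis, 3 return rates, 40 replicates)
    spanning the zero-growth frontier at every phi, shared across tests."""
    grid = ScenarioGrid(
        offtake_values=range(0, 5001, 250),
        phi_values=(0.78, 0.81, 0.84),
        replicates=40,
        base_seed=2024,
    )
    return grid, run_grid(grid, DemographicParams())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
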