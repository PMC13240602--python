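import numpy as np
import pytest

from borealcarbon import PftParams
from borealcarbon.model_core import DOMAIN_PROTOCOL, run_spinup
from borealcarbon.synthetic_data import ScenarioSpec, gen_forcing, \
    gen_scenarios


@pytest.fixture(scope="session")
def params():
    return PftParams()


@pytest.fixture(scope="session")
def quiet_forcing():
    """Stationary climate, flat preindustrial CO2, no disturbance."""
    return gen_forcing(range(1750, 2024), 1, seed=11,
                       ar1_sd=0.0, warming_rate=0.0,
                       co2_1900=277.0, co2_end=277.0)


@pytest.fixture(scope="session")
def trend_forcing():
    """Warming climate and rising CO2, 2 cells, no disturbance."""
    return gen_forcing(range(1750, 2024), 2, seed=7)


@pytest.fixture(scope="session")
def equilibrium(params, quiet_forcing):
    return run_spinup(params, quiet_forcing, 0)


@pytest.fixture(scope="session")
def small_ensemble(params):
    """Four-scenario ensemble on a small 4-cell domain."""
    spec = ScenarioSpec(n_cells=4, seed=5)
    return spec, gen_scenarios(spec)


@pytest.fixture(scope="session")
def domain_protocol():
    return DOMAIN_PROTOCOL
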