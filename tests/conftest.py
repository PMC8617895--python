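import numpy as np
import pytest

from pullfold import (
    BARNASE_BE_DEFAULTS,
    ElasticParams,
    SimulationConfig,
    ThermalContext,
)


@pytest.fixture(scope="session")
def ctx() -> ThermalContext:
    return ThermalContext()


@pytest.fixture(scope="session")
def barnase() -> ElasticParams:
    return ElasticParams.barnase()


@pytest.fixture(scope="session")
def be_params():
    return BARNASE_BE_DEFAULTS


@pytest.fixture()
def sim_cfg(barnase):
    return SimulationConfig(be=BARNASE_BE_DEFAULTS, elastic=barnase, seed=11)


@pytest.fixture(scope="session")
def wlc_grid_oracle(ctx):
    """Brute-force inversion of the WLC interpolation formula on a dense
    z grid, independent of the package's bisection path."""

    def invert(f: float, persistence_length: float = 0.8) -> float:
        z = np.linspace(1e-9, 1 - 1e-9, 10_000)
        force = ctx.kBT / (4 * persistence_length) * ((1 - z) ** -2 + 4 * z - 1)
        return float(np.interp(f, force, z))

    return invert
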