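import numpy as np
import pytest

from coupledpk import make_scenario, simulate
from coupledpk.pso import PSOConfig


@pytest.fixture(scope="session")
def baseline_system():
    return make_scenario()


@pytest.fixture(scope="session")
def uncoupled_traj(baseline_system):
    """Dense reference simulation of the uncoupled baseline scenario."""
    return simulate(baseline_system.uncoupled(), horizon=40.0, output_step=0.001)


@pytest.fixture(scope="session")
def fast_pso():
    """Small swarm budget used by the test studies; the deterministic local
    polish makes the optimum insensitive to the swarm budget."""
    return PSOConfig(n_particles=24, max_iter=120, patience=25, seed=11)


@pytest.fixture(autouse=True)
def _quiet_numpy():
    with np.errstate(all="ignore"):
        yield
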