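import numpy as np
import pytest

import bsfopt as B

HOURLY = 1.0 / 24.0


@pytest.fixture(scope="session")
def params():
    return B.ModelParameters()


@pytest.fixture(scope="session")
def hard():
    return B.NumericsConfig(hard_mode=True)


@pytest.fixture(scope="session")
def benchmark_traj(params):
    """Standard 14-d constant-environment run (25 °C, 16 h/d)."""
    return B.simulate(params, B.ControlSchedule.constant(25.0, 16.0, 14.0))


@pytest.fixture(scope="session")
def benchmark_traj_40d(params):
    """Extended run for die-off metrics."""
    return B.simulate(params, B.ControlSchedule.constant(25.0, 16.0, 40.0))


@pytest.fixture(scope="session")
def benchmark_traj_40d_hard(params, hard):
    """Extended run with exact switches (sharp conservation properties)."""
    return B.simulate(params, B.ControlSchedule.constant(25.0, 16.0, 40.0), cfg=hard)


@pytest.fixture(scope="session")
def standard_ocp_hourly(params):
    """Standard scenario at the operational hourly control grid."""
    return B.solve_ocp(params, B.OCPConfig(dt_control=HOURLY))


@pytest.fixture(scope="session")
def standard_ocp_2h(params):
    return B.solve_ocp(params, B.OCPConfig(dt_control=2 * HOURLY))


@pytest.fixture(scope="session")
def q_sweep_4h(params):
    """Optimized egg mass for increasing egg-reward weight, coarse grid."""
    out = {}
    for Q in (0.0, 12.0, 120.0):
        out[Q] = B.solve_ocp(params, B.OCPConfig(Q=Q, dt_control=4 * HOURLY))
    return out


@pytest.fixture(scope="session")
def light_only_2h(params):
    return B.run_scenario("light_only", params, dt_control=2 * HOURLY)


@pytest.fixture(scope="session")
def high_penalty_2h(params):
    return B.run_scenario("high_penalty", params, dt_control=2 * HOURLY)


@pytest.fixture(scope="session")
def delayed_4h(params):
    return B.run_scenario("delayed", params, dt_control=4 * HOURLY)
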