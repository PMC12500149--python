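import numpy as np
import pytest

from braincsp import (BrainModel, CSPConfig, ParameterSet, ScenarioProtocol,
                      integrate_scenario, scan_exhausted_modes,
                      segment_periods, steady_state)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def baseline(params) -> np.ndarray:
    """Newton-refined baseline steady state."""
    return steady_state(params)


@pytest.fixture(scope="session")
def model(params) -> BrainModel:
    return BrainModel(params, ScenarioProtocol())


@pytest.fixture(scope="session")
def trajectory(params, baseline):
    """The full activation scenario, 0-10000 s."""
    return integrate_scenario(ScenarioProtocol(), params,
                              initial_state=baseline)


@pytest.fixture(scope="session")
def mode_scan(trajectory):
    """(times, M) with the calibrated default criterion."""
    return scan_exhausted_modes(trajectory, CSPConfig())


@pytest.fixture(scope="session")
def period_table(mode_scan):
    times, M = mode_scan
    return segment_periods(times, M)


@pytest.fixture()
def random_states(baseline):
    """Seeded random physiological states around the baseline."""
    rng = np.random.default_rng(17)
    A = ParameterSet().A_tot

    def make(n):
        states = baseline[None, :] * rng.uniform(0.85, 1.15, (n, 29))
        states[:, 16:18] = np.clip(states[:, 16:18], 0.5, 0.98 * A)
        return states

    return make
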