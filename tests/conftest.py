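import numpy as np
import pytest

from mitodyn.assembly import ModelSystem
from mitodyn.config import ModelConfig, generate_default_fixture
from mitodyn.experiments import solve_steady_state


@pytest.fixture(scope="session")
def fixture_config() -> ModelConfig:
    """The bundled calibrated parameter set."""
    return generate_default_fixture()


@pytest.fixture(scope="session")
def reference_system(fixture_config) -> ModelSystem:
    return ModelSystem(fixture_config)


@pytest.fixture(scope="session")
def reference_result(reference_system):
    """The solved reference steady state (load multiplier 1)."""
    res = solve_steady_state(reference_system, 1.0,
                             reference_system.initial_state(), pre_time=0.0)
    assert res.converged, "reference steady state must converge"
    return res


@pytest.fixture(scope="session")
def reference_state(reference_result) -> np.ndarray:
    return reference_result.state
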