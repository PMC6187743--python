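import numpy as np
import pytest

from branchrd.model_core import (
    InitialConditionSpec,
    ModelParameters,
    SimulationDomain,
    StepperConfig,
)


@pytest.fixture
def params():
    """Baseline side-branching parameter set."""
    return ModelParameters()


@pytest.fixture
def tip_params():
    """Tip-bifurcation parameter set (fast activator/inhibitor turnover)."""
    return ModelParameters(mu=0.8, nu=0.08)


@pytest.fixture
def small_domain():
    return SimulationDomain(16, 14, 12)


@pytest.fixture
def seeded_ic():
    return InitialConditionSpec(rng_seed=42)


@pytest.fixture
def quick_stepper():
    return StepperConfig(dt=0.5, n_steps=50)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
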