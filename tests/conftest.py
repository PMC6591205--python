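import numpy as np
import pytest

from pd1sim import ModelParameters, PKParameters
from pd1sim.engine import Scenario
from pd1sim.pk import build_regimen


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def pk() -> PKParameters:
    return PKParameters()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def short_treated_scenario() -> Scenario:
    """Biweekly dosing over a quarter year with weekly sampling (fast)."""
    return Scenario(label="short_treated",
                    regimen=build_regimen(3.0, 14.0, 14.0, 6),
                    horizon=90.0,
                    output_grid=np.arange(0.0, 91.0, 7.0))


@pytest.fixture(scope="session")
def short_untreated_scenario() -> Scenario:
    return Scenario(label="short_none", horizon=90.0,
                    output_grid=np.arange(0.0, 91.0, 7.0))
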