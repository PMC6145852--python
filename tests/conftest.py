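import numpy as np
import pytest

from vnccpg.circuit import (
    ParameterRanges,
    build_default_architecture,
    expand_genotype,
)
from vnccpg.dynamics import SimulationConfig
from vnccpg.synthetic import (
    make_constant_instance,
    make_damped_oscillator,
    make_reference_oscillator,
    sample_genotype,
)


@pytest.fixture(scope="session")
def arch():
    return build_default_architecture()


@pytest.fixture(scope="session")
def ranges():
    return ParameterRanges()


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def constant_instance():
    return make_constant_instance()


@pytest.fixture(scope="session")
def reference():
    """Frozen criteria-passing oscillator fixture."""
    return make_reference_oscillator()


@pytest.fixture(scope="session")
def damped():
    """Frozen damped-oscillation fixture (fails the long-horizon re-filter)."""
    return make_damped_oscillator()


@pytest.fixture
def random_instance():
    return expand_genotype(sample_genotype(11))
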