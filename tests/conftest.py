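import numpy as np
import pytest

from corm import (
    InitialCondition,
    build_corm,
    build_flux_graph,
    nominal_parameters,
    simulate,
)
from corm.kinetics import CompiledNetwork, ParameterSet


@pytest.fixture(scope="session")
def network():
    return build_corm()


@pytest.fixture(scope="session")
def compiled(network):
    return CompiledNetwork(network)


@pytest.fixture(scope="session")
def nominal():
    return nominal_parameters()


@pytest.fixture(scope="session")
def zero_params(network):
    return ParameterSet({name: 0.0 for name in network.parameter_names}, name="all_zero")


@pytest.fixture(scope="session")
def traj_both(network, nominal, compiled):
    """Nominal run with both substrates present."""
    return simulate(network, nominal, InitialCondition(0.015, 8.0, 8.0), compiled=compiled)


@pytest.fixture(scope="session")
def traj_aa_only(network, nominal, compiled):
    return simulate(network, nominal, InitialCondition(0.015, 16.0, 0.0), compiled=compiled)


@pytest.fixture(scope="session")
def graph_both(traj_both, network):
    return build_flux_graph(traj_both, network)


@pytest.fixture(scope="session")
def graph_aa_only(traj_aa_only, network):
    return build_flux_graph(traj_aa_only, network)
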