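import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pulseheat as ph
from pulseheat.meshing import build_grid
from pulseheat.scenario import GridSpec

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_scenario():
    return ph.default_scenario()


@pytest.fixture(scope="session")
def coarse_grid(default_scenario):
    """Coarse far-field grid of the reference geometry, shared across tests."""
    return build_grid(default_scenario.geometry, GridSpec.coarse())


@pytest.fixture(scope="session")
def coarse_field(default_scenario, coarse_grid):
    """Self-consistent 4 kV field solution on the coarse grid."""
    from pulseheat.electrostatics import porate_fixed_point
    s = default_scenario
    return porate_fixed_point(coarse_grid, s.materials, s.conductivity,
                              s.protocol.voltage, 37.0, s.solver)
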