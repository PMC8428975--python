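import numpy as np
import pytest

from gliasim.network_builder import (
    ConnectivityParams,
    connect_network,
    place_cells,
)
from gliasim.simulate import SimulationParams, run_simulation


@pytest.fixture(scope="session")
def small_topology():
    """A 60-neuron / 24-astrocyte network for fast dynamical tests."""
    npos, apos = place_cells(60, 24, volume=(400.0, 400.0, 10.0), seed=7)
    return connect_network(npos, apos, ConnectivityParams(), seed=8)


@pytest.fixture(scope="session")
def small_trace(small_topology):
    params = SimulationParams(duration_s=60.0, seed=9)
    return run_simulation(small_topology, params)


@pytest.fixture(scope="session")
def default_topology():
    """Full-size network at the study's default geometry (250 + 107 cells)."""
    npos, apos = place_cells(250, 107, seed=1)
    return connect_network(npos, apos, ConnectivityParams(), seed=2)
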