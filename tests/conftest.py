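import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vasowave import (BifurcationSpec, SimulationConfig, assemble_network,
                      build_bifurcation_mesh, build_cell_lattice,
                      reference_params, run_simulation)
from vasowave.agonist import uniform_atp_map
from vasowave.fixtures import patch_lattice


@pytest.fixture(scope="session")
def params():
    return reference_params()


@pytest.fixture(scope="session")
def mesh80():
    """A small 80-degree bifurcation (4 x 8 domains per segment)."""
    return build_bifurcation_mesh(BifurcationSpec.from_angle(80.0),
                                  domains=(4, 8))


@pytest.fixture(scope="session")
def lattice80(mesh80):
    return build_cell_lattice(mesh80)


@pytest.fixture(scope="session")
def one_domain():
    """The reference 288-cell quadrilateral-domain lattice."""
    return patch_lattice(1, 1)


def _patch_run(params, atp_level, duration=500.0, seed=1):
    lat = patch_lattice(1, 1)
    system = assemble_network(lat, uniform_atp_map(lat.n_ec, atp_level), params)
    cfg = SimulationConfig(duration=duration, record_interval=1.0, seed=seed)
    return lat, run_simulation(system, cfg)


@pytest.fixture(scope="session")
def apex_run(params):
    """500 s, one domain, uniform apex-level (1 uM) ATP."""
    return _patch_run(params, 1.0)


@pytest.fixture(scope="session")
def seam_run(params):
    """500 s, one domain, uniform seam-level (0.2 uM) ATP."""
    return _patch_run(params, 0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
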