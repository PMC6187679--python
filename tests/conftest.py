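import numpy as np
import pytest

from spherotrap.geometry import build_trap_geometry, default_config
from spherotrap.meshing import generate_mesh
from spherotrap.flow import solve_flow


@pytest.fixture(scope="session")
def u500_test_mesh():
    """Integrated U trap, D = 500 µm, few-thousand-cell test mesh."""
    return generate_mesh(build_trap_geometry(default_config("integrated_u", 500)),
                         "test")


@pytest.fixture(scope="session")
def u500_test_flow(u500_test_mesh):
    return solve_flow(u500_test_mesh, 5.0, mode="stokes")


@pytest.fixture(scope="session")
def duct_mesh():
    """Empty straight channel (no trap, no spheroid) for duct-flow oracles."""
    solid = build_trap_geometry(default_config("integrated_u", 500),
                                include_trap=False, include_spheroid=False)
    return generate_mesh(solid, "coarse")


@pytest.fixture(scope="session")
def duct_flow(duct_mesh):
    return solve_flow(duct_mesh, 5.0, mode="stokes")


@pytest.fixture(scope="session")
def bath_coarse_mesh():
    """Suspended spheroid in mid-channel, no trap: 1D cross-check geometry."""
    cfg = default_config("integrated_u", 500,
                         spheroid_center=(500.0, 500.0, 1000.0),
                         contact_embed=0.0)
    return generate_mesh(build_trap_geometry(cfg, include_trap=False), "coarse",
                         refine_sphere_box=True)


def rel_err(a, b):
    return abs(a - b) / max(abs(b), 1e-300)
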