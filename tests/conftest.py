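import numpy as np
import pytest

from rspm.grid import HexLattice
from rspm.motility import DEFAULT_FORCE_MODEL
from rspm.surface import PatchGrid, PhysicsConstants, RoughnessParams, build_grid


@pytest.fixture(scope="session")
def phys():
    return PhysicsConstants()


@pytest.fixture(scope="session")
def force_model():
    return DEFAULT_FORCE_MODEL


@pytest.fixture(scope="session")
def rough():
    """Reference roughness: the ceramic-plate surface Phi=0.4, D=1.8."""
    return RoughnessParams(Phi=0.4, D=1.8)


@pytest.fixture
def small_grid():
    return build_grid(8, 8, RoughnessParams(Phi=0.5, D=1.8), seed=42,
                      porosity="uniform")


def uniform_patch_grid(n=8, phi=0.9, pc=0.3, D=1.8, l_p=5e-4):
    """A homogeneous domain: every patch identical (handy for exact oracles)."""
    lattice = HexLattice(n, n, l_p)
    return PatchGrid(
        lattice=lattice,
        roughness=RoughnessParams(Phi=phi, D=D),
        Phi_field=np.full((n, n), phi),
        pc_field=np.full((n, n), pc),
    )
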