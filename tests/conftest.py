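import numpy as np
import pytest

from mcfsim.fibril_geometry import (
    BeadTopology,
    Box,
    FibrilSpec,
    build_idealized_fibril,
)
from mcfsim.forcefield import default_forcefield
from mcfsim.mineralizer import MassModel


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture(scope="session")
def masses():
    return MassModel()


@pytest.fixture(scope="session")
def small_spec():
    """A fast ~300-bead fibril (short molecules, small D) for MD tests."""
    return FibrilSpec(
        diameter_nm=5.0, length_periods=5, D_nm=13.0,
        bead_spacing_A=14.0, beads_per_molecule=44,
    )


@pytest.fixture(scope="session")
def small_fibril(small_spec):
    return build_idealized_fibril(small_spec)


@pytest.fixture(scope="session")
def mini_spec():
    """An even smaller open-ended fibril (~130 beads) for oracle tests."""
    return FibrilSpec(
        diameter_nm=4.0, length_periods=5, D_nm=6.7,
        bead_spacing_A=14.0, beads_per_molecule=19, periodic_z=False,
    )


@pytest.fixture(scope="session")
def mini_fibril(mini_spec):
    return build_idealized_fibril(mini_spec)


def make_dimer(r=14.0, axis=2):
    """Two bonded collagen beads separated by r along an axis."""
    pos = np.zeros((2, 3))
    pos[1, axis] = r
    return BeadTopology(
        positions=pos,
        species=np.zeros(2, np.uint8),
        molecule_id=np.zeros(2, np.int64),
        bonds=np.array([[0, 1]], np.int64),
        angles=np.empty((0, 3), np.int64),
        box=Box(np.full(3, -100.0), np.full(3, 100.0),
                np.array([False, False, False])),
    )


@pytest.fixture
def dimer():
    return make_dimer()
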