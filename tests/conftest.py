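import numpy as np
import pytest

from clusteradapt.lattice import LatticeGeometry, build_lattice
from clusteradapt.mwc import calibrate
from clusteradapt.reaction_system import CopyNumbers, RateSet, VariantFlags


@pytest.fixture(scope="session")
def small_geometry():
    """A 2x2-unit lattice (72 dimers, 12 complexes)."""
    return build_lattice(2, 2)


@pytest.fixture(scope="session")
def reduced_geometry():
    """The 8x8-unit reduced production lattice (1152 dimers)."""
    return build_lattice(8, 8)


@pytest.fixture(scope="session")
def mwc_params():
    return calibrate()


@pytest.fixture(scope="session")
def two_dimer_geometry():
    """Synthetic single-complex geometry with two mutually adjacent dimers.

    Not buildable by the lattice constructor (whose complexes have six
    dimers); used only to keep exact-enumeration oracles tractable.
    """
    return LatticeGeometry(
        n_dimers=2,
        neighbors=np.array([[1, -1, -1, -1, -1, -1], [0, -1, -1, -1, -1, -1]], dtype=np.int32),
        n_neighbors=np.array([1, 1], dtype=np.int32),
        complex_of=np.array([0, 0], dtype=np.int32),
        complexes=np.array([[0, 1]], dtype=np.int32),
        units=None,
    )


@pytest.fixture(scope="session")
def slow_rates():
    """A slowed-down rate set keeping micro-model state spaces well mixed."""
    return RateSet(
        k_t_bind_r=0.5, k_t_bind_b=0.5,
        k_m_bind_bulk_r=0.2, k_m_bind_bulk_b=0.2,
        k_t_unbind_r=1.0, k_t_unbind_b=1.0,
        k_m_bind_local_r=5.0, k_m_bind_local_b=5.0,
        k_t_bind_local_r=5.0, k_t_bind_local_b=5.0,
        k_m_unbind_r=2.0, k_m_unbind_b=2.0,
        k_cat_r=1.0, k_cat_b=1.0,
        a_p=2.0, d_p=1.0,
    )
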