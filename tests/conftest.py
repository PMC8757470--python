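import numpy as np
import pytest

from stochgas.gas_constraints import (
    GASPartition,
    LocalConstraints,
    band_constraints,
    build_supergroup_table,
)
from stochgas.hamiltonian import Determinant, synthetic_integrals


@pytest.fixture(scope="session")
def rand6():
    """Random (6e, 6o) integral table with a dominant reference."""
    return synthetic_integrals(6, 11, scale=0.2)


@pytest.fixture(scope="session")
def cas6():
    part = GASPartition([6])
    table = build_supergroup_table(part, LocalConstraints([0], [12]), 6)
    return part, table


@pytest.fixture(scope="session")
def gas33():
    """Two connected spaces of three orbitals, one interspace excitation."""
    part = GASPartition([3, 3])
    constraints = band_constraints(part, [3, 3], 1, "local")
    table = build_supergroup_table(part, constraints, 6)
    return part, table


@pytest.fixture(scope="session")
def ref6():
    return Determinant.from_orbitals([0, 1, 2], [0, 1, 2])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
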