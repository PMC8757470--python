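"""Reduced density matrices, spin expectation, pseudonatural orbitals.

Computes exact 1- and 2-RDMs from an eigenvector, reconstructs the energy
from them, evaluates <S^2> by the spin-flip contraction, and diagonalizes
the per-space blocks of the 1-RDM.  For disconnected GAS spaces the 1-RDM
is block diagonal, so pseudonatural and natural orbitals coincide.
"""

import numpy as np

from stochgas.gas_constraints import (
    GASPartition,
    build_supergroup_table,
    disconnected_constraints,
)
from stochgas.hamiltonian import exact_diagonalization, synthetic_integrals
from stochgas.rdm import (
    energy_from_rdms,
    exact_rdms,
    pseudonatural_orbitals,
    spin_expectation,
)

integrals = synthetic_integrals(6, seed=11, scale=0.2)
part = GASPartition([3, 3])
table = build_supergroup_table(part, disconnected_constraints([4, 2]), 6)
sol = exact_diagonalization(part, integrals, table, m_s=0)
one, two = exact_rdms(sol, 6)

print(f"exact energy:            {sol.energy:.8f}")
print(f"energy from (h, g, RDMs): {energy_from_rdms(integrals, one, two):.8f}")
s2, s = spin_expectation(one, two)
print(f"<S^2> = {s2:.6f}  ->  s = {s:.3f}")

off_block = np.abs(one.total[:3, 3:]).max()
print(f"largest interspace 1-RDM element: {off_block:.2e} "
      "(disconnected spaces: identically zero)")

_, occs = pseudonatural_orbitals(one, part)
for i, block in enumerate(occs):
    print(f"space {i} pseudonatural occupations: "
          + " ".join(f"{v:.4f}" for v in block)
          + f"  (sum {block.sum():.4f})")
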