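"""Integrals, Slater–Condon matrix elements, and exact diagonalization.

Conventions
-----------
* Spatial orbitals are 0-based.  Spin orbitals are ordered alpha block then
  beta block: alpha p -> p, beta p -> n + p.  The fermionic phase of an
  excitation is the parity of occupied spin orbitals crossed when operators
  are applied in this fixed ordering.
* Two-electron integrals ``g`` use chemists' notation ``(ij|kl)`` with the
  full 8-fold permutational symmetry, matching the FCIDUMP convention.
* Point-group symmetry is ignored (treated as C1); symmetry labels in
  FCIDUMP files are accepted but not exploited.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .gas_constraints import (
    GASPartition,
    SupergroupTable,
    supergroup_of_determinant,
)
from .hilbert import SpinSector, enumerate_determinants


@dataclass(frozen=True, order=True)
class Determinant:
    """Slater determinant as alpha/beta occupation bit-vectors (spatial)."""

    alpha: int
    beta: int

    def n_alpha(self) -> int:
        return self.alpha.bit_count()

    def n_beta(self) -> int:
        return self.beta.bit_count()

    def n_elec(self) -> int:
        return self.n_alpha() + self.n_beta()

    def spin_orbitals(self, n_orb: int) -> int:
        """Combined occupation over spin orbitals (alpha block then beta)."""
        return self.alpha | (self.beta << n_orb)

    def occupied_alpha(self) -> list[int]:
        return _bits(self.alpha)

    def occupied_beta(self) -> list[int]:
        return _bits(self.beta)

    @classmethod
    def from_spin_orbitals(cls, occ: int, n_orb: int) -> "Determinant":
        mask = (1 << n_orb) - 1
        return cls(occ & mask, occ >> n_orb)

    @classmethod
    def from_orbitals(
        cls, alpha_orbs: Sequence[int], beta_orbs: Sequence[int]
    ) -> "Determinant":
        a = b = 0
        for p in alpha_orbs:
            a |= 1 << p
        for p in beta_orbs:
            b |= 1 << p
        return cls(a, b)


def _bits(x: int) -> list[int]:
    out = []
    while x:
        low = x & -x
        out.append(low.bit_length() - 1)
        x ^= low
    return out


@dataclass
class IntegralTable:
    """Core energy, one-electron ``h`` and two-electron ``g`` integrals."""

    core_energy: float
    h: np.ndarray
    g: np.ndarray
    n_elec: Optional[int] = None
    ms2: Optional[int] = None

    @property
    def n_orb(self) -> int:
        return self.h.shape[0]

    def check_symmetry(self, tol: float = 1e-12) -> None:
        h, g = self.h, self.g
        if not np.allclose(h, h.T, atol=tol):
            raise ValueError("one-electron integrals are not symmetric")
        for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
            if not np.allclose(g, g.transpose(perm), atol=tol):
                raise ValueError(
                    "two-electron integrals violate 8-fold permutational symmetry"
                )


def symmetrize_g(g: np.ndarray) -> np.ndarray:
    """Average a 4-index tensor over the 8 chemists'-notation permutations."""
    out = np.zeros_like(g)
    for perm in (
        (0, 1, 2, 3),
        (1, 0, 2, 3),
        (0, 1, 3, 2),
        (1, 0, 3, 2),
        (2, 3, 0, 1),
        (3, 2, 0, 1),
        (2, 3, 1, 0),
        (3, 2, 1, 0),
    ):
        out += g.transpose(perm)
    return out / 8.0


# ---------------------------------------------------------------------------
# FCIDUMP I/O
# ---------------------------------------------------------------------------

def write_fcidump(table: IntegralTable, path, tol: float = 1e-14) -> None:
    """Write a Molpro-style FCIDUMP (canonical representatives only)."""
    n = table.n_orb
    n_elec = table.n_elec if table.n_elec is not None else 0
    ms2 = table.ms2 if table.ms2 is not None else 0
    with open(path, "w") as fh:
        fh.write(f"&FCI NORB={n},NELEC={n_elec},MS2={ms2},\n")
        fh.write("  ORBSYM=" + ",".join(["1"] * n) + ",\n")
        fh.write("  ISYM=1,\n")
        fh.write("&END\n")
        for i in range(n):
            for j in range(i + 1):
                for k in range(i + 1):
                    lmax = j if k == i else k
                    for l in range(lmax + 1):
                        v = table.g[i, j, k, l]
                        if abs(v) > tol:
                            fh.write(
                                f"{v:23.16E} {i + 1:4d} {j + 1:4d} {k + 1:4d} {l + 1:4d}\n"
                            )
        for i in range(n):
            for j in range(i + 1):
                v = table.h[i, j]
                if abs(v) > tol:
                    fh.write(f"{v:23.16E} {i + 1:4d} {j + 1:4d}    0    0\n")
        fh.write(f"{table.core_energy:23.16E}    0    0    0    0\n")


def read_fcidump(path) -> IntegralTable:
    """Read an FCIDUMP file, completing the 8-fold symmetry of ``g``."""
    header_lines: list[str] = []
    data_lines: list[str] = []
    with open(path) as fh:
        in_header = True
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if in_header:
                header_lines.append(line)
                upper = line.upper()
                if "&END" in upper or upper.endswith("/"):
                    in_header = False
                continue
            data_lines.append(line)
    header = " ".join(header_lines)
    m = re.search(r"NORB\s*=\s*(\d+)", header, re.IGNORECASE)
    if not m:
        raise ValueError("malformed FCIDUMP header: NORB missing")
    n = int(m.group(1))
    m = re.search(r"NELEC\s*=\s*(\d+)", header, re.IGNORECASE)
    n_elec = int(m.group(1)) if m else None
    m = re.search(r"MS2\s*=\s*(-?\d+)", header, re.IGNORECASE)
    ms2 = int(m.group(1)) if m else None

    h = np.zeros((n, n))
    g = np.zeros((n, n, n, n))
    core = 0.0
    for line in data_lines:
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"malformed FCIDUMP line: {line!r}")
        v = float(parts[0].replace("D", "E").replace("d", "e"))
        i, j, k, l = (int(p) for p in parts[1:])
        if any(idx > n or idx < 0 for idx in (i, j, k, l)):
            raise ValueError(f"orbital index out of range in line: {line!r}")
        if i == j == k == l == 0:
            core = v
        elif k == l == 0:
            if i == 0 or j == 0:
                raise ValueError(f"malformed one-electron entry: {line!r}")
            h[i - 1, j - 1] = v
            h[j - 1, i - 1] = v
        else:
            if 0 in (i, j, k, l):
                raise ValueError(f"malformed two-electron entry: {line!r}")
            a, b, c, d = i - 1, j - 1, k - 1, l - 1
            for x, y, z, w in (
                (a, b, c, d),
                (b, a, c, d),
                (a, b, d, c),
                (b, a, d, c),
                (c, d, a, b),
                (d, c, a, b),
                (c, d, b, a),
                (d, c, b, a),
            ):
                g[x, y, z, w] = v
    return IntegralTable(core, h, g, n_elec=n_elec, ms2=ms2)


# ---------------------------------------------------------------------------
# Slater–Condon matrix elements
# ---------------------------------------------------------------------------

def _apply_sign(occ: int, annihilate: Sequence[int], create: Sequence[int]):
    """Sign of applying annihilation then creation operators to ``occ``.

    Returns (sign, new_occ); sign 0 when the string annihilates the state.
    """
    sign = 1
    for p in annihilate:
        bit = 1 << p
        if not occ & bit:
            return 0, occ
        if (occ & (bit - 1)).bit_count() & 1:
            sign = -sign
        occ ^= bit
    for p in create:
        bit = 1 << p
        if occ & bit:
            return 0, occ
        if (occ & (bit - 1)).bit_count() & 1:
            sign = -sign
        occ |= bit
    return sign, occ


def _g_so(g: np.ndarray, n: int, x: int, y: int, z: int, w: int) -> float:
    """Chemists' two-electron integral over spin orbitals, with spin deltas."""
    if (x < n) != (y < n) or (z < n) != (w < n):
        return 0.0
    return g[x % n, y % n, z % n, w % n]


def matrix_element(
    d_i: Determinant, d_j: Determinant, table: IntegralTable
) -> float:
    """Slater–Condon value ``<D_j| H |D_i>`` including the fermionic phase.

    Zero beyond double excitations; ``core_energy`` is included on the
    diagonal.  Both determinants must lie in the same spin sector.
    """
    if d_i.n_alpha() != d_j.n_alpha() or d_i.n_beta() != d_j.n_beta():
        raise ValueError("determinants are in different spin sectors")
    n = table.n_orb
    occ_i = d_i.spin_orbitals(n)
    occ_j = d_j.spin_orbitals(n)
    diff = occ_i ^ occ_j
    level = diff.bit_count() // 2
    if level == 0:
        return diagonal_element(d_i, table)
    if level > 2:
        return 0.0
    holes = _bits(diff & occ_i)
    parts = _bits(diff & occ_j)
    h, g = table.h, table.g
    if level == 1:
        (p,), (r,) = holes, parts
        sign, _ = _apply_sign(occ_i, [p], [r])
        val = h[p % n, r % n] if (p < n) == (r < n) else 0.0
        for u in _bits(occ_i & ~(1 << p)):
            val += _g_so(g, n, p, r, u, u) - _g_so(g, n, p, u, u, r)
        return sign * val
    (p, q), (r, s) = holes, parts
    sign, _ = _apply_sign(occ_i, [p, q], [s, r])
    return sign * (_g_so(g, n, p, r, q, s) - _g_so(g, n, p, s, q, r))


def diagonal_element(det: Determinant, table: IntegralTable) -> float:
    n = table.n_orb
    occ = _bits(det.spin_orbitals(n))
    h, g = table.h, table.g
    val = table.core_energy
    for u in occ:
        val += h[u % n, u % n]
    for a, u in enumerate(occ):
        for v in occ[a + 1 :]:
            val += _g_so(g, n, u, u, v, v) - _g_so(g, n, u, v, v, u)
    return val


def gas_masked_element(
    d_i: Determinant,
    d_j: Determinant,
    table: IntegralTable,
    sg_table: SupergroupTable,
) -> float:
    """Hamiltonian element with GAS-forbidden couplings zeroed.

    The decision depends only on the supergroup of the target determinant:
    couplings leaving the allowed supergroup set vanish, everything else is
    the unmasked element.
    """
    if not sg_table.contains(
        supergroup_of_determinant(d_j, sg_table.partition)
    ):
        return 0.0
    return matrix_element(d_i, d_j, table)


def core_hamiltonian(
    core_dets: Sequence[Determinant],
    table: IntegralTable,
    sg_table: Optional[SupergroupTable] = None,
) -> np.ndarray:
    """Dense symmetric Hamiltonian over an explicit determinant list."""
    if sg_table is not None:
        for d in core_dets:
            if not sg_table.contains(
                supergroup_of_determinant(d, sg_table.partition)
            ):
                raise ValueError("core list contains a GAS-forbidden determinant")
    dim = len(core_dets)
    mat = np.zeros((dim, dim))
    for a in range(dim):
        mat[a, a] = diagonal_element(core_dets[a], table)
        for b in range(a + 1, dim):
            v = matrix_element(core_dets[a], core_dets[b], table)
            mat[a, b] = mat[b, a] = v
    return mat


# ---------------------------------------------------------------------------
# Connected-determinant generation (shared by ED and the test oracles)
# ---------------------------------------------------------------------------

def connected_excitations(det: Determinant, n_orb: int):
    """Yield all single and double excitations within the same spin sector."""
    occ = _bits(det.spin_orbitals(n_orb))
    m = 2 * n_orb
    occ_set = set(occ)
    virt = [p for p in range(m) if p not in occ_set]
    occ_bits = det.spin_orbitals(n_orb)
    for p in occ:
        for r in virt:
            if (p < n_orb) != (r < n_orb):
                continue
            yield Determinant.from_spin_orbitals(
                occ_bits ^ (1 << p) | (1 << r), n_orb
            )
    for a, p in enumerate(occ):
        for q in occ[a + 1 :]:
            spin_pq = (p >= n_orb) + (q >= n_orb)
            for c, r in enumerate(virt):
                for s in virt[c + 1 :]:
                    if (r >= n_orb) + (s >= n_orb) != spin_pq:
                        continue
                    yield Determinant.from_spin_orbitals(
                        occ_bits ^ (1 << p) ^ (1 << q) | (1 << r) | (1 << s),
                        n_orb,
                    )


# ---------------------------------------------------------------------------
# Exact diagonalization
# ---------------------------------------------------------------------------

@dataclass
class ExactSolution:
    energy: float
    coefficients: np.ndarray
    basis: list = field(repr=False, default_factory=list)

    def coefficient_map(self) -> dict:
        return {d: c for d, c in zip(self.basis, self.coefficients)}


def build_hamiltonian_matrix(
    basis: Sequence[Determinant],
    table: IntegralTable,
    sparse: bool = True,
):
    """Hamiltonian over an enumerated basis, via excitation-driven assembly."""
    n = table.n_orb
    index = {d: a for a, d in enumerate(basis)}
    rows, cols, vals = [], [], []
    for a, det in enumerate(basis):
        rows.append(a)
        cols.append(a)
        vals.append(diagonal_element(det, table))
        for child in connected_excitations(det, n):
            b = index.get(child)
            if b is not None and b > a:
                v = matrix_element(det, child, table)
                if v != 0.0:
                    rows.extend((a, b))
                    cols.extend((b, a))
                    vals.extend((v, v))
    dim = len(basis)
    mat = scipy.sparse.coo_matrix(
        (vals, (rows, cols)), shape=(dim, dim)
    ).tocsr()
    return mat if sparse else mat.toarray()


def exact_diagonalization(
    partition: GASPartition,
    table: IntegralTable,
    sg_table: SupergroupTable,
    m_s: float,
    cap: int = 20000,
) -> ExactSolution:
    """Ground state of the (GAS-masked) Hamiltonian over the enumerated basis.

    Masking is implicit: the basis contains exactly the GAS-allowed
    determinants, and couplings out of the space never enter.  Uses a sparse
    iterative eigensolver with a dense fallback for tiny bases.
    """
    basis = enumerate_determinants(partition, sg_table, m_s, cap=cap)
    mat = build_hamiltonian_matrix(basis, table)
    dim = mat.shape[0]
    if dim == 1:
        return ExactSolution(float(mat[0, 0]), np.ones(1), basis)
    if dim <= 300:
        w, v = np.linalg.eigh(mat.toarray())
        vec = v[:, 0]
    else:
        w, v = scipy.sparse.linalg.eigsh(mat, k=1, which="SA")
        vec = v[:, 0]
    vec = vec / np.linalg.norm(vec)
    residual = np.linalg.norm(mat @ vec - w[0] * vec)
    if residual > 1e-6 * max(1.0, abs(w[0])):
        raise RuntimeError(f"eigensolver residual too large: {residual}")
    return ExactSolution(float(w[0]), vec, basis)


# ---------------------------------------------------------------------------
# Synthetic systems
# ---------------------------------------------------------------------------

def synthetic_integrals(
    n_orb: int, seed: int, scale: float = 0.1
) -> IntegralTable:
    """Random symmetry-complete integrals with a well-separated reference.

    The one-electron diagonal is dominant and ascending, so the
    lowest-orbital closed-shell determinant is a good reference; ``scale``
    sets the magnitude of all off-diagonal randomness.
    """
    rng = np.random.default_rng(seed)
    h = scale * rng.standard_normal((n_orb, n_orb))
    h = 0.5 * (h + h.T)
    h[np.diag_indices(n_orb)] = -2.0 + 0.8 * np.arange(n_orb)
    g = symmetrize_g(scale * rng.standard_normal((n_orb,) * 4))
    # Add a physical repulsive Coulomb-like diagonal.
    for p in range(n_orb):
        for q in range(n_orb):
            g[p, p, q, q] += 0.5 / (1.0 + abs(p - q))
    return IntegralTable(0.0, h, g)


def hubbard_integrals(
    L: int, U: float, t: float, periodic: bool = False
) -> IntegralTable:
    """Nearest-neighbor Hubbard chain (or ring) in the site basis."""
    h = np.zeros((L, L))
    for i in range(L - 1):
        h[i, i + 1] = h[i + 1, i] = -t
    if periodic and L > 2:
        h[0, L - 1] = h[L - 1, 0] = -t
    g = np.zeros((L,) * 4)
    for i in range(L):
        g[i, i, i, i] = U
    return IntegralTable(0.0, h, g)
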