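"""Reduced density matrices and properties derived from them.

Conventions: the spin-orbital 2-RDM is ``Gamma[P,Q,R,S] = <a+_P a+_Q a_S
a_R>`` over spin orbitals ordered alpha block then beta block; the 1-RDM is
``gamma[P,Q] = <a+_P a_Q>`` and is spin-block diagonal for states of fixed
spin projection.  Energies reconstruct as

    E = E_core + sum_PQ h_PQ gamma_PQ
        + 1/2 sum_PQRS (PR|QS) Gamma[P,Q,R,S]

with chemists' integrals.  The spin expectation uses the textbook contraction
``<S^2> = m_s (m_s + 1) + N_beta - sum_pq Gamma[p_b, q_a, q_b, p_a]``
(validated against brute-force operator construction in the test suite).

Exact RDMs contract an eigenvector over the enumerated basis; stochastic RDMs
accumulate diagonal contributions from walker populations and off-diagonal
contributions from the spawn events of the dynamics, each reweighted by its
generation probability.  The stochastic estimator shares walkers between the
bra and the ket (no replica trick), a known source of a small positive bias
documented in the methods note; hole pairs whose Hamiltonian coupling
vanishes identically (e.g. pure spin-flip blocks) are never proposed by the
heat-bath generator and are therefore not sampled — the energy functional
only touches sampled blocks, but spin expectations should use exact RDMs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gas_constraints import GASPartition
from .hamiltonian import Determinant, ExactSolution, IntegralTable, _bits

__all__ = [
    "OneRDM",
    "TwoRDM",
    "exact_rdms",
    "RdmAccumulator",
    "sampled_rdms",
    "energy_from_rdms",
    "spin_expectation",
    "pseudonatural_orbitals",
    "save_rdms",
    "load_rdms",
]


@dataclass
class OneRDM:
    """Spin-resolved one-body density over spatial orbitals."""

    gamma_a: np.ndarray
    gamma_b: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.gamma_a + self.gamma_b

    @property
    def n_orb(self) -> int:
        return self.gamma_a.shape[0]


@dataclass
class TwoRDM:
    """Spin-orbital two-body density ``Gamma[P,Q,R,S] = <a+_P a+_Q a_S a_R>``."""

    gamma: np.ndarray  # (m, m, m, m) with m = 2 n_orb

    @property
    def m(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_orb(self) -> int:
        return self.m // 2

    def spin_block(self, s1: str, s2: str) -> np.ndarray:
        """Block ``Gamma[p s1, q s2, r s1, s s2]`` as an (n,n,n,n) array."""
        n = self.n_orb
        o = {"a": slice(0, n), "b": slice(n, 2 * n)}
        return self.gamma[o[s1], o[s2], o[s1], o[s2]]


def _apply_sign(occ: int, annihilate, create):
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


def _split(gamma_so: np.ndarray, n: int) -> OneRDM:
    return OneRDM(gamma_so[:n, :n].copy(), gamma_so[n:, n:].copy())


def _expand_weights(
    diag_weight: dict[int, float],
    pair_weight: dict[tuple[int, int], float],
    n_orb: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand determinant/pair weights into (gamma_so, Gamma) contributions.

    ``pair_weight[(occ_i, occ_j)]`` multiplies ``<D_j| O |D_i>`` for every
    one- and two-body excitation operator ``O`` connecting the pair; the
    diagonal weights multiply the number operators.
    """
    m = 2 * n_orb
    gamma = np.zeros((m, m))
    Gamma = np.zeros((m, m, m, m))
    for occ, w in diag_weight.items():
        occ_list = _bits(occ)
        for P in occ_list:
            gamma[P, P] += w
            for Q in occ_list:
                if P != Q:
                    Gamma[P, Q, P, Q] += w
                    Gamma[P, Q, Q, P] -= w
    for (occ_i, occ_j), w in pair_weight.items():
        diff = occ_i ^ occ_j
        holes = _bits(diff & occ_i)
        if len(holes) == 1:
            (I,), (A,) = holes, _bits(diff & occ_j)
            s, _ = _apply_sign(occ_i, [I], [A])
            gamma[A, I] += w * s
        for R in _bits(occ_i):
            sR, occ1 = _apply_sign(occ_i, [R], [])
            for S in _bits(occ1):
                sS, occ2 = _apply_sign(occ1, [S], [])
                missing = occ_j & ~occ2
                if missing.bit_count() != 2 or (occ2 & ~occ_j):
                    continue
                PQ = _bits(missing)
                for P, Q in ((PQ[0], PQ[1]), (PQ[1], PQ[0])):
                    sQ, occ3 = _apply_sign(occ2, [], [Q])
                    sP, occ4 = _apply_sign(occ3, [], [P])
                    if occ4 == occ_j:
                        Gamma[P, Q, R, S] += w * sR * sS * sQ * sP
    return gamma, Gamma


def exact_rdms(
    solution: ExactSolution, n_orb: int, cap: int = 5000
) -> tuple[OneRDM, TwoRDM]:
    """Direct contraction of an eigenvector with the excitation operators."""
    from .hamiltonian import connected_excitations

    basis = solution.basis
    if len(basis) > cap:
        raise ValueError(f"basis size {len(basis)} above the RDM cap {cap}")
    coeff = {d: float(c) for d, c in zip(basis, solution.coefficients)}
    diag_weight = {
        d.spin_orbitals(n_orb): c * c for d, c in coeff.items()
    }
    pair_weight: dict[tuple[int, int], float] = {}
    for det, c_i in coeff.items():
        occ_i = det.spin_orbitals(n_orb)
        for child in connected_excitations(det, n_orb):
            c_j = coeff.get(child)
            if c_j:
                pair_weight[(occ_i, child.spin_orbitals(n_orb))] = c_i * c_j
    gamma, Gamma = _expand_weights(diag_weight, pair_weight, n_orb)
    norm = sum(diag_weight.values())
    gamma /= norm
    Gamma /= norm
    return _split(gamma, n_orb), TwoRDM(Gamma)


def energy_from_rdms(
    table: IntegralTable, one: OneRDM, two: TwoRDM
) -> float:
    """Reconstruct the total energy from (h, g) and the density matrices."""
    n = table.n_orb
    e = table.core_energy
    e += float(np.einsum("pq,pq->", table.h, one.gamma_a))
    e += float(np.einsum("pq,pq->", table.h, one.gamma_b))
    for s1 in ("a", "b"):
        for s2 in ("a", "b"):
            block = two.spin_block(s1, s2)
            e += 0.5 * float(np.einsum("prqs,pqrs->", table.g, block))
    return e


def spin_expectation(
    one: OneRDM, two: TwoRDM, tol: float = 1e-6
) -> tuple[float, float]:
    """``<S^2>`` and the inferred spin quantum number ``s``.

    ``<S^2> = m_s (m_s + 1) + N_beta - sum_pq Gamma[p_b, q_a, q_b, p_a]``;
    ``s = (-1 + sqrt(1 + 4 <S^2>)) / 2``.  Raises when the value falls below
    the exact lower bound ``m_s (m_s + 1)`` by more than ``tol`` (noise or a
    bug upstream).
    """
    n = one.n_orb
    n_alpha = float(np.trace(one.gamma_a))
    n_beta = float(np.trace(one.gamma_b))
    m_s = 0.5 * (n_alpha - n_beta)
    flip = 0.0
    g = two.gamma
    for p in range(n):
        for q in range(n):
            flip += g[n + p, q, n + q, p]
    s_squared = m_s * (m_s + 1) + n_beta - flip
    if s_squared < m_s * (m_s + 1) - tol:
        raise ValueError(
            f"<S^2> = {s_squared} below the m_s(m_s+1) bound — noisy RDMs?"
        )
    s = 0.5 * (-1.0 + np.sqrt(max(1.0 + 4.0 * s_squared, 0.0)))
    return float(s_squared), float(s)


def pseudonatural_orbitals(
    one: OneRDM, partition: GASPartition
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Block-diagonalize the spin-summed 1-RDM, one block per GAS subspace.

    Returns the block-diagonal unitary (columns are pseudonatural orbitals in
    the original basis) and the per-space occupation lists, each sorted
    descending.  For disconnected spaces the interspace blocks of the 1-RDM
    vanish, so pseudonatural and natural orbitals coincide.
    """
    total = one.total
    n = total.shape[0]
    if partition.n_orb != n:
        raise ValueError("partition does not match the 1-RDM dimension")
    U = np.zeros((n, n))
    occupations = []
    for off, size in zip(partition.space_offsets(), partition.space_sizes):
        block = total[off : off + size, off : off + size]
        w, v = np.linalg.eigh(0.5 * (block + block.T))
        order = np.argsort(w)[::-1]
        U[off : off + size, off : off + size] = v[:, order]
        occupations.append(w[order])
    return U, occupations


# ---------------------------------------------------------------------------
# Stochastic sampling
# ---------------------------------------------------------------------------

class RdmAccumulator:
    """Accumulates RDM contributions during a dynamics run.

    Diagonal contributions are walker-population squares; off-diagonal
    contributions come from accepted spawn events ``i -> j`` with estimator
    weight ``sign(c_i) c_j n_spawn / (dtau |K_ij|)``: the expected spawn count
    of a route is ``|c_i| dtau |K_ij|``, so the weights sum to ``c_i c_j`` per
    iteration in expectation.  Contributions are expanded into RDM elements only once per
    unique determinant/pair at finalization.
    """

    def __init__(self, n_orb: int):
        self.n_orb = n_orb
        self.diag_weight: dict[int, float] = {}
        self.pair_weight: dict[tuple[int, int], float] = {}
        self.norm = 0.0
        self.samples = 0

    def collect(
        self,
        store,
        child_keys: Sequence[tuple[int, int]],
        counts: Sequence[int],
        parent_dets: Sequence[Determinant],
        parent_pops: Sequence[float],
        kmags: Sequence[float],
        dtau: float,
    ) -> None:
        n = self.n_orb
        for det, pop in store.items():
            occ = det.spin_orbitals(n)
            self.diag_weight[occ] = self.diag_weight.get(occ, 0.0) + pop * pop
            self.norm += pop * pop
        for t in range(len(child_keys)):
            ca, cb = child_keys[t]
            child = Determinant(ca, cb)
            c_j = store.get(child, 0.0)
            if not c_j:
                continue
            # events already arrive at a rate proportional to |c_i|, so the
            # per-event weight carries only the parent's sign
            sign_i = 1.0 if parent_pops[t] > 0 else -1.0
            w = sign_i * c_j * abs(counts[t]) / (dtau * kmags[t])
            key = (parent_dets[t].spin_orbitals(n), child.spin_orbitals(n))
            self.pair_weight[key] = self.pair_weight.get(key, 0.0) + w
        self.samples += 1

    def finalize(self, n_elec: int) -> tuple[OneRDM, TwoRDM]:
        """Expand accumulated weights into (1-RDM, 2-RDM), normalized so that
        ``trace(gamma) = N`` exactly; output is hermitized."""
        n = self.n_orb
        if self.norm <= 0:
            raise ValueError("empty sampling window")
        gamma, Gamma = _expand_weights(self.diag_weight, self.pair_weight, n)
        gamma /= self.norm
        Gamma /= self.norm
        gamma = 0.5 * (gamma + gamma.T)
        Gamma = 0.5 * (Gamma + Gamma.transpose(2, 3, 0, 1))
        trace = np.trace(gamma)
        if trace > 0:
            gamma *= n_elec / trace
            pairs = n_elec * (n_elec - 1)
            t2 = float(np.einsum("pqpq->", Gamma))
            if t2 > 0:
                Gamma *= pairs / t2
        return _split(gamma, n), TwoRDM(Gamma)


def save_rdms(path, one: OneRDM, two: TwoRDM, meta: Optional[dict] = None) -> None:
    """Write spin-resolved RDMs plus metadata to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("gamma_a", data=one.gamma_a)
        fh.create_dataset("gamma_b", data=one.gamma_b)
        fh.create_dataset("gamma2", data=two.gamma)
        if meta:
            for key, value in meta.items():
                fh.attrs[key] = value


def load_rdms(path) -> tuple[OneRDM, TwoRDM, dict]:
    import h5py

    with h5py.File(path, "r") as fh:
        one = OneRDM(fh["gamma_a"][...], fh["gamma_b"][...])
        two = TwoRDM(fh["gamma2"][...])
        meta = {k: fh.attrs[k] for k in fh.attrs}
    return one, two, meta


def sampled_rdms(
    run,
    n_elec: int,
    sampling_iterations: int,
    min_iterations: int = 64,
) -> tuple[OneRDM, TwoRDM]:
    """Attach an accumulator to a running dynamics and sample RDMs.

    ``run`` is a :class:`stochgas.fciqmc.FciqmcRun` that has already been
    equilibrated; the next ``sampling_iterations`` iterations contribute.
    """
    if sampling_iterations < min_iterations:
        raise ValueError(
            f"sampling window {sampling_iterations} below minimum {min_iterations}"
        )
    acc = RdmAccumulator(run.n)
    run.rdm_accumulator = acc
    for _ in range(sampling_iterations):
        run.iterate()
    run.rdm_accumulator = None
    return acc.finalize(n_elec)
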