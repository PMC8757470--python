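"""Precomputed heat-bath (PCHB) excitation generation, FCI and GAS flavors.

Double excitations are proposed by drawing a hole pair ``(A, B)`` from an
alias-sampled distribution proportional to ``|H_IJ^AB|`` — the double-
excitation matrix element magnitude, which depends only on the orbital
indices, never on the parent determinant.  Under GAS constraints the same
holds per *supergroup*: one distribution set is stored per supergroup with
GAS-forbidden moves given exactly zero weight, so forbidden determinants are
never proposed.  Single excitations pick a particle uniformly and a hole
uniformly among the spin-compatible holes whose space move keeps the
composition allowed (precomputed bitmasks per supergroup and source space).

FCI-PCHB is the special case with a single implicit supergroup and no mask.
All generators return an :class:`ExcitationEvent` carrying the exact
generation probability ``p_gen``, or a :class:`Rejection` describing why the
attempt produced no child (a normal outcome whose probability mass is part of
the unbiasedness bookkeeping).

Tables are indexed over spin-orbital pairs; the factor-of-~4 memory reduction
from spatial-orbital indexing is documented in :func:`memory_estimate` but not
implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gas_constraints import (
    GASPartition,
    SupergroupTable,
    supergroup_of_determinant,
)
from .hamiltonian import Determinant, IntegralTable


@dataclass(frozen=True)
class ExcitationEvent:
    kind: str  # "single" | "double"
    I: int
    A: int
    child: Determinant
    p_gen: float
    J: int = -1
    B: int = -1


@dataclass(frozen=True)
class Rejection:
    reason: str  # "occupied_hole" | "no_hole" | "empty_row" | "gas_forbidden"
    p_attempt: float  # probability mass of the rejected attempt path


class AliasTable:
    """Walker's alias method: O(1) sampling from a fixed finite distribution.

    The sampled distribution equals the normalized input weights exactly
    (up to floating-point rounding of the per-cell cut points).
    """

    def __init__(self, weights: np.ndarray):
        w = np.asarray(weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a nonempty 1-D array")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("all weights are zero")
        self.total = float(total)
        self.probabilities = w / total
        K = w.size
        scaled = self.probabilities * K
        self.cut = np.ones(K)
        self.alias = np.arange(K)
        small = [i for i in range(K) if scaled[i] < 1.0]
        large = [i for i in range(K) if scaled[i] >= 1.0]
        scaled = scaled.copy()
        while small and large:
            s = small.pop()
            l = large.pop()
            self.cut[s] = scaled[s]
            self.alias[s] = l
            scaled[l] = scaled[l] - (1.0 - scaled[s])
            (small if scaled[l] < 1.0 else large).append(l)
        for i in small + large:
            self.cut[i] = 1.0
            self.alias[i] = i

    def sample(self, rng: np.random.Generator) -> int:
        i = int(rng.integers(self.cut.size))
        return i if rng.random() < self.cut[i] else int(self.alias[i])

    def sample_many(self, rng: np.random.Generator, size: int) -> np.ndarray:
        idx = rng.integers(self.cut.size, size=size)
        keep = rng.random(size) < self.cut[idx]
        return np.where(keep, idx, self.alias[idx])


def build_alias(weights: Sequence[float]) -> AliasTable:
    return AliasTable(np.asarray(weights, dtype=float))


def _pair_arrays(m: int):
    """Arrays A, B (A < B) for all spin-orbital pairs and a reverse lookup."""
    A, B = np.triu_indices(m, k=1)
    pair_id = -np.ones((m, m), dtype=np.int64)
    pair_id[A, B] = np.arange(A.size)
    pair_id[B, A] = np.arange(A.size)
    return A.astype(np.int64), B.astype(np.int64), pair_id


class PchbTables:
    """Per-supergroup alias tables for hole pairs plus single-hole bitmasks.

    ``gas=False`` builds one implicit supergroup with no mask (FCI-PCHB);
    otherwise one table set per supergroup of ``sg_table`` with GAS-forbidden
    ``(A, B <- I, J)`` moves at exactly zero weight.
    """

    def __init__(
        self,
        integrals: IntegralTable,
        sg_table: Optional[SupergroupTable],
        gas: bool = True,
        p_double: float = 0.8,
        memory_cap_bytes: Optional[int] = None,
    ):
        if gas and sg_table is None:
            raise ValueError("GAS tables require a supergroup table")
        self.integrals = integrals
        self.sg_table = sg_table
        self.gas = gas
        self.p_double = float(p_double)
        n = integrals.n_orb
        self.n_orb = n
        m = 2 * n
        self.m = m
        self.pair_A, self.pair_B, self.pair_id = _pair_arrays(m)
        npairs = self.pair_A.size
        n_sg = sg_table.n_sg if gas else 1
        self.n_sg = n_sg
        est = memory_estimate(n, n_sg)
        self.memory_bytes = est
        if memory_cap_bytes is not None and est > memory_cap_bytes:
            raise MemoryError(
                f"PCHB tables would need ~{est / 1e9:.2f} GB "
                f"(cap {memory_cap_bytes / 1e9:.2f} GB)"
            )

        partition = sg_table.partition if sg_table is not None else None
        if partition is not None:
            orb_space = np.array(partition.orbital_to_space, dtype=np.int64)
            so_space = np.concatenate([orb_space, orb_space])
            self._so_space = so_space
            spA = so_space[self.pair_A]
            spB = so_space[self.pair_B]
        self.partition = partition

        # |H_IJ^AB| for every pair, before masking: identical per supergroup.
        g = integrals.g
        an, bn = self.pair_A % n, self.pair_B % n
        sa, sb = self.pair_A >= n, self.pair_B >= n
        base = np.empty((npairs, npairs))
        for ij in range(npairs):
            I, J = int(self.pair_A[ij]), int(self.pair_B[ij])
            i_n, j_n = I % n, J % n
            si, sj = I >= n, J >= n
            direct = g[an, i_n, bn, j_n] * ((sa == si) & (sb == sj))
            exch = g[an, j_n, bn, i_n] * ((sa == sj) & (sb == si))
            w = np.abs(direct - exch)
            # A hole coinciding with a chosen particle is not an excitation.
            w[(self.pair_A == I) | (self.pair_A == J)] = 0.0
            w[(self.pair_B == I) | (self.pair_B == J)] = 0.0
            base[ij] = w
        self._base_weights = base

        # Supergroup masks over hole pairs, resolved by space moves.
        self.alias: list[list[Optional[AliasTable]]] = []
        self.probabilities: list[list[Optional[np.ndarray]]] = []
        self.single_masks: list[list[int]] = []
        allowed = set(sg_table.supergroups) if gas else None
        for isg in range(n_sg):
            alias_row: list[Optional[AliasTable]] = []
            prob_row: list[Optional[np.ndarray]] = []
            if gas:
                x = sg_table.supergroups[isg]
                k = partition.k
                move_ok = {}
                for ij in range(npairs):
                    sI = int(so_space[self.pair_A[ij]])
                    sJ = int(so_space[self.pair_B[ij]])
                    key_rm = (sI, sJ)
                    if key_rm not in move_ok:
                        ok = np.empty(npairs, dtype=bool)
                        for ab in range(npairs):
                            tA = int(spA[ab])
                            tB = int(spB[ab])
                            y = list(x)
                            y[sI] -= 1
                            y[sJ] -= 1
                            y[tA] += 1
                            y[tB] += 1
                            ok[ab] = tuple(y) in allowed
                        move_ok[key_rm] = ok
                for ij in range(npairs):
                    sI = int(so_space[self.pair_A[ij]])
                    sJ = int(so_space[self.pair_B[ij]])
                    w = base[ij] * move_ok[(sI, sJ)]
                    if w.sum() > 0:
                        at = AliasTable(w)
                        alias_row.append(at)
                        prob_row.append(at.probabilities)
                    else:
                        alias_row.append(None)
                        prob_row.append(None)
            else:
                for ij in range(npairs):
                    w = base[ij]
                    if w.sum() > 0:
                        at = AliasTable(w)
                        alias_row.append(at)
                        prob_row.append(at.probabilities)
                    else:
                        alias_row.append(None)
                        prob_row.append(None)
            self.alias.append(alias_row)
            self.probabilities.append(prob_row)

            # Single-excitation hole bitmasks per source space (spatial bits).
            if gas:
                offsets = partition.space_offsets()
                masks = []
                for s_from in range(partition.k):
                    mask = 0
                    x = sg_table.supergroups[isg]
                    for s_to in range(partition.k):
                        y = list(x)
                        y[s_from] -= 1
                        y[s_to] += 1
                        if tuple(y) in allowed:
                            mask |= (
                                (1 << partition.space_sizes[s_to]) - 1
                            ) << offsets[s_to]
                    masks.append(mask)
                self.single_masks.append(masks)
            else:
                self.single_masks.append([(1 << n) - 1])

    # -- helpers -----------------------------------------------------------

    def supergroup_index0(self, det: Determinant) -> int:
        """0-based supergroup index of a determinant (0 for FCI tables)."""
        if not self.gas:
            return 0
        x = supergroup_of_determinant(det, self.partition)
        return self.sg_table.index(x) - 1

    def single_hole_mask(self, isg0: int, I: int) -> int:
        """Spatial-orbital bitmask of spaces reachable by moving particle I."""
        if not self.gas:
            return self.single_masks[0][0]
        s_from = int(self._so_space[I])
        return self.single_masks[isg0][s_from]


def build_pchb_tables(
    integrals: IntegralTable,
    sg_table: Optional[SupergroupTable],
    gas: bool = True,
    p_double: float = 0.8,
    memory_cap_bytes: Optional[int] = None,
) -> PchbTables:
    return PchbTables(
        integrals, sg_table, gas=gas, p_double=p_double,
        memory_cap_bytes=memory_cap_bytes,
    )


def _occupied_spin_orbitals(det: Determinant, n: int) -> list[int]:
    return [p for p in det.occupied_alpha()] + [n + p for p in det.occupied_beta()]


def _child_double(det: Determinant, n: int, I: int, J: int, A: int, B: int):
    occ = det.spin_orbitals(n)
    occ ^= (1 << I) | (1 << J)
    occ |= (1 << A) | (1 << B)
    return Determinant.from_spin_orbitals(occ, n)


def _child_single(det: Determinant, n: int, I: int, A: int):
    occ = det.spin_orbitals(n)
    occ = (occ ^ (1 << I)) | (1 << A)
    return Determinant.from_spin_orbitals(occ, n)


def sample_double(
    det: Determinant, tables: PchbTables, rng: np.random.Generator
):
    """One double-excitation attempt: uniform particle pair, alias-drawn holes.

    Returns an :class:`ExcitationEvent` (with the full ``p_gen`` including the
    double-vs-single and particle-pair factors) or a :class:`Rejection` when
    the drawn holes are occupied or the (IJ) row has no allowed hole pair.
    """
    n = tables.n_orb
    occ = _occupied_spin_orbitals(det, n)
    ne = len(occ)
    npair = ne * (ne - 1) // 2
    u = int(rng.integers(npair))
    # map flat index to (a < b)
    a = 0
    while u >= ne - 1 - a:
        u -= ne - 1 - a
        a += 1
    I, J = occ[a], occ[a + 1 + u]
    isg = tables.supergroup_index0(det)
    pid = int(tables.pair_id[I, J])
    p_path = tables.p_double / npair
    alias = tables.alias[isg][pid]
    if alias is None:
        return Rejection("empty_row", p_path)
    ab = alias.sample(rng)
    A, B = int(tables.pair_A[ab]), int(tables.pair_B[ab])
    occ_bits = det.spin_orbitals(n)
    if (occ_bits >> A) & 1 or (occ_bits >> B) & 1:
        return Rejection("occupied_hole", p_path * float(alias.probabilities[ab]))
    child = _child_double(det, n, I, J, A, B)
    p_gen = p_path * float(alias.probabilities[ab])
    return ExcitationEvent("double", I, A, child, p_gen, J=J, B=B)


def sample_single(
    det: Determinant, tables: PchbTables, rng: np.random.Generator
):
    """One single-excitation attempt: uniform particle, uniform allowed hole."""
    n = tables.n_orb
    occ = _occupied_spin_orbitals(det, n)
    ne = len(occ)
    I = occ[int(rng.integers(ne))]
    isg = tables.supergroup_index0(det)
    mask = tables.single_hole_mask(isg, I)
    same_spin_occ = det.alpha if I < n else det.beta
    avail = mask & ~same_spin_occ
    count = avail.bit_count()
    p_path = (1.0 - tables.p_double) / ne
    if count == 0:
        return Rejection("no_hole", p_path)
    j = int(rng.integers(count))
    a_spatial = _nth_set_bit(avail, j)
    A = a_spatial if I < n else n + a_spatial
    child = _child_single(det, n, I, A)
    return ExcitationEvent("single", I, A, child, p_path / count)


def _nth_set_bit(x: int, j: int) -> int:
    for _ in range(j):
        x &= x - 1
    return (x & -x).bit_length() - 1


def sample_event(
    det: Determinant, tables: PchbTables, rng: np.random.Generator
):
    """Full attempt: choose double vs single, then delegate."""
    if rng.random() < tables.p_double:
        return sample_double(det, tables, rng)
    return sample_single(det, tables, rng)


def pgen(det: Determinant, event: ExcitationEvent, tables: PchbTables) -> float:
    """Exact probability the generator assigns to this event from ``det``.

    Recomputed from the tables (not from the value the event carries);
    unreachable events get 0.
    """
    n = tables.n_orb
    occ = _occupied_spin_orbitals(det, n)
    ne = len(occ)
    isg = tables.supergroup_index0(det)
    if event.kind == "single":
        mask = tables.single_hole_mask(isg, event.I)
        same_spin_occ = det.alpha if event.I < n else det.beta
        avail = mask & ~same_spin_occ
        a_spatial = event.A % n
        if not (avail >> a_spatial) & 1:
            return 0.0
        return (1.0 - tables.p_double) / ne / avail.bit_count()
    npair = ne * (ne - 1) // 2
    pid = int(tables.pair_id[event.I, event.J])
    probs = tables.probabilities[isg][pid]
    if probs is None:
        return 0.0
    ab = int(tables.pair_id[event.A, event.B])
    return tables.p_double / npair * float(probs[ab])


def discarding_generator(
    det: Determinant,
    fci_tables: PchbTables,
    sg_table: SupergroupTable,
    rng: np.random.Generator,
):
    """FCI-PCHB proposal with a-posteriori rejection of GAS-forbidden children.

    The baseline generator: correct but wasteful, since probability mass spent
    on forbidden children is lost to rejections.
    """
    out = sample_event(det, fci_tables, rng)
    if isinstance(out, Rejection):
        return out
    x = supergroup_of_determinant(out.child, sg_table.partition)
    if not sg_table.contains(x):
        return Rejection("gas_forbidden", out.p_gen)
    return out


def memory_estimate(
    n_orb: int, n_sg: int, entry_bytes: int = 4, spatial: bool = False
) -> int:
    """Bytes needed for the hole-pair distributions.

    ``(#ordered pairs)^2 * n_sg * entry_bytes`` with pairs over spin orbitals
    by default; ``spatial=True`` gives the ~16x-smaller spatial-indexed layout
    that production codes use.  Used for the build-time refusal cap.
    """
    m = n_orb if spatial else 2 * n_orb
    npairs = m * (m - 1) // 2
    return npairs * npairs * n_sg * entry_bytes
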