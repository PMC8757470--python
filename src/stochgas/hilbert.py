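"""Hilbert-space sizes for CAS and GAS wave functions.

Counts (and, at desk scale, enumerates) Slater determinants resolved by spin
projection, and counts spin-adapted configuration state functions (CSFs) via
the van Vleck–Sherman branching formula.  Counting is exact big-integer
arithmetic throughout: per-supergroup counts are computed by convolving the
per-space generating polynomials of the alpha-electron distribution, so spaces
holding ``x_i`` electrons in ``n_i`` orbitals contribute
``sum_a C(n_i, a) C(n_i, x_i - a) z^a`` and the coefficient of ``z^{n_alpha}``
in the product is the number of determinants of that supergroup.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterator

from .gas_constraints import GASPartition, SupergroupTable

DEFAULT_ENUMERATION_CAP = 10**6


@dataclass(frozen=True)
class SpinSector:
    """Electron counts per spin channel; ``m_s = (n_alpha - n_beta) / 2``."""

    n_alpha: int
    n_beta: int

    @property
    def N(self) -> int:
        return self.n_alpha + self.n_beta

    @property
    def m_s(self) -> float:
        return (self.n_alpha - self.n_beta) / 2

    @classmethod
    def from_ms(cls, N: int, m_s: float) -> "SpinSector":
        two_ms = round(2 * m_s)
        if (N + two_ms) % 2:
            raise ValueError(f"m_s = {m_s} inconsistent with N = {N} parity")
        n_alpha = (N + two_ms) // 2
        n_beta = N - n_alpha
        if n_alpha < 0 or n_beta < 0:
            raise ValueError(f"|2 m_s| = {abs(two_ms)} exceeds N = {N}")
        return cls(n_alpha, n_beta)


def count_sds(n_orb: int, N: int, m_s: float) -> int:
    """Number of Slater determinants at fixed spin projection.

    ``C(n_orb, n_alpha) * C(n_orb, n_beta)``; infeasible sectors count 0.
    """
    if n_orb < 0 or N < 0:
        raise ValueError("n_orb and N must be nonnegative")
    try:
        sector = SpinSector.from_ms(N, m_s)
    except ValueError:
        return 0
    if sector.n_alpha > n_orb or sector.n_beta > n_orb:
        return 0
    return comb(n_orb, sector.n_alpha) * comb(n_orb, sector.n_beta)


def _space_alpha_poly(n_i: int, x_i: int) -> list[int]:
    """Coefficients over alpha count ``a`` of determinant counts in one space."""
    return [comb(n_i, a) * comb(n_i, x_i - a) for a in range(x_i + 1)]


def _convolve(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a:
            for j, b in enumerate(q):
                out[i + j] += a * b
    return out


def count_sds_supergroup(
    partition: GASPartition, supergroup: tuple[int, ...], n_alpha: int
) -> int:
    """Determinants of one supergroup with ``n_alpha`` total alpha electrons."""
    poly = [1]
    for n_i, x_i in zip(partition.space_sizes, supergroup):
        poly = _convolve(poly, _space_alpha_poly(n_i, x_i))
    if not 0 <= n_alpha < len(poly):
        return 0
    return poly[n_alpha]


def count_sds_gas(
    partition: GASPartition, table: SupergroupTable, m_s: float
) -> int:
    """Total GAS determinant count at fixed spin projection (exact integer)."""
    try:
        sector = SpinSector.from_ms(table.N, m_s)
    except ValueError:
        return 0
    return sum(
        count_sds_supergroup(partition, sg, sector.n_alpha)
        for sg in table.supergroups
    )


def _iter_space_occupations(
    offset: int, size: int, n_elec: int
) -> Iterator[tuple[int, int]]:
    """(alpha_bits, beta_bits) pairs for one space holding ``n_elec`` electrons."""
    orbs = range(offset, offset + size)
    for n_a in range(max(0, n_elec - size), min(size, n_elec) + 1):
        n_b = n_elec - n_a
        for alpha_orbs in combinations(orbs, n_a):
            a_bits = 0
            for p in alpha_orbs:
                a_bits |= 1 << p
            for beta_orbs in combinations(orbs, n_b):
                b_bits = 0
                for p in beta_orbs:
                    b_bits |= 1 << p
                yield a_bits, b_bits


def enumerate_determinants(
    partition: GASPartition,
    table: SupergroupTable,
    m_s: float,
    cap: int = DEFAULT_ENUMERATION_CAP,
):
    """Complete, duplicate-free determinant basis of the GAS space.

    Ordered by (supergroup index, then per-space bit patterns); deterministic.
    Refuses when the counted size exceeds ``cap``.  Returns a list of
    :class:`stochgas.hamiltonian.Determinant`.
    """
    from .hamiltonian import Determinant

    total = count_sds_gas(partition, table, m_s)
    if total > cap:
        raise ValueError(
            f"GAS space holds {total} determinants, above the enumeration cap {cap}"
        )
    sector = SpinSector.from_ms(table.N, m_s)
    offsets = partition.space_offsets()
    dets: list[Determinant] = []

    def recurse(space: int, sg: tuple[int, ...], alpha: int, beta: int, n_a: int):
        if space == partition.k:
            if n_a == sector.n_alpha:
                dets.append(Determinant(alpha, beta))
            return
        remaining_alpha_cap = sum(partition.space_sizes[space:])
        if n_a + remaining_alpha_cap < sector.n_alpha:
            return
        for a_bits, b_bits in _iter_space_occupations(
            offsets[space], partition.space_sizes[space], sg[space]
        ):
            na_here = a_bits.bit_count()
            if n_a + na_here > sector.n_alpha:
                continue
            recurse(space + 1, sg, alpha | a_bits, beta | b_bits, n_a + na_here)

    for sg in table.supergroups:
        recurse(0, sg, 0, 0, 0)
    assert len(dets) == total
    return dets


def csf_count(n_open: int, s: float) -> int:
    """Number of spin-``s`` CSFs over ``n_open`` singly occupied orbitals.

    The van Vleck–Sherman branching count
    ``(2s + 1) / (n + 1) * C(n + 1, n/2 - s)``; zero when the parity of
    ``2s`` does not match ``n_open`` or ``s > n_open / 2``.
    """
    if n_open < 0:
        raise ValueError("n_open must be nonnegative")
    two_s = round(2 * s)
    if two_s < 0 or two_s > n_open or (n_open - two_s) % 2:
        return 0
    # (2s+1)/(n+1) C(n+1, (n - 2s)/2) is integral; compute as a difference of
    # binomials to stay in exact integers.
    half = (n_open - two_s) // 2
    return comb(n_open, half) - (comb(n_open, half - 1) if half > 0 else 0)
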