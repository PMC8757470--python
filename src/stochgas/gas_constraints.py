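"""Occupation-number constraints for generalized active spaces (GAS).

A GAS calculation partitions the active spatial orbitals into ``k`` subspaces
and restricts the electron count per subspace.  A *composition* is an ordered
distribution ``x = (x_1, ..., x_k)`` of the ``N`` active electrons over the
subspaces; a composition satisfying the constraints is called a *supergroup*.
Two kinds of constraint are supported:

* *local* — per-space bounds ``n_min[i] <= x_i <= n_max[i]``;
* *cumulative* — bounds on the partial sums
  ``cum_min[i] <= x_1 + ... + x_{i+1} <= cum_max[i]``.

All determinants sharing a supergroup face identical excitation restrictions,
which is what makes supergroups the natural indexing unit for precomputed
excitation-generator tables.

Index conventions: compositions and supergroups are indexed 1-based (matching
the standard tabulations in the field); orbitals and spaces are 0-based.
Compositions are ordered lexicographically *decreasing*.  All counting is done
in exact (arbitrary-precision) integer arithmetic — conceptual spaces can
exceed the 64-bit range and are only ever counted, never materialized.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from math import comb
from typing import Iterator, Sequence, Union


@dataclass(frozen=True)
class GASPartition:
    """Partition of the active spatial orbitals into GAS subspaces.

    Orbitals are assigned contiguously: the first ``space_sizes[0]`` spatial
    orbitals belong to space 0, the next ``space_sizes[1]`` to space 1, etc.
    """

    space_sizes: tuple[int, ...]

    def __init__(self, space_sizes: Sequence[int]):
        sizes = tuple(int(s) for s in space_sizes)
        if len(sizes) < 1:
            raise ValueError("at least one GAS space is required")
        if any(s <= 0 for s in sizes):
            raise ValueError("space sizes must be positive")
        object.__setattr__(self, "space_sizes", sizes)

    @property
    def k(self) -> int:
        return len(self.space_sizes)

    @property
    def n_orb(self) -> int:
        return sum(self.space_sizes)

    @property
    def orbital_to_space(self) -> tuple[int, ...]:
        mapping = []
        for i, size in enumerate(self.space_sizes):
            mapping.extend([i] * size)
        return tuple(mapping)

    def capacities(self) -> tuple[int, ...]:
        """Spin-orbital capacity (2 electrons per spatial orbital) per space."""
        return tuple(2 * s for s in self.space_sizes)

    def space_offsets(self) -> tuple[int, ...]:
        off, acc = [], 0
        for s in self.space_sizes:
            off.append(acc)
            acc += s
        return tuple(off)


@dataclass(frozen=True)
class LocalConstraints:
    """Per-space occupation bands ``n_min[i] <= x_i <= n_max[i]``."""

    n_min: tuple[int, ...]
    n_max: tuple[int, ...]

    def __init__(self, n_min: Sequence[int], n_max: Sequence[int]):
        lo = tuple(int(v) for v in n_min)
        hi = tuple(int(v) for v in n_max)
        if len(lo) != len(hi):
            raise ValueError("n_min and n_max must have equal length")
        object.__setattr__(self, "n_min", lo)
        object.__setattr__(self, "n_max", hi)

    @property
    def k(self) -> int:
        return len(self.n_min)


@dataclass(frozen=True)
class CumulativeConstraints:
    """Bands on partial sums ``cum_min[i] <= sum(x[: i + 1]) <= cum_max[i]``."""

    cum_min: tuple[int, ...]
    cum_max: tuple[int, ...]

    def __init__(self, cum_min: Sequence[int], cum_max: Sequence[int]):
        lo = tuple(int(v) for v in cum_min)
        hi = tuple(int(v) for v in cum_max)
        if len(lo) != len(hi):
            raise ValueError("cum_min and cum_max must have equal length")
        object.__setattr__(self, "cum_min", lo)
        object.__setattr__(self, "cum_max", hi)

    @property
    def k(self) -> int:
        return len(self.cum_min)


Constraints = Union[LocalConstraints, CumulativeConstraints]

Composition = tuple[int, ...]


def n_compositions(k: int, n: int) -> int:
    """Number of ordered distributions of ``n`` particles over ``k`` slots.

    Equals ``C(n + k - 1, k - 1)`` (stars and bars), exact integer.
    """
    if k < 1 or n < 0:
        raise ValueError("require k >= 1 and n >= 0")
    return comb(n + k - 1, k - 1)


def iter_compositions(k: int, n: int) -> Iterator[Composition]:
    """Yield all compositions of ``n`` into ``k`` parts, decreasing lex order."""
    if k == 1:
        yield (n,)
        return
    for first in range(n, -1, -1):
        for rest in iter_compositions(k - 1, n - first):
            yield (first,) + rest


def composition_index(x: Sequence[int]) -> int:
    """1-based position of ``x`` in the decreasing-lex list of compositions.

    Computed by "jumping over" all compositions with a larger leading term at
    each position, each jump contributing the stars-and-bars count of the
    remaining suffix; only binomial-table lookups are needed.
    """
    x = tuple(int(v) for v in x)
    k = len(x)
    n = sum(x)
    idx = 1
    rem = n
    for i in range(k - 1):
        suffix = k - i - 1
        for lead in range(x[i] + 1, rem + 1):
            idx += n_compositions(suffix, rem - lead)
        rem -= x[i]
    return idx


def is_allowed(x: Sequence[int], constraints: Constraints) -> bool:
    """True iff the composition satisfies the (local or cumulative) bounds."""
    x = tuple(x)
    if len(x) != constraints.k:
        raise ValueError(
            f"composition length {len(x)} != number of constrained spaces {constraints.k}"
        )
    if isinstance(constraints, LocalConstraints):
        return all(
            lo <= xi <= hi
            for xi, lo, hi in zip(x, constraints.n_min, constraints.n_max)
        )
    acc = 0
    for xi, lo, hi in zip(x, constraints.cum_min, constraints.cum_max):
        acc += xi
        if not lo <= acc <= hi:
            return False
    return True


@dataclass(frozen=True)
class SupergroupTable:
    """Ordered list of GAS-allowed compositions with O(log) index lookup.

    ``supergroups`` is decreasing-lex ordered; ``comp_indices`` holds the
    (strictly increasing) composition indices, so the supergroup index of a
    composition is found by one composition-index evaluation plus a binary
    search.
    """

    partition: GASPartition
    constraints: Constraints
    N: int
    supergroups: tuple[Composition, ...]
    comp_indices: tuple[int, ...] = field(repr=False)

    @property
    def n_sg(self) -> int:
        return len(self.supergroups)

    def index(self, x: Sequence[int]) -> int:
        """1-based supergroup index of composition ``x``."""
        return supergroup_index(x, self)

    def contains(self, x: Sequence[int]) -> bool:
        x = tuple(x)
        caps = self.partition.capacities()
        return (
            len(x) == self.partition.k
            and all(0 <= xi <= c for xi, c in zip(x, caps))
            and sum(x) == self.N
            and is_allowed(x, self.constraints)
        )


def validate(
    partition: GASPartition, constraints: Constraints, N: int
) -> list[str]:
    """Diagnose a constraint specification; returns a list of violations.

    An empty list means the specification is consistent: bounds are
    well-formed, the Pauli principle is satisfiable, and at least one
    composition survives.  Nothing is raised — callers decide whether to abort.
    """
    problems: list[str] = []
    k = partition.k
    caps = partition.capacities()
    if constraints.k != k:
        return [f"constraints cover {constraints.k} spaces but partition has {k}"]
    if isinstance(constraints, LocalConstraints):
        for i, (lo, hi) in enumerate(zip(constraints.n_min, constraints.n_max)):
            if lo < 0:
                problems.append(f"space {i}: negative minimum {lo}")
            if lo > hi:
                problems.append(f"space {i}: minimum {lo} exceeds maximum {hi}")
            if lo > caps[i]:
                problems.append(
                    f"space {i}: minimum {lo} exceeds spin-orbital capacity {caps[i]}"
                )
        if sum(constraints.n_min) > N:
            problems.append(
                f"total minimum {sum(constraints.n_min)} exceeds electron count {N}: "
                "no valid composition"
            )
        if sum(min(hi, c) for hi, c in zip(constraints.n_max, caps)) < N:
            problems.append(
                "total maximum below electron count: no valid composition"
            )
    else:
        lo, hi = constraints.cum_min, constraints.cum_max
        if any(a > b for a, b in zip(lo, hi)):
            problems.append("cumulative minimum exceeds cumulative maximum")
        if any(lo[i] > lo[i + 1] for i in range(k - 1)):
            problems.append("cumulative minima are not nondecreasing")
        if any(hi[i] > hi[i + 1] for i in range(k - 1)):
            problems.append("cumulative maxima are not nondecreasing")
        if lo and lo[-1] > N:
            problems.append(
                f"cumulative minimum for the last space {lo[-1]} exceeds "
                f"electron count {N}: no valid composition"
            )
        if hi and hi[-1] < N:
            problems.append(
                f"cumulative maximum for the last space {hi[-1]} is below "
                f"electron count {N}: no valid composition"
            )
    if not problems:
        if not any(
            is_allowed(x, constraints)
            for x in _iter_capped_compositions(caps, N)
        ):
            problems.append("no composition satisfies the constraints")
    return problems


def _iter_capped_compositions(caps: Sequence[int], n: int) -> Iterator[Composition]:
    """Compositions of ``n`` respecting per-slot capacities, decreasing lex."""
    caps = tuple(caps)
    if len(caps) == 1:
        if 0 <= n <= caps[0]:
            yield (n,)
        return
    tail_cap = sum(caps[1:])
    for first in range(min(n, caps[0]), -1, -1):
        if n - first > tail_cap:
            continue
        for rest in _iter_capped_compositions(caps[1:], n - first):
            yield (first,) + rest


def build_supergroup_table(
    partition: GASPartition, constraints: Constraints, N: int
) -> SupergroupTable:
    """Enumerate the GAS-allowed compositions and their composition indices.

    Enumeration is done once at setup; it need not be fast, only correct.
    Raises ``ValueError`` when no composition survives the constraints.
    """
    caps = partition.capacities()
    groups = [
        x
        for x in _iter_capped_compositions(caps, N)
        if is_allowed(x, constraints)
    ]
    if not groups:
        raise ValueError(
            "empty supergroup table: no composition satisfies the constraints; "
            f"diagnostics: {validate(partition, constraints, N)}"
        )
    # _iter_capped_compositions already yields decreasing-lex order.
    indices = tuple(composition_index(x) for x in groups)
    return SupergroupTable(partition, constraints, N, tuple(groups), indices)


def supergroup_index(x: Sequence[int], table: SupergroupTable) -> int:
    """1-based supergroup index via composition index + binary search."""
    x = tuple(int(v) for v in x)
    if not table.contains(x):
        raise ValueError(f"composition {x} is not allowed by the GAS constraints")
    ic = composition_index(x)
    pos = bisect_left(table.comp_indices, ic)
    return pos + 1


def supergroup_of_determinant(det, partition: GASPartition) -> Composition:
    """Electron count (alpha + beta) per GAS space for a determinant.

    ``det`` provides ``alpha``/``beta`` occupation bit-vectors over spatial
    orbitals (see :mod:`stochgas.hamiltonian`).
    """
    counts = [0] * partition.k
    offsets = partition.space_offsets()
    for space, (off, size) in enumerate(zip(offsets, partition.space_sizes)):
        mask = ((1 << size) - 1) << off
        counts[space] = (det.alpha & mask).bit_count() + (det.beta & mask).bit_count()
    return tuple(counts)


@dataclass(frozen=True)
class ConversionResult:
    constraints: Constraints
    equivalent: bool


def convert(
    constraints: Constraints, partition: GASPartition, N: int
) -> ConversionResult:
    """Convert local <-> cumulative constraints and test equivalence.

    Cumulative -> local uses ``n_min[i] = cum_min[i] - cum_max[i-1]`` and
    ``n_max[i] = cum_max[i] - cum_min[i-1]`` (clipped below at 0); the inverse
    direction takes running sums of the local bounds (clipped above at N).
    Conversion is not always faithful: the two constraint families are not
    equally expressive, so equivalence is decided *constructively* by building
    both supergroup tables and comparing the allowed sets.
    """
    if isinstance(constraints, CumulativeConstraints):
        lo, hi = constraints.cum_min, constraints.cum_max
        n_min = [max(0, lo[0])] + [
            max(0, lo[i] - hi[i - 1]) for i in range(1, len(lo))
        ]
        n_max = [hi[0]] + [hi[i] - lo[i - 1] for i in range(1, len(hi))]
        converted: Constraints = LocalConstraints(n_min, n_max)
    else:
        lo, hi = constraints.n_min, constraints.n_max
        cum_min, cum_max, a, b = [], [], 0, 0
        for i in range(len(lo)):
            a += lo[i]
            b += hi[i]
            cum_min.append(a)
            cum_max.append(min(b, N))
        # Tight bound for the last space ties the total electron count in.
        cum_min[-1] = max(cum_min[-1], min(N, cum_max[-1]))
        converted = CumulativeConstraints(cum_min, cum_max)

    try:
        original = build_supergroup_table(partition, constraints, N).supergroups
        new = build_supergroup_table(partition, converted, N).supergroups
        equivalent = set(original) == set(new)
    except ValueError:
        equivalent = False
    return ConversionResult(converted, equivalent)


def band_constraints(
    partition: GASPartition,
    neutral_occ: Sequence[int],
    n_exc: int,
    kind: str = "cumulative",
) -> Constraints:
    """Constraints allowing up to ``n_exc`` interspace excitations.

    ``neutral_occ`` is the reference (charge-neutral) electron count per space.
    The *local* band allows each space to deviate from neutrality by at most
    ``n_exc`` electrons; the *cumulative* band bounds each partial sum within
    ``n_exc`` of the neutral partial sum, with the last partial sum pinned to
    the total electron count.  Both are clipped to the per-space (respectively
    running) spin-orbital capacity.  ``n_exc = 0`` gives disconnected spaces
    (a single supergroup) for either kind.
    """
    if n_exc < 0:
        raise ValueError("n_exc must be nonnegative")
    neutral = tuple(int(v) for v in neutral_occ)
    if len(neutral) != partition.k:
        raise ValueError("neutral occupation must cover every GAS space")
    N = sum(neutral)
    caps = partition.capacities()
    if kind == "local":
        n_min = [max(0, v - n_exc) for v in neutral]
        n_max = [min(c, v + n_exc) for v, c in zip(neutral, caps)]
        return LocalConstraints(n_min, n_max)
    if kind == "cumulative":
        cum_neutral, acc = [], 0
        for v in neutral:
            acc += v
            cum_neutral.append(acc)
        run_cap, acc = [], 0
        for c in caps:
            acc += c
            run_cap.append(acc)
        cum_min = [max(0, v - n_exc) for v in cum_neutral]
        cum_max = [min(c, v + n_exc) for v, c in zip(cum_neutral, run_cap)]
        cum_min[-1] = cum_max[-1] = N
        return CumulativeConstraints(cum_min, cum_max)
    raise ValueError(f"unknown constraint kind {kind!r}")


def disconnected_constraints(occ: Sequence[int]) -> LocalConstraints:
    """Fixed occupation per space (no interspace excitations)."""
    occ = tuple(int(v) for v in occ)
    return LocalConstraints(occ, occ)
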