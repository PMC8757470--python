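"""Stochastic imaginary-time propagation (FCIQMC) with GAS support.

Signed integer walkers sample the linearized propagator
``1 - dtau (H - E_ref - S)``: per iteration each walker attempts one
excitation (double with probability ``p_double``, else single), spawns onto
the child with probability ``dtau |K_ij| / p_gen`` (multi-spawns allowed),
dies/clones on the diagonal with probability ``dtau (K_jj - S)``, and
opposite-sign arrivals on the same determinant annihilate.  ``K = H -
E_ref 1`` with ``E_ref`` the diagonal element of the initial reference, the
convention under which the population-control shift ``S`` equals the
correlation energy at stationarity.

Refinements: initiator threshold (spawns from weakly populated parents onto
empty determinants are vetoed), adaptive shift (non-initiators get a local
shift ``S_i = Delta + f_i (S - Delta)`` where ``f_i`` is the running
PT-weighted fraction of their spawns that survived the initiator veto), and
semistochastic propagation (the most populated determinants form a core space
propagated by exact matrix application, with real amplitudes).

The module exposes both step-level operations (``spawn_step``, ``death_step``,
``annihilate``, ...) and a batched driver (:class:`FciqmcRun`) that vectorizes
the per-walker sampling per occupied determinant, keeping Python overhead
proportional to the number of occupied determinants rather than the walker
count.  Both paths run the same physics through the same tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .excitgen import PchbTables, Rejection, sample_event
from .gas_constraints import SupergroupTable, supergroup_of_determinant
from .hamiltonian import (
    Determinant,
    IntegralTable,
    connected_excitations,
    diagonal_element,
    gas_masked_element,
    matrix_element,
)

__all__ = [
    "DynamicsConfig",
    "TimeSeries",
    "WalkerStore",
    "FciqmcRun",
    "FciqmcResult",
    "run_fciqmc",
    "spawn_step",
    "death_step",
    "annihilate",
    "update_shift",
    "initiator_filter",
    "adaptive_shift",
    "semistochastic_project",
    "projected_energy",
    "blocking_error",
    "stochastic_round",
]


# ---------------------------------------------------------------------------
# Configuration and bookkeeping containers
# ---------------------------------------------------------------------------

@dataclass
class DynamicsConfig:
    """Knobs of the walker dynamics; defaults follow common practice.

    ``adaptive_offset_frac`` expresses the adaptive-shift offset as a fraction
    of the instantaneous global shift, ``Delta = frac * S`` (so ``S <= Delta
    <= 0`` holds automatically for ``frac`` in [0, 1]); ``frac = 1`` reduces
    to the conventional initiator scheme and ``frac = 0`` applies the full
    correction.  An absolute ``adaptive_offset`` (<= 0) overrides the
    fraction when set.
    """

    time_step: Optional[float] = None
    target_population: float = 1e4
    initial_population: Optional[float] = None
    shift_damping: float = 0.05
    shift_interval: int = 5
    # The pure integral update telescopes to S(t) = S(0) - zeta/(A dtau)
    # ln(N(t)/N(0)), so any error in S(0) is paid for with a proportional
    # population drift; population_restore adds a weak setpoint term that
    # pins the stationary population at the target instead.
    population_restore: float = 0.1
    initial_shift: float = 0.0
    initiator: bool = False
    n_add: float = 3.0
    adaptive: bool = False
    adaptive_offset_frac: Optional[float] = None
    adaptive_offset: Optional[float] = None
    forgetting_half_life: float = 500.0
    core_size: int = 0
    seed: int = 0
    max_iterations: int = 2000
    equilibration: int = 500
    reference_switch_factor: float = 1.5
    reference_switch_patience: int = 100

    def __post_init__(self):
        if self.time_step is not None and self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.adaptive_offset is not None and self.adaptive_offset > 0:
            raise ValueError("adaptive offset must satisfy S <= Delta <= 0")


@dataclass
class TimeSeries:
    """Per-iteration records; numerator and denominator kept separate so they
    can be averaged independently before taking the ratio."""

    shift: list = field(default_factory=list)
    n_walkers: list = field(default_factory=list)
    numerator: list = field(default_factory=list)
    denominator: list = field(default_factory=list)
    ref_population: list = field(default_factory=list)
    ref_diagonal: list = field(default_factory=list)
    ref_switches: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.shift)


@dataclass
class SpawnRecord:
    parent: Determinant
    child: Determinant
    count: int  # signed
    parent_population: float


class WalkerStore(dict):
    """Signed populations keyed by determinant; zero entries are dropped."""

    @property
    def n_walkers(self) -> float:
        return sum(abs(v) for v in self.values())

    def add(self, det: Determinant, count: float) -> None:
        new = self.get(det, 0) + count
        if new == 0:
            self.pop(det, None)
        else:
            self[det] = new


def stochastic_round(x: float, rng: np.random.Generator) -> int:
    """Unbiased rounding of a nonnegative real to a neighboring integer."""
    low = math.floor(x)
    return low + (1 if rng.random() < x - low else 0)


# ---------------------------------------------------------------------------
# Vectorized Slater–Condon helpers (shared by the batched driver and tests)
# ---------------------------------------------------------------------------

def _count_below(occ_bits, t: np.ndarray) -> np.ndarray:
    """Occupied spin orbitals strictly below each index in ``t``.

    ``occ_bits`` may be a scalar or an array broadcastable against ``t``.
    """
    masks = (np.int64(1) << t) - np.int64(1)
    return np.bitwise_count(np.asarray(occ_bits, dtype=np.int64) & masks).astype(
        np.int64
    )


def double_elements_batch(
    occ_bits,
    p: np.ndarray,
    q: np.ndarray,
    r: np.ndarray,
    s: np.ndarray,
    g: np.ndarray,
    n: int,
) -> np.ndarray:
    """Signed double-excitation elements for holes ``p<q`` -> particles ``r<s``.

    Same phase convention as :func:`stochgas.hamiltonian.matrix_element`.
    """
    par = (
        _count_below(occ_bits, p)
        + _count_below(occ_bits, q) - 1
        + _count_below(occ_bits, s) - (p < s) - (q < s)
        + _count_below(occ_bits, r) - (p < r) - (q < r)
    )
    sign = 1 - 2 * (par & 1)
    pn, qn, rn, sn = p % n, q % n, r % n, s % n
    direct = g[pn, rn, qn, sn] * (((p < n) == (r < n)) & ((q < n) == (s < n)))
    exch = g[pn, sn, qn, rn] * (((p < n) == (s < n)) & ((q < n) == (r < n)))
    return sign * (direct - exch)


def single_phase_batch(occ_bits, I: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Fermionic sign of single excitations ``I -> A`` (vectorized)."""
    par = _count_below(occ_bits, I) + _count_below(occ_bits, A) - (I < A)
    return 1 - 2 * (par & 1)


def _member(values: np.ndarray, sorted_table: np.ndarray) -> np.ndarray:
    """Vectorized membership of ``values`` in a sorted int array."""
    if sorted_table.size == 0:
        return np.zeros(values.size, dtype=bool)
    pos = np.searchsorted(sorted_table, values)
    pos = np.minimum(pos, sorted_table.size - 1)
    return sorted_table[pos] == values


# ---------------------------------------------------------------------------
# Step-level operations (reference path, used directly by unit tests)
# ---------------------------------------------------------------------------

def spawn_step(
    store: WalkerStore,
    tables: PchbTables,
    integrals: IntegralTable,
    dtau: float,
    rng: np.random.Generator,
    sg_table: Optional[SupergroupTable] = None,
) -> list[SpawnRecord]:
    """One spawning sweep: every walker makes one excitation attempt.

    Accepts spawns with probability ``dtau |K_ij| / p_gen`` (values above one
    yield multiple children); the child sign follows ``-sign(parent) *
    sign(K_ij)``.
    """
    buffer: list[SpawnRecord] = []
    for det, pop in list(store.items()):
        attempts = stochastic_round(abs(pop), rng)
        parent_sign = 1 if pop > 0 else -1
        for _ in range(attempts):
            out = sample_event(det, tables, rng)
            if isinstance(out, Rejection):
                continue
            if sg_table is not None:
                k_ij = gas_masked_element(det, out.child, integrals, sg_table)
            else:
                k_ij = matrix_element(det, out.child, integrals)
            if k_ij == 0.0:
                continue
            p_acc = dtau * abs(k_ij) / out.p_gen
            n_spawn = stochastic_round(p_acc, rng)
            if n_spawn == 0:
                continue
            sign = -parent_sign * (1 if k_ij > 0 else -1)
            buffer.append(SpawnRecord(det, out.child, sign * n_spawn, pop))
    return buffer


def death_step(
    store: WalkerStore,
    integrals: IntegralTable,
    e_ref: float,
    shift_of,
    dtau: float,
    rng: np.random.Generator,
) -> bool:
    """Diagonal death/cloning; returns True when the time step looks too long.

    ``shift_of(det)`` supplies the (possibly determinant-local) shift.  Each
    walker dies with probability ``dtau (K_jj - S)``; a negative probability
    clones instead.
    """
    warned = False
    for det, pop in list(store.items()):
        p_death = dtau * (diagonal_element(det, integrals) - e_ref - shift_of(det))
        if abs(p_death) > 1.0:
            warned = True
        change = stochastic_round(abs(p_death) * abs(pop), rng)
        if change == 0:
            continue
        sign = 1 if pop > 0 else -1
        store.add(det, -sign * change if p_death > 0 else sign * change)
    return warned


def initiator_filter(
    parent_population: float, child_occupied: bool, n_add: float
) -> bool:
    """True when a spawn survives: vetoed only if the parent sits below the
    initiator threshold *and* the child determinant is empty."""
    return child_occupied or abs(parent_population) >= n_add


def annihilate(
    store: WalkerStore,
    buffer: Sequence[SpawnRecord],
    initiator: bool = False,
    n_add: float = 3.0,
) -> WalkerStore:
    """Merge signed spawns into the store (order-independent by construction).

    The initiator veto is applied against the pre-merge occupancy, so
    coincident spawns within one iteration do not unlock each other.
    """
    occupied = set(store.keys()) if initiator else None
    for rec in buffer:
        if initiator and not initiator_filter(
            rec.parent_population, rec.child in occupied, n_add
        ):
            continue
        store.add(rec.child, rec.count)
    return store


def update_shift(
    S: float,
    n_now: float,
    n_then: float,
    dtau: float,
    damping: float,
    interval: int,
    n_target: Optional[float] = None,
    restore: float = 0.0,
) -> float:
    """Damped population-control update; at stationarity S tracks E_corr.

    The optional ``restore`` term adds weak proportional control toward the
    target population, which removes the stationary population offset that a
    pure integral update leaves when the shift starts away from the
    correlation energy.
    """
    correction = math.log(n_now / n_then)
    if restore and n_target:
        correction += restore * math.log(n_now / n_target)
    return S - damping / (interval * dtau) * correction


def adaptive_shift(S: float, f_i: float, delta: float) -> float:
    """Local shift ``S_i = Delta + f_i (S - Delta)`` of a non-initiator."""
    return delta + f_i * (S - delta)


def semistochastic_project(
    core_pops: np.ndarray,
    core_matrix: np.ndarray,
    e_ref: float,
    shift: float,
    dtau: float,
) -> np.ndarray:
    """Exact application of ``1 - dtau (H^core - E_ref - S)`` to the core."""
    return core_pops - dtau * (
        core_matrix @ core_pops - (e_ref + shift) * core_pops
    )


# ---------------------------------------------------------------------------
# Blocking analysis
# ---------------------------------------------------------------------------

@dataclass
class BlockingResult:
    error: float
    curve: np.ndarray
    plateau_found: bool


def blocking_error(series: Sequence[float], min_blocks: int = 16) -> BlockingResult:
    """Flyvbjerg–Petersen blocking: successive pair averaging.

    The standard error is read off at the first level whose increase over the
    previous level falls within the error-of-the-error (a plateau); if the
    curve never flattens the maximum is returned with ``plateau_found=False``.
    Constant series return error 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 64:
        raise ValueError("blocking needs at least 64 samples")
    if np.allclose(x, x[0]):
        return BlockingResult(0.0, np.zeros(1), True)
    curve: list[float] = []
    eoe: list[float] = []
    data = x
    while data.size >= min_blocks:
        n = data.size
        se = data.std(ddof=1) / math.sqrt(n)
        curve.append(se)
        eoe.append(se / math.sqrt(2 * (n - 1)))
        if data.size % 2:
            data = data[:-1]
        data = 0.5 * (data[0::2] + data[1::2])
    curve_arr = np.array(curve)
    for k in range(1, len(curve)):
        if curve[k] - curve[k - 1] <= eoe[k - 1]:
            return BlockingResult(float(max(curve[: k + 1])), curve_arr, True)
    return BlockingResult(float(curve_arr.max()), curve_arr, False)


def projected_energy(
    series: TimeSeries, equilibration: int
) -> tuple[float, float, BlockingResult]:
    """Projected-energy estimate with a blocking error bar.

    Numerator and denominator are summed separately before the ratio; the
    error bar is a blocking analysis of the per-iteration ratio series.
    Samples before the last reference switch are discarded.
    """
    start = equilibration
    for t in range(len(series)):
        if series.ref_switches[t]:
            start = max(start, t + 1)
    num = np.asarray(series.numerator[start:], dtype=float)
    den = np.asarray(series.denominator[start:], dtype=float)
    diag = np.asarray(series.ref_diagonal[start:], dtype=float)
    if num.size == 0 or np.any(den == 0):
        raise ValueError("zero-denominator window in projected-energy series")
    estimate = float(np.sum(num + diag * den) / np.sum(den))
    ratio = num / den + diag
    blocking = blocking_error(ratio)
    return estimate, blocking.error, blocking


# ---------------------------------------------------------------------------
# Batched driver
# ---------------------------------------------------------------------------

class _DetInfo:
    """Static per-determinant data reused across iterations."""

    __slots__ = (
        "det", "occ", "occ_bits", "isg", "diag", "pair_ids",
        "alias_list", "hole_mat", "hole_counts", "single_elems", "npair",
    )

    def __init__(self, det: Determinant, tables: PchbTables,
                 integrals: IntegralTable):
        n = tables.n_orb
        self.det = det
        occ = np.array(
            det.occupied_alpha() + [n + p for p in det.occupied_beta()],
            dtype=np.int64,
        )
        self.occ = occ
        self.occ_bits = det.spin_orbitals(n)
        self.isg = tables.supergroup_index0(det)
        self.diag = diagonal_element(det, integrals)
        ne = occ.size
        ii, jj = np.triu_indices(ne, k=1)
        I, J = occ[ii], occ[jj]
        self.pair_ids = tables.pair_id[I, J]
        self.npair = I.size
        self.alias_list = [tables.alias[self.isg][int(p)] for p in self.pair_ids]

        # Singles: allowed holes and their Slater–Condon magnitudes (no phase)
        # per occupied particle; the phase is applied per event.
        g, h = integrals.g, integrals.h
        occ_n = occ % n
        hole_lists, elem_lists = [], []
        for t in range(ne):
            I_so = int(occ[t])
            mask = tables.single_hole_mask(self.isg, I_so)
            same_spin_occ = det.alpha if I_so < n else det.beta
            avail = mask & ~same_spin_occ
            holes_spatial = []
            x = avail
            while x:
                low = x & -x
                holes_spatial.append(low.bit_length() - 1)
                x ^= low
            a_n = np.array(holes_spatial, dtype=np.int64)
            if a_n.size:
                i_n = I_so % n
                G1 = g[i_n]
                coul = G1[a_n][:, occ_n, occ_n].sum(axis=1)
                same = occ[(occ >= n) == (I_so >= n)] % n
                exch = G1[same, same, :][:, a_n].sum(axis=0)
                vals = (
                    h[i_n, a_n] + coul - exch
                    - (G1[a_n, i_n, i_n] - G1[i_n, i_n, a_n])
                )
                holes_so = a_n + (0 if I_so < n else n)
            else:
                vals = np.zeros(0)
                holes_so = a_n
            hole_lists.append(holes_so)
            elem_lists.append(vals)
        max_h = max((len(hl) for hl in hole_lists), default=0)
        self.hole_mat = np.zeros((ne, max(max_h, 1)), dtype=np.int64)
        self.single_elems = np.zeros((ne, max(max_h, 1)))
        self.hole_counts = np.zeros(ne, dtype=np.int64)
        for t, (hl, el) in enumerate(zip(hole_lists, elem_lists)):
            self.hole_counts[t] = len(hl)
            self.hole_mat[t, : len(hl)] = hl
            self.single_elems[t, : len(hl)] = el


@dataclass
class FciqmcResult:
    series: TimeSeries
    store: WalkerStore
    e_ref: float
    energy: float
    error: float
    blocking: BlockingResult
    dtau: float
    time_step_warnings: int
    shift_mean: float


class FciqmcRun:
    """Batched FCIQMC driver; see module docstring for the step structure."""

    def __init__(
        self,
        integrals: IntegralTable,
        tables: PchbTables,
        cfg: DynamicsConfig,
        reference: Determinant,
        sg_table: Optional[SupergroupTable] = None,
    ):
        self.integrals = integrals
        self.tables = tables
        self.cfg = cfg
        self.sg_table = sg_table if sg_table is not None else tables.sg_table
        self.rng = np.random.default_rng(cfg.seed)
        self.n = integrals.n_orb
        if self.sg_table is not None and not self.sg_table.contains(
            supergroup_of_determinant(reference, self.sg_table.partition)
        ):
            raise ValueError("reference determinant is GAS-forbidden")
        self.reference = reference
        self.e_ref = diagonal_element(reference, integrals)

        self.store = WalkerStore()
        init = cfg.initial_population
        if init is None:
            init = cfg.target_population
        self.store[reference] = float(round(init))

        self.info_cache: dict[Determinant, _DetInfo] = {}
        self.diag_cache: dict[Determinant, float] = {}
        self.varying_shift = self.store.n_walkers >= cfg.target_population
        self.series = TimeSeries()
        self.iteration = 0
        self.time_step_warnings = 0
        self._pop_at_update = self.store.n_walkers
        self._switch_count = 0
        self._ref_conn: dict[Determinant, float] = {}
        self._build_ref_connections()
        self.shift = cfg.initial_shift
        self.f_acc: dict[Determinant, float] = {}
        self.f_tot: dict[Determinant, float] = {}
        self._lambda = 0.5 ** (1.0 / cfg.forgetting_half_life)
        self._instant_energy = self.e_ref

        self.core_index: dict[Determinant, int] = {}
        self.core_dets: list[Determinant] = []
        self.core_matrix: Optional[np.ndarray] = None
        self.rdm_accumulator = None  # set by stochgas.rdm.sampled_rdms

        self.dtau = cfg.time_step if cfg.time_step is not None else self._auto_dtau()

    # -- setup helpers -----------------------------------------------------

    def _auto_dtau(self, n_probe: int = 500) -> float:
        """Freeze dtau from a warm-up scan: 0.9 / max(|K_ij| / p_gen)."""
        rng = np.random.default_rng(self.cfg.seed + 1)
        worst = 0.0
        for _ in range(n_probe):
            out = sample_event(self.reference, self.tables, rng)
            if isinstance(out, Rejection):
                continue
            k = self._element(self.reference, out.child)
            if k != 0.0:
                worst = max(worst, abs(k) / out.p_gen)
        return 0.9 / worst if worst > 0 else 1e-3

    def _element(self, d_i: Determinant, d_j: Determinant) -> float:
        if self.sg_table is not None:
            return gas_masked_element(d_i, d_j, self.integrals, self.sg_table)
        return matrix_element(d_i, d_j, self.integrals)

    def pt2_correlation_estimate(self) -> float:
        """Epstein–Nesbet second-order correlation energy of the reference.

        A cheap a-priori scale for the correlation energy, useful for
        choosing ``initial_shift`` or an absolute adaptive offset (the
        customary starting point is half the correlation energy).
        """
        e2 = 0.0
        for child, h in self._ref_conn.items():
            gap = self._diag(child) - self.e_ref
            if gap > 1e-8:
                e2 -= h * h / gap
        return e2

    def _build_ref_connections(self) -> None:
        conn = {}
        for child in connected_excitations(self.reference, self.n):
            v = self._element(self.reference, child)
            if v != 0.0:
                conn[child] = v
        self._ref_conn = conn

    def _info(self, det: Determinant) -> _DetInfo:
        info = self.info_cache.get(det)
        if info is None:
            info = _DetInfo(det, self.tables, self.integrals)
            self.info_cache[det] = info
            self.diag_cache[det] = info.diag
        return info

    def _diag(self, det: Determinant) -> float:
        d = self.diag_cache.get(det)
        if d is None:
            d = diagonal_element(det, self.integrals)
            self.diag_cache[det] = d
        return d

    # -- semistochastic core -----------------------------------------------

    def build_core(self, size: Optional[int] = None) -> None:
        """Freeze the core space as the currently most populated determinants.

        Ties at equal population break toward the smaller determinant hash so
        the choice is reproducible across runs with the same seed.
        """
        size = self.cfg.core_size if size is None else size
        if size <= 0:
            return
        ranked = sorted(
            self.store.items(), key=lambda kv: (-abs(kv[1]), hash(kv[0]))
        )[:size]
        self.core_dets = [d for d, _ in ranked]
        if self.sg_table is not None:
            for d in self.core_dets:
                assert self.sg_table.contains(
                    supergroup_of_determinant(d, self.sg_table.partition)
                ), "GAS-forbidden determinant in core space"
        self.core_index = {d: a for a, d in enumerate(self.core_dets)}
        dim = len(self.core_dets)
        mat = np.zeros((dim, dim))
        for a in range(dim):
            mat[a, a] = self._diag(self.core_dets[a])
            for b in range(a + 1, dim):
                v = self._element(self.core_dets[a], self.core_dets[b])
                mat[a, b] = mat[b, a] = v
        self.core_matrix = mat

    # -- one iteration -------------------------------------------------------

    def _stack_infos(self, dets: list[Determinant]):
        """Stack per-determinant static data into batch arrays."""
        infos = [self._info(d) for d in dets]
        D = len(infos)
        ne = infos[0].occ.size if D else 0
        occ_mat = np.empty((D, ne), dtype=np.int64)
        occ_bits = np.empty(D, dtype=np.int64)
        isg = np.empty(D, dtype=np.int64)
        pid_mat = np.empty((D, infos[0].npair if D else 0), dtype=np.int64)
        diag = np.empty(D)
        hmax = max((i.hole_mat.shape[1] for i in infos), default=1)
        hole3 = np.zeros((D, ne, hmax), dtype=np.int64)
        elem3 = np.zeros((D, ne, hmax))
        hcnt = np.empty((D, ne), dtype=np.int64)
        for a, info in enumerate(infos):
            occ_mat[a] = info.occ
            occ_bits[a] = info.occ_bits
            isg[a] = info.isg
            pid_mat[a] = info.pair_ids
            diag[a] = info.diag
            w = info.hole_mat.shape[1]
            hole3[a, :, :w] = info.hole_mat
            elem3[a, :, :w] = info.single_elems
            hcnt[a] = info.hole_counts
        return occ_mat, occ_bits, isg, pid_mat, diag, hole3, elem3, hcnt

    def _spawn_batches(self, dets, pops, occ_mat, occ_bits, isg, pid_mat,
                       hole3, elem3, hcnt):
        """Vectorized spawning sweep, batched globally across determinants.

        Alias draws are grouped by ``(supergroup, particle-pair)`` key — a
        small fixed set — so the cost per iteration is a handful of array
        passes over the attempt list, not a Python loop over walkers.
        """
        rng = self.rng
        dtau = self.dtau
        n = self.n
        p_double = self.tables.p_double
        D = len(dets)
        ne = occ_mat.shape[1]
        npair = ne * (ne - 1) // 2
        abs_pops = np.abs(pops)
        attempts = np.floor(abs_pops).astype(np.int64)
        attempts += rng.random(D) < (abs_pops - attempts)
        nd_vec = rng.binomial(attempts, p_double)
        ns_vec = attempts - nd_vec
        parent_sign = np.where(pops > 0, 1, -1).astype(np.int64)

        out = []  # list of (child_a, child_b, count, parent_row, kmag) arrays

        ii_g, jj_g = np.triu_indices(ne, k=1)
        total_nd = int(nd_vec.sum())
        if total_nd and npair:
            prow = np.repeat(np.arange(D), nd_vec)
            u = rng.integers(npair, size=total_nd)
            pid = pid_mat[prow, u]
            key = isg[prow] * (self.tables.pair_A.size + 1) + pid
            order = np.argsort(key, kind="stable")
            keys_sorted = key[order]
            boundaries = np.nonzero(np.diff(keys_sorted))[0] + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [total_nd]))
            ab = np.full(total_nd, -1, dtype=np.int64)
            pab = np.zeros(total_nd)
            for st, en in zip(starts, ends):
                kk = int(keys_sorted[st])
                isg_k, pid_k = divmod(kk, self.tables.pair_A.size + 1)
                alias = self.tables.alias[isg_k][pid_k]
                if alias is None:
                    continue  # empty row: every attempt is a rejection
                sel = order[st:en]
                drawn = alias.sample_many(rng, en - st)
                ab[sel] = drawn
                pab[sel] = alias.probabilities[drawn]
            live = ab >= 0
            if np.any(live):
                prow_l = prow[live]
                ab_l = ab[live]
                A = self.tables.pair_A[ab_l]
                B = self.tables.pair_B[ab_l]
                I = occ_mat[prow_l, ii_g[u[live]]]
                J = occ_mat[prow_l, jj_g[u[live]]]
                bits = occ_bits[prow_l]
                free = (((bits >> A) & 1) == 0) & (((bits >> B) & 1) == 0)
                if np.any(free):
                    prow_l, A, B = prow_l[free], A[free], B[free]
                    I, J = I[free], J[free]
                    bits = bits[free]
                    pab_l = pab[live][free]
                    p, q = np.minimum(I, J), np.maximum(I, J)
                    r, s = np.minimum(A, B), np.maximum(A, B)
                    kv = double_elements_batch(bits, p, q, r, s,
                                               self.integrals.g, n)
                    p_acc = dtau * np.abs(kv) * npair / (p_double * pab_l)
                    nsp = np.floor(p_acc).astype(np.int64)
                    nsp += rng.random(p_acc.size) < (p_acc - nsp)
                    keep = (nsp > 0) & (kv != 0.0)
                    if np.any(keep):
                        child_bits = (
                            (bits[keep]
                             ^ (np.int64(1) << p[keep])
                             ^ (np.int64(1) << q[keep]))
                            | (np.int64(1) << A[keep])
                            | (np.int64(1) << B[keep])
                        )
                        pr = prow_l[keep]
                        sgn = np.where(kv[keep] > 0, -parent_sign[pr],
                                       parent_sign[pr])
                        out.append((child_bits, sgn * nsp[keep], pr,
                                    np.abs(kv[keep])))

        total_ns = int(ns_vec.sum())
        if total_ns:
            prow = np.repeat(np.arange(D), ns_vec)
            t_idx = rng.integers(ne, size=total_ns)
            cnts = hcnt[prow, t_idx]
            ok = cnts > 0
            if np.any(ok):
                prow, t_idx, cnts = prow[ok], t_idx[ok], cnts[ok]
                j = (rng.random(prow.size) * cnts).astype(np.int64)
                A = hole3[prow, t_idx, j]
                I = occ_mat[prow, t_idx]
                bits = occ_bits[prow]
                kv = single_phase_batch(bits, I, A) * elem3[prow, t_idx, j]
                p_acc = dtau * np.abs(kv) * ne * cnts / (1.0 - p_double)
                nsp = np.floor(p_acc).astype(np.int64)
                nsp += rng.random(p_acc.size) < (p_acc - nsp)
                keep = (nsp > 0) & (kv != 0.0)
                if np.any(keep):
                    child_bits = (
                        bits[keep] ^ (np.int64(1) << I[keep])
                    ) | (np.int64(1) << A[keep])
                    pr = prow[keep]
                    sgn = np.where(kv[keep] > 0, -parent_sign[pr],
                                   parent_sign[pr])
                    out.append((child_bits, sgn * nsp[keep], pr,
                                np.abs(kv[keep])))

        if not out:
            return (np.zeros(0, dtype=np.int64),) * 3 + (np.zeros(0),)
        child_bits = np.concatenate([o[0] for o in out])
        counts = np.concatenate([o[1] for o in out])
        prows = np.concatenate([o[2] for o in out])
        kmags = np.concatenate([o[3] for o in out])
        return child_bits, counts, prows, kmags

    def _shift_of(self, det: Determinant, pop: float) -> float:
        cfg = self.cfg
        if not (cfg.initiator and cfg.adaptive):
            return self.shift
        if abs(pop) >= cfg.n_add:
            return self.shift  # initiators keep the global shift
        if cfg.adaptive_offset is not None:
            delta = cfg.adaptive_offset
        elif cfg.adaptive_offset_frac is not None:
            delta = cfg.adaptive_offset_frac * self.shift
        else:
            delta = 0.0
        acc = self.f_acc.get(det, 0.0)
        tot = self.f_tot.get(det, 0.0)
        f_i = acc / tot if tot > 0 else 1.0
        return adaptive_shift(self.shift, f_i, delta)

    def iterate(self) -> None:
        cfg = self.cfg
        rng = self.rng
        dets = list(self.store.keys())
        pops = np.array([self.store[d] for d in dets], dtype=float)
        (occ_mat, occ_bits, isg, pid_mat, diag_vec,
         hole3, elem3, hcnt) = self._stack_infos(dets)
        child_bits, counts, prows, kmags = self._spawn_batches(
            dets, pops, occ_mat, occ_bits, isg, pid_mat, hole3, elem3, hcnt
        )
        spatial_mask = np.int64((1 << self.n) - 1)

        # Discarding mode: GAS-aware tables never propose forbidden children,
        # but plain FCI tables do — apply the mask a posteriori here.
        if (
            self.sg_table is not None
            and not self.tables.gas
            and child_bits.size
        ):
            part = self.sg_table.partition
            uniq, inv = np.unique(child_bits, return_inverse=True)
            ok = np.array([
                self.sg_table.contains(
                    supergroup_of_determinant(
                        Determinant(int(b) & int(spatial_mask),
                                    int(b) >> self.n),
                        part,
                    )
                )
                for b in uniq
            ])
            live = ok[inv]
            child_bits = child_bits[live]
            counts = counts[live]
            prows = prows[live]
            kmags = kmags[live]

        # Optional RDM sampling hook (state before this iteration's update).
        if self.rdm_accumulator is not None:
            child_a = (child_bits & spatial_mask).tolist()
            child_b = (child_bits >> np.int64(self.n)).tolist()
            prows_l = prows.tolist()
            self.rdm_accumulator.collect(
                self.store,
                list(zip(child_a, child_b)),
                counts.tolist(),
                [dets[i] for i in prows_l],
                [pops[i] for i in prows_l],
                kmags.tolist(),
                self.dtau,
            )

        # Initiator veto + adaptive-shift bookkeeping (vectorized).
        adaptive = cfg.initiator and cfg.adaptive
        core_set = self.core_index
        keep = np.ones(child_bits.size, dtype=bool)
        if core_set:
            core_bits = np.sort(
                np.array(
                    [d.spin_orbitals(self.n) for d in self.core_dets],
                    dtype=np.int64,
                )
            )
            child_in_core = _member(child_bits, core_bits)
            parent_in_core = np.array(
                [d in core_set for d in dets], dtype=bool
            )[prows]
            keep &= ~(child_in_core & parent_in_core)
        accepted = keep.copy()
        if cfg.initiator:
            occ_sorted = np.sort(occ_bits)
            child_occupied = _member(child_bits, occ_sorted)
            accepted &= child_occupied | (
                np.abs(pops[prows]) >= cfg.n_add
            )
        if adaptive and child_bits.size:
            uniq, inv = np.unique(child_bits, return_inverse=True)
            diag_u = np.array(
                [
                    self._diag(
                        Determinant(int(b) & ((1 << self.n) - 1),
                                    int(b) >> self.n)
                    )
                    for b in uniq
                ]
            )
            denom = np.maximum(diag_u[inv] - self._instant_energy, 1e-2)
            w = kmags / denom
            D = len(dets)
            tot_arr = np.zeros(D)
            acc_arr = np.zeros(D)
            np.add.at(tot_arr, prows[keep], w[keep])
            np.add.at(acc_arr, prows[accepted], w[accepted])
            lam = self._lambda
            for a in np.nonzero(tot_arr)[0]:
                det = dets[a]
                self.f_tot[det] = lam * self.f_tot.get(det, 0.0) + tot_arr[a]
                self.f_acc[det] = lam * self.f_acc.get(det, 0.0) + acc_arr[a]

        # Merge accepted spawns per unique child.
        merged_bits = np.zeros(0, dtype=np.int64)
        merged_counts = np.zeros(0, dtype=np.int64)
        if np.any(accepted):
            uniq, inv = np.unique(child_bits[accepted], return_inverse=True)
            sums = np.bincount(inv, weights=counts[accepted]).astype(np.int64)
            live = sums != 0
            merged_bits, merged_counts = uniq[live], sums[live]

        # Deterministic core propagation (diagonal included in H^core).
        if self.core_matrix is not None:
            core_pops = np.array(
                [self.store.get(d, 0.0) for d in self.core_dets], dtype=float
            )
            new_core = semistochastic_project(
                core_pops, self.core_matrix, self.e_ref, self.shift, self.dtau
            )

        # Stochastic death / cloning outside the core (vectorized).
        if cfg.initiator and cfg.adaptive:
            shift_vec = np.array(
                [self._shift_of(d, p) for d, p in zip(dets, pops)]
            )
        else:
            shift_vec = self.shift
        p_death = self.dtau * (diag_vec - self.e_ref - shift_vec)
        self.time_step_warnings += int(np.count_nonzero(np.abs(p_death) > 1.0))
        mean_change = np.abs(p_death) * np.abs(pops)
        change = np.floor(mean_change).astype(np.int64)
        change += rng.random(len(dets)) < (mean_change - change)
        for a in np.nonzero(change)[0]:
            det = dets[a]
            if core_set and det in core_set:
                continue
            sign = 1 if pops[a] > 0 else -1
            delta = -sign * int(change[a]) if p_death[a] > 0 else sign * int(change[a])
            self.store.add(det, delta)

        # Annihilation: merge signed spawns.
        for b, cnt in zip(merged_bits.tolist(), merged_counts.tolist()):
            self.store.add(
                Determinant(b & ((1 << self.n) - 1), b >> self.n), cnt
            )

        # Core populations: deterministic update plus stochastic arrivals.
        if self.core_matrix is not None:
            for a, d in enumerate(self.core_dets):
                arrivals = self.store.get(d, 0.0) - core_pops[a]
                val = new_core[a] + arrivals
                if val == 0.0:
                    self.store.pop(d, None)
                else:
                    self.store[d] = val

        # Debug-mode GAS closure assertion.
        if __debug__ and self.sg_table is not None and self.tables.gas:
            for d in self.store:
                assert self.sg_table.contains(
                    supergroup_of_determinant(d, self.sg_table.partition)
                ), "GAS-forbidden determinant occupied"

        # Record the time series (end-of-iteration state).
        ref_pop = self.store.get(self.reference, 0.0)
        num = 0.0
        if len(self._ref_conn) < len(self.store):
            for child, hval in self._ref_conn.items():
                c = self.store.get(child)
                if c is not None:
                    num += hval * c
        else:
            for det, c in self.store.items():
                hval = self._ref_conn.get(det)
                if hval is not None:
                    num += hval * c
        nw = self.store.n_walkers
        switched = self._maybe_switch_reference()
        self.series.shift.append(self.shift)
        self.series.n_walkers.append(nw)
        self.series.numerator.append(num)
        self.series.denominator.append(ref_pop)
        self.series.ref_population.append(abs(ref_pop))
        self.series.ref_diagonal.append(self.e_ref)
        self.series.ref_switches.append(switched)
        if ref_pop:
            self._instant_energy = self.e_ref + num / ref_pop

        # Shift control.
        self.iteration += 1
        if not self.varying_shift:
            if nw >= cfg.target_population:
                self.varying_shift = True
                self._pop_at_update = nw
        elif self.iteration % cfg.shift_interval == 0:
            if nw > 0 and self._pop_at_update > 0:
                self.shift = update_shift(
                    self.shift, nw, self._pop_at_update, self.dtau,
                    cfg.shift_damping, cfg.shift_interval,
                    n_target=cfg.target_population,
                    restore=cfg.population_restore,
                )
            self._pop_at_update = nw

    def _maybe_switch_reference(self) -> bool:
        cfg = self.cfg
        ref_pop = abs(self.store.get(self.reference, 0.0))
        challenger = 0.0
        for det, pop in self.store.items():
            if det != self.reference and abs(pop) > challenger:
                challenger = abs(pop)
        if challenger > cfg.reference_switch_factor * max(ref_pop, 1.0):
            self._switch_count += 1
        else:
            self._switch_count = 0
        if self._switch_count >= cfg.reference_switch_patience:
            self.reference = max(self.store, key=lambda d: abs(self.store[d]))
            self.e_ref = self._diag(self.reference)
            self._build_ref_connections()
            self._switch_count = 0
            return True
        return False

    def run(self, n_iterations: Optional[int] = None) -> FciqmcResult:
        n_iter = self.cfg.max_iterations if n_iterations is None else n_iterations
        for _ in range(n_iter):
            self.iterate()
        energy, error, blocking = projected_energy(
            self.series, self.cfg.equilibration
        )
        shifts = np.asarray(self.series.shift[self.cfg.equilibration:])
        return FciqmcResult(
            self.series, self.store, self.e_ref, energy, error, blocking,
            self.dtau, self.time_step_warnings,
            float(shifts.mean()) if shifts.size else float("nan"),
        )


def run_fciqmc(
    integrals: IntegralTable,
    tables: PchbTables,
    cfg: DynamicsConfig,
    reference: Determinant,
    sg_table: Optional[SupergroupTable] = None,
    n_iterations: Optional[int] = None,
) -> FciqmcResult:
    """Build a driver, optionally freeze a semistochastic core, and run.

    The core space is selected from the walker distribution after the
    equilibration phase, when the populations reflect the wave function
    rather than the initial reference-only state.
    """
    run = FciqmcRun(integrals, tables, cfg, reference, sg_table)
    n_iter = cfg.max_iterations if n_iterations is None else n_iterations
    if cfg.core_size > 0:
        warm = min(cfg.equilibration, n_iter)
        for _ in range(warm):
            run.iterate()
        run.build_core()
        return run.run(n_iter - warm)
    return run.run(n_iter)
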