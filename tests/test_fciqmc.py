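"""Walker dynamics: steps, refinements, estimators, blocking."""

import numpy as np
import pytest

from stochgas.excitgen import build_pchb_tables
from stochgas.fciqmc import (
    DynamicsConfig,
    FciqmcRun,
    TimeSeries,
    WalkerStore,
    adaptive_shift,
    annihilate,
    blocking_error,
    death_step,
    double_elements_batch,
    initiator_filter,
    projected_energy,
    run_fciqmc,
    semistochastic_project,
    single_phase_batch,
    spawn_step,
    SpawnRecord,
    stochastic_round,
    update_shift,
)
from stochgas.gas_constraints import (
    GASPartition,
    LocalConstraints,
    build_supergroup_table,
    supergroup_of_determinant,
)
from stochgas.hamiltonian import (
    Determinant,
    connected_excitations,
    diagonal_element,
    exact_diagonalization,
    hubbard_integrals,
    matrix_element,
    synthetic_integrals,
)
from stochgas.hilbert import enumerate_determinants


@pytest.fixture(scope="module")
def small_system():
    """(4e, 4o) random system with CAS tables and its exact solution."""
    table = synthetic_integrals(4, 7, scale=0.25)
    part = GASPartition([4])
    sg = build_supergroup_table(part, LocalConstraints([0], [8]), 4)
    tables = build_pchb_tables(table, sg, gas=True)
    sol = exact_diagonalization(part, table, sg, 0.0)
    ref = Determinant.from_orbitals([0, 1], [0, 1])
    return table, part, sg, tables, sol, ref


class TestVectorizedElements:
    """The batched Slater–Condon path must agree with the scalar rules."""

    def test_double_and_single_elements_match(self, rand6, cas6):
        part, sg = cas6
        basis = enumerate_determinants(part, sg, 0.0)
        rng = np.random.default_rng(0)
        n = 6
        for det in (basis[i] for i in rng.integers(len(basis), size=8)):
            occ_bits = det.spin_orbitals(n)
            for child in connected_excitations(det, n):
                expect = matrix_element(det, child, rand6)
                cbits = child.spin_orbitals(n)
                diff = occ_bits ^ cbits
                holes = sorted(
                    b for b in range(2 * n)
                    if (diff >> b) & 1 and (occ_bits >> b) & 1
                )
                parts = sorted(
                    b for b in range(2 * n)
                    if (diff >> b) & 1 and (cbits >> b) & 1
                )
                if len(holes) == 2:
                    arr = lambda v: np.array([v], dtype=np.int64)
                    got = double_elements_batch(
                        occ_bits, arr(holes[0]), arr(holes[1]),
                        arr(parts[0]), arr(parts[1]), rand6.g, n,
                    )[0]
                    assert got == pytest.approx(expect, abs=1e-12)


class TestSpawnStep:
    def test_zero_coupling_never_spawns(self):
        # U=0 Hubbard dimer: double excitations carry no two-body coupling
        table = hubbard_integrals(2, 0.0, 0.0)
        part = GASPartition([2])
        sg = build_supergroup_table(part, LocalConstraints([0], [4]), 2)
        tables = build_pchb_tables(table, sg, gas=True)
        store = WalkerStore({Determinant.from_orbitals([0], [0]): 50})
        buf = spawn_step(store, tables, table, 0.01, np.random.default_rng(0))
        assert buf == []

    def test_expected_spawned_weight(self, small_system):
        table, part, sg, tables, sol, ref = small_system
        dtau = 0.005
        pop = 2000
        rng = np.random.default_rng(12)
        totals: dict[Determinant, float] = {}
        reps = 40
        for _ in range(reps):
            store = WalkerStore({ref: pop})
            for rec in spawn_step(store, tables, table, dtau, rng):
                totals[rec.child] = totals.get(rec.child, 0.0) + rec.count
        checked = 0
        for child in connected_excitations(ref, 4):
            k = matrix_element(ref, child, table)
            expected = -dtau * k * pop
            if abs(expected) < 0.5:
                continue
            got = totals.get(child, 0.0) / reps
            sigma = np.sqrt(3 * abs(expected) / reps)
            assert abs(got - expected) < 5 * sigma
            checked += 1
        assert checked > 5

    def test_gas_buffer_never_contains_forbidden(self, rand6, gas33):
        part, sg = gas33
        tables = build_pchb_tables(rand6, sg, gas=True)
        ref = Determinant.from_orbitals([0, 1, 3], [0, 1, 3])
        store = WalkerStore({ref: 500})
        buf = spawn_step(
            store, tables, rand6, 0.01, np.random.default_rng(5), sg_table=sg
        )
        assert buf
        for rec in buf:
            assert sg.contains(supergroup_of_determinant(rec.child, part))


class TestDeathStep:
    def test_population_preserved_when_diagonal_equals_shift(self):
        table = hubbard_integrals(2, 4.0, 1.0)
        det = Determinant.from_orbitals([0], [0])
        e_ref = diagonal_element(det, table)
        store = WalkerStore({det: 1000})
        death_step(store, table, e_ref, lambda d: 0.0, 0.01,
                   np.random.default_rng(0))
        assert store[det] == 1000

    def test_decay_rate_matches_closed_form(self):
        table = hubbard_integrals(2, 4.0, 1.0)
        det = Determinant.from_orbitals([0], [0])  # doubly occupied: K_jj = U
        e_ref = 0.0
        k_jj = diagonal_element(det, table) - e_ref
        dtau, steps, pop0 = 0.02, 25, 20000
        rng = np.random.default_rng(1)
        store = WalkerStore({det: pop0})
        for _ in range(steps):
            death_step(store, table, e_ref, lambda d: 0.0, dtau, rng)
        expected = pop0 * (1 - dtau * k_jj) ** steps
        sigma = np.sqrt(pop0 * dtau * k_jj * steps)
        assert abs(store.get(det, 0) - expected) < 5 * max(sigma, 1.0)

    def test_large_population_limit_is_linear_update(self):
        table = hubbard_integrals(2, 4.0, 1.0)
        det = Determinant.from_orbitals([0, 1], [])
        e_ref = 0.0
        p = 0.01 * (diagonal_element(det, table) - e_ref)
        pop0 = 10**7
        store = WalkerStore({det: pop0})
        death_step(store, table, e_ref, lambda d: 0.0, 0.01,
                   np.random.default_rng(2))
        assert store[det] == pytest.approx(pop0 * (1 - p), rel=1e-3)


class TestAnnihilate:
    def _rec(self, child, count, parent_pop=10):
        parent = Determinant.from_orbitals([0], [0])
        return SpawnRecord(parent, child, count, parent_pop)

    def test_opposite_signs_cancel(self):
        child = Determinant.from_orbitals([1], [1])
        store = WalkerStore()
        annihilate(store, [self._rec(child, 3), self._rec(child, -3)])
        assert child not in store

    def test_order_independent(self, rng):
        children = [Determinant.from_orbitals([i], [i]) for i in range(4)]
        recs = [
            self._rec(children[int(rng.integers(4))], int(rng.integers(-3, 4)))
            for _ in range(50)
        ]
        s1, s2 = WalkerStore(), WalkerStore()
        annihilate(s1, recs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        annihilate(s2, shuffled)
        assert s1 == s2

    def test_walker_count_matches_tally(self, rng):
        children = [Determinant.from_orbitals([i], [i]) for i in range(4)]
        recs = [
            self._rec(children[int(rng.integers(4))], int(rng.integers(-3, 4)))
            for _ in range(200)
        ]
        store = WalkerStore()
        annihilate(store, recs)
        tally: dict[Determinant, int] = {}
        for r in recs:
            tally[r.child] = tally.get(r.child, 0) + r.count
        assert store.n_walkers == sum(abs(v) for v in tally.values())


class TestShiftControl:
    def test_constant_population_leaves_shift(self):
        assert update_shift(-1.0, 5000, 5000, 0.01, 0.05, 5) == -1.0

    def test_growth_lowers_shift(self):
        assert update_shift(-1.0, 6000, 5000, 0.01, 0.05, 5) < -1.0

    def test_pt2_estimate_is_a_sane_correlation_scale(self, rand6, cas6,
                                                      ref6):
        part, sg = cas6
        tables = build_pchb_tables(rand6, sg, gas=True)
        sol = exact_diagonalization(part, rand6, sg, 0.0)
        run = FciqmcRun(rand6, tables, DynamicsConfig(), ref6)
        e2 = run.pt2_correlation_estimate()
        e_corr = sol.energy - run.e_ref
        assert e2 < 0
        # right order of magnitude for a perturbative estimate
        assert 0.2 * abs(e_corr) < abs(e2) < 5 * abs(e_corr)

    def test_stationary_shift_tracks_correlation_energy(self, rand6, cas6,
                                                        ref6):
        part, sg = cas6
        tables = build_pchb_tables(rand6, sg, gas=True)
        sol = exact_diagonalization(part, rand6, sg, 0.0)
        cfg = DynamicsConfig(time_step=5e-3, target_population=2e4, seed=7,
                             max_iterations=3000, equilibration=1500)
        res = run_fciqmc(rand6, tables, cfg, ref6)
        e_corr = sol.energy - res.e_ref
        shift_err = blocking_error(res.series.shift[1500:]).error
        assert abs(res.shift_mean - e_corr) < max(5 * shift_err, 0.02)


class TestInitiatorFilter:
    def test_strong_parent_spawns_anywhere(self):
        assert initiator_filter(4, False, 3)

    def test_weak_parent_vetoed_on_empty_child(self):
        assert not initiator_filter(1, False, 3)

    def test_weak_parent_allowed_on_occupied_child(self):
        assert initiator_filter(1, True, 3)


class TestAdaptiveShift:
    def test_limits(self):
        assert adaptive_shift(-2.0, 1.0, 0.0) == -2.0
        assert adaptive_shift(-2.0, 0.5, -2.0) == -2.0  # Delta = S
        assert adaptive_shift(-2.0, 0.0, 0.0) == 0.0

    def test_full_offset_reproduces_conventional_initiator(self, small_system):
        """Delta = S collapses the adaptive scheme onto plain i-FCIQMC,
        trajectory for trajectory at fixed seed."""
        table, part, sg, tables, sol, ref = small_system
        common = dict(time_step=5e-3, target_population=2000, seed=42,
                      max_iterations=400, equilibration=100,
                      initiator=True, n_add=3.0)
        plain = DynamicsConfig(**common)
        adapt = DynamicsConfig(adaptive=True, adaptive_offset_frac=1.0,
                               **common)
        r1 = run_fciqmc(table, tables, plain, ref)
        r2 = run_fciqmc(table, tables, adapt, ref)
        assert r1.series.n_walkers == r2.series.n_walkers
        assert r1.series.shift == r2.series.shift
        assert r1.series.numerator == r2.series.numerator


class TestSemistochastic:
    def test_full_core_is_deterministic_power_iteration(self, small_system):
        table, part, sg, tables, sol, ref = small_system
        basis = enumerate_determinants(part, sg, 0.0)
        cfg = DynamicsConfig(time_step=5e-3, target_population=1e15,
                             initial_population=2000,
                             initial_shift=sol.energy - diagonal_element(ref, table),
                             seed=0, max_iterations=4000, equilibration=3500,
                             core_size=len(basis))
        run = FciqmcRun(table, tables, cfg, ref)
        run.store = WalkerStore({d: 0.0 for d in basis})
        run.store[ref] = 2000.0
        run.build_core(len(basis))
        res = run.run()
        assert res.energy == pytest.approx(sol.energy, abs=2e-4)
        assert res.error < 1e-6

    def test_core_reduces_projected_energy_noise(self, small_system):
        table, part, sg, tables, sol, ref = small_system
        common = dict(time_step=5e-3, target_population=3000, seed=9,
                      max_iterations=1200, equilibration=600)
        plain = run_fciqmc(table, tables, DynamicsConfig(**common), ref)
        semis = run_fciqmc(
            table, tables, DynamicsConfig(core_size=12, **common), ref
        )
        assert semis.error < plain.error

    def test_projection_operator(self):
        H = np.array([[1.0, 0.2], [0.2, 2.0]])
        c = np.array([3.0, 1.0])
        out = semistochastic_project(c, H, 0.5, -0.1, 0.01)
        expected = c - 0.01 * (H @ c - 0.4 * c)
        assert np.allclose(out, expected)


class TestProjectedEnergy:
    def test_eigenvector_gives_eigenvalue_exactly(self, small_system):
        table, part, sg, tables, sol, ref = small_system
        cmap = sol.coefficient_map()
        num = sum(
            matrix_element(ref, d, table) * c
            for d, c in cmap.items()
            if d != ref
        )
        den = cmap[ref]
        e_ref = diagonal_element(ref, table)
        series = TimeSeries()
        for _ in range(70):
            series.shift.append(0.0)
            series.n_walkers.append(1.0)
            series.numerator.append(num)
            series.denominator.append(den)
            series.ref_population.append(abs(den))
            series.ref_diagonal.append(e_ref)
            series.ref_switches.append(False)
        est, err, _ = projected_energy(series, 0)
        assert est == pytest.approx(sol.energy, abs=1e-10)
        assert err == 0.0

    def test_zero_denominator_window_raises(self):
        series = TimeSeries()
        for _ in range(70):
            series.shift.append(0.0)
            series.n_walkers.append(1.0)
            series.numerator.append(1.0)
            series.denominator.append(0.0)
            series.ref_population.append(0.0)
            series.ref_diagonal.append(0.0)
            series.ref_switches.append(False)
        with pytest.raises(ValueError, match="denominator"):
            projected_energy(series, 0)


class TestBlocking:
    def test_white_noise(self):
        rng = np.random.default_rng(3)
        sigma, n = 0.7, 2**14
        res = blocking_error(rng.normal(0.0, sigma, size=n))
        assert res.error == pytest.approx(sigma / np.sqrt(n), rel=0.2)

    def test_ar1_inflation(self):
        rng = np.random.default_rng(4)
        phi, n = 0.8, 2**16
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        sigma_x = 1.0 / np.sqrt(1 - phi * phi)
        naive = sigma_x / np.sqrt(n)
        inflation = np.sqrt((1 + phi) / (1 - phi))
        res = blocking_error(x)
        assert res.error == pytest.approx(naive * inflation, rel=0.25)

    def test_constant_series(self):
        res = blocking_error(np.ones(128))
        assert res.error == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            blocking_error(np.ones(10))


class TestStochasticRound:
    def test_unbiased(self):
        rng = np.random.default_rng(5)
        vals = [stochastic_round(2.3, rng) for _ in range(20000)]
        assert np.mean(vals) == pytest.approx(2.3, abs=0.02)
        assert set(vals) <= {2, 3}


class TestDiscardingVsApriori:
    def test_same_energy_and_noisier_baseline(self, rand6, gas33):
        """FCI proposals with a-posteriori masking (the discarding baseline)
        converge to the same GAS energy as the a-priori generator, with an
        equal-iteration blocking error at least as large."""
        part, sg = gas33
        ref = Determinant.from_orbitals([0, 1, 3], [0, 1, 3])
        common = dict(time_step=0.02, target_population=1e4, seed=11,
                      max_iterations=2500, equilibration=800)
        gas_tables = build_pchb_tables(rand6, sg, gas=True)
        apriori = run_fciqmc(rand6, gas_tables, DynamicsConfig(**common),
                             ref, sg_table=sg)
        fci_tables = build_pchb_tables(rand6, None, gas=False)
        discard = run_fciqmc(rand6, fci_tables, DynamicsConfig(**common),
                             ref, sg_table=sg)
        # blocking bars without a detected plateau are lower bounds, so
        # floor each at 2 mHa before combining
        combined = 3 * np.hypot(max(apriori.error, 2e-3),
                                max(discard.error, 2e-3))
        assert abs(apriori.energy - discard.energy) < combined
        for det in discard.store:
            assert sg.contains(supergroup_of_determinant(det, part))
        assert discard.error >= apriori.error


class TestGasClosure:
    def test_dynamics_never_occupies_forbidden(self, rand6, gas33):
        part, sg = gas33
        tables = build_pchb_tables(rand6, sg, gas=True)
        ref = Determinant.from_orbitals([0, 1, 3], [0, 1, 3])
        cfg = DynamicsConfig(time_step=5e-3, target_population=3000, seed=2,
                             max_iterations=300, equilibration=100)
        res = run_fciqmc(rand6, tables, cfg, ref, sg_table=sg)
        for det in res.store:
            assert sg.contains(supergroup_of_determinant(det, part))
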