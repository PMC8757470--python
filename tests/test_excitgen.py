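"""Alias sampling and the PCHB excitation generators."""

import numpy as np
import pytest
import scipy.stats

from stochgas.excitgen import (
    AliasTable,
    ExcitationEvent,
    Rejection,
    build_alias,
    build_pchb_tables,
    discarding_generator,
    memory_estimate,
    pgen,
    sample_double,
    sample_event,
    sample_single,
)
from stochgas.gas_constraints import (
    GASPartition,
    LocalConstraints,
    band_constraints,
    build_supergroup_table,
    disconnected_constraints,
    supergroup_of_determinant,
)
from stochgas.hamiltonian import Determinant, synthetic_integrals
from stochgas.hilbert import enumerate_determinants
from stochgas.validate import enumerate_pgen, frequency_harness


class TestAliasTable:
    def test_single_outcome(self, rng):
        at = build_alias([1.0])
        assert all(at.sample(rng) == 0 for _ in range(20))

    def test_uniform_frequencies_pass_chi2(self):
        at = build_alias([1.0, 1.0, 1.0, 1.0])
        rng = np.random.default_rng(7)
        draws = at.sample_many(rng, 100000)
        counts = np.bincount(draws, minlength=4)
        chi2 = ((counts - 25000.0) ** 2 / 25000.0).sum()
        assert chi2 < scipy.stats.chi2.ppf(0.999, 3)

    def test_zero_weight_never_drawn_and_ratio(self):
        at = build_alias([0.0, 3.0, 1.0])
        rng = np.random.default_rng(8)
        draws = at.sample_many(rng, 40000)
        counts = np.bincount(draws, minlength=3)
        assert counts[0] == 0
        p = 0.75
        sigma = np.sqrt(p * (1 - p) * 40000)
        assert abs(counts[1] - p * 40000) < 5 * sigma

    def test_distribution_reconstructs_exactly(self, rng):
        """The alias structure implies the normalized weights exactly."""
        for _ in range(50):
            K = int(rng.integers(2, 60))
            w = rng.random(K) * (rng.random(K) < 0.7)
            if w.sum() == 0:
                w[0] = 1.0
            at = AliasTable(w)
            implied = at.cut.copy()
            for i in range(K):
                if at.alias[i] != i:
                    implied[at.alias[i]] += 1.0 - at.cut[i]
            implied /= K
            assert np.abs(implied - at.probabilities).max() < 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            build_alias([0.0, 0.0])


@pytest.fixture(scope="module")
def gas_setup():
    table = synthetic_integrals(6, 11, scale=0.2)
    part = GASPartition([3, 3])
    sg = build_supergroup_table(
        part, band_constraints(part, [3, 3], 1, "local"), 6
    )
    tables = build_pchb_tables(table, sg, gas=True)
    ref = Determinant.from_orbitals([0, 1, 3], [0, 1, 3])
    return table, part, sg, tables, ref


class TestBuildTables:
    def test_fci_equals_gas_with_cas_constraints(self, rand6):
        part = GASPartition([6])
        sg = build_supergroup_table(part, LocalConstraints([0], [12]), 6)
        fci = build_pchb_tables(rand6, sg, gas=False)
        gas = build_pchb_tables(rand6, sg, gas=True)
        assert gas.n_sg == 1
        for pid in range(len(fci.alias[0])):
            a, b = fci.probabilities[0][pid], gas.probabilities[0][pid]
            if a is None:
                assert b is None
            else:
                assert np.array_equal(a, b)

    def test_forbidden_moves_have_zero_weight(self, gas_setup):
        integrals, part, sg, tables, ref = gas_setup
        allowed = set(sg.supergroups)
        so_space = tables._so_space
        for isg in range(tables.n_sg):
            x = sg.supergroups[isg]
            for pid in range(tables.pair_A.size):
                probs = tables.probabilities[isg][pid]
                if probs is None:
                    continue
                I, J = int(tables.pair_A[pid]), int(tables.pair_B[pid])
                for ab in np.nonzero(probs)[0]:
                    A = int(tables.pair_A[ab])
                    B = int(tables.pair_B[ab])
                    y = list(x)
                    y[so_space[I]] -= 1
                    y[so_space[J]] -= 1
                    y[so_space[A]] += 1
                    y[so_space[B]] += 1
                    assert tuple(y) in allowed

    def test_rows_normalize(self, gas_setup):
        _, _, _, tables, _ = gas_setup
        for isg in range(tables.n_sg):
            for probs in tables.probabilities[isg]:
                if probs is not None:
                    assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_memory_cap_refusal(self, rand6, cas6):
        part, sg = cas6
        with pytest.raises(MemoryError):
            build_pchb_tables(rand6, sg, memory_cap_bytes=10)


class TestSampling:
    def test_gas_children_always_allowed(self, gas_setup):
        integrals, part, sg, tables, ref = gas_setup
        rng = np.random.default_rng(3)
        dets = enumerate_determinants(part, sg, 0.0)
        parents = [dets[i] for i in rng.integers(len(dets), size=40)]
        for parent in parents:
            for _ in range(500):
                out = sample_event(parent, tables, rng)
                if isinstance(out, ExcitationEvent):
                    x = supergroup_of_determinant(out.child, part)
                    assert sg.contains(x)

    def test_event_for_event_identical_fci_and_cas_gas(self, rand6):
        part = GASPartition([6])
        sg = build_supergroup_table(part, LocalConstraints([0], [12]), 6)
        fci = build_pchb_tables(rand6, sg, gas=False)
        gas = build_pchb_tables(rand6, sg, gas=True)
        ref = Determinant.from_orbitals([0, 1, 2], [0, 1, 2])
        r1, r2 = np.random.default_rng(5), np.random.default_rng(5)
        for _ in range(2000):
            a, b = sample_event(ref, fci, r1), sample_event(ref, gas, r2)
            assert type(a) is type(b)
            if isinstance(a, ExcitationEvent):
                assert a == b

    def test_fully_occupied_system_always_rejects(self):
        table = synthetic_integrals(2, 1)
        part = GASPartition([2])
        sg = build_supergroup_table(part, LocalConstraints([0], [4]), 4)
        tables = build_pchb_tables(table, sg, gas=True)
        det = Determinant.from_orbitals([0, 1], [0, 1])
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert isinstance(sample_event(det, tables, rng), Rejection)

    def test_disconnected_singles_stay_in_space(self):
        table = synthetic_integrals(6, 2)
        part = GASPartition([3, 3])
        sg = build_supergroup_table(part, disconnected_constraints([3, 3]), 6)
        tables = build_pchb_tables(table, sg, gas=True)
        det = Determinant.from_orbitals([0, 1, 3], [0, 3, 4])  # x = [3, 3]
        mapping = part.orbital_to_space
        rng = np.random.default_rng(4)
        seen = 0
        for _ in range(2000):
            out = sample_single(det, tables, rng)
            if isinstance(out, ExcitationEvent):
                seen += 1
                assert mapping[out.I % 6] == mapping[out.A % 6]
        assert seen > 0

    def test_single_hole_distribution_normalizes(self, gas_setup):
        integrals, part, sg, tables, ref = gas_setup
        n = 6
        from stochgas.excitgen import _occupied_spin_orbitals

        isg = tables.supergroup_index0(ref)
        for I in _occupied_spin_orbitals(ref, n):
            mask = tables.single_hole_mask(isg, I)
            same = ref.alpha if I < n else ref.beta
            avail = mask & ~same
            count = avail.bit_count()
            if count:
                # uniform over available holes: probabilities sum to one
                assert count * (1.0 / count) == pytest.approx(1.0)


class TestPgen:
    def test_carried_pgen_matches_recomputation(self, gas_setup):
        integrals, part, sg, tables, ref = gas_setup
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 300:
            out = sample_event(ref, tables, rng)
            if isinstance(out, ExcitationEvent):
                assert pgen(ref, out, tables) == pytest.approx(
                    out.p_gen, rel=1e-12
                )
                checked += 1

    def test_total_probability_sums_to_one(self):
        """Children plus rejection channels exhaust the sample space."""
        table = synthetic_integrals(6, 13, scale=0.3)
        part = GASPartition([6])
        sg = build_supergroup_table(part, LocalConstraints([0], [12]), 4)
        tables = build_pchb_tables(table, sg, gas=True)
        det = Determinant.from_orbitals([0, 1], [0, 2])
        pmap = enumerate_pgen(det, tables)
        n = 6
        occ_bits = det.spin_orbitals(n)
        from stochgas.excitgen import _occupied_spin_orbitals

        occ = _occupied_spin_orbitals(det, n)
        ne = len(occ)
        npair = ne * (ne - 1) // 2
        isg = tables.supergroup_index0(det)
        reject = 0.0
        for a in range(ne):
            for b in range(a + 1, ne):
                pid = int(tables.pair_id[occ[a], occ[b]])
                probs = tables.probabilities[isg][pid]
                p_path = tables.p_double / npair
                if probs is None:
                    reject += p_path
                    continue
                for ab in range(probs.size):
                    if probs[ab] == 0.0:
                        continue
                    A = int(tables.pair_A[ab])
                    B = int(tables.pair_B[ab])
                    if (occ_bits >> A) & 1 or (occ_bits >> B) & 1:
                        reject += p_path * float(probs[ab])
        for I in occ:
            mask = tables.single_hole_mask(isg, I)
            same = det.alpha if I < n else det.beta
            if (mask & ~same).bit_count() == 0:
                reject += (1.0 - tables.p_double) / ne
        assert sum(pmap.values()) + reject == pytest.approx(1.0, abs=1e-12)

    def test_gas_forbidden_child_has_zero_pgen(self, gas_setup):
        integrals, part, sg, tables, ref = gas_setup
        # double transfer out of space 1 leaves the band: x=[6,0]
        child = Determinant.from_orbitals([0, 1, 2], [0, 1, 2])
        event = ExcitationEvent(
            "double", I=3, A=2, child=child, p_gen=0.0, J=6 + 3, B=6 + 2
        )
        assert pgen(ref, event, tables) == 0.0


class TestFrequencyCalibration:
    def test_chi2_on_gas_fixture(self, gas_setup):
        integrals, part, sg, tables, ref = gas_setup
        report = frequency_harness(
            ref, tables, 40000, np.random.default_rng(21)
        )
        assert report.n_forbidden == 0
        assert report.chi2 < report.threshold


class TestDiscarding:
    def test_cas_constraints_never_reject_for_gas_reasons(self, rand6, cas6):
        part, sg = cas6
        fci = build_pchb_tables(rand6, sg, gas=False)
        ref = Determinant.from_orbitals([0, 1, 2], [0, 1, 2])
        rng = np.random.default_rng(2)
        for _ in range(2000):
            out = discarding_generator(ref, fci, sg, rng)
            if isinstance(out, Rejection):
                assert out.reason != "gas_forbidden"

    def test_truncated_space_produces_rejections(self, gas_setup):
        integrals, part, sg, tables, ref = gas_setup
        fci = build_pchb_tables(integrals, None, gas=False)
        rng = np.random.default_rng(6)
        reasons = [
            out.reason
            for out in (
                discarding_generator(ref, fci, sg, rng) for _ in range(5000)
            )
            if isinstance(out, Rejection)
        ]
        assert "gas_forbidden" in reasons

    def test_accepted_doubles_match_gas_row_distribution(self, gas_setup):
        """Conditioned on a particle pair, the discarding generator's
        accepted-hole distribution equals the a-priori masked one."""
        integrals, part, sg, tables, ref = gas_setup
        fci = build_pchb_tables(integrals, None, gas=False)
        isg = tables.supergroup_index0(ref)
        for pid in range(tables.pair_A.size):
            p_gas = tables.probabilities[isg][pid]
            p_fci = fci.probabilities[0][pid]
            if p_gas is None or p_fci is None:
                continue
            mask = p_gas > 0
            renorm = p_fci * mask
            if renorm.sum() == 0:
                continue
            renorm = renorm / renorm.sum()
            assert np.allclose(renorm, p_gas, atol=1e-12)


class TestMemoryEstimate:
    def test_supergroup_scaling_is_linear(self):
        assert memory_estimate(30, 81) == 81 * memory_estimate(30, 1)

    def test_quartic_orbital_scaling(self):
        ratio = memory_estimate(32, 1) / memory_estimate(16, 1)
        assert 14 < ratio < 17

    def test_fragment_stack_triple_excitation_magnitude(self):
        est = memory_estimate(30, 2401)
        assert 34.81e9 / 2 < est < 34.81e9 * 2
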