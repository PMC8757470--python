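"""Calibration harness for the excitation generators.

Enumerates every child reachable from a parent determinant together with its
exact generation probability, samples the generator many times, and compares
observed frequencies against expectation with a chi-squared statistic
(rejections form one extra category).  A correctly implemented generator
passes at the 0.999 quantile; any GAS-forbidden child is reported separately
because for GAS-aware tables the correct count is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .excitgen import (
    ExcitationEvent,
    PchbTables,
    Rejection,
    _occupied_spin_orbitals,
    sample_event,
)
from .gas_constraints import supergroup_of_determinant
from .hamiltonian import Determinant


def enumerate_pgen(det: Determinant, tables: PchbTables) -> dict[Determinant, float]:
    """Exact generator distribution over children of ``det``.

    Returns child -> p_gen; the residual ``1 - sum`` is the total rejection
    probability (occupied holes, empty rows, hole-less singles).
    """
    n = tables.n_orb
    occ = _occupied_spin_orbitals(det, n)
    occ_bits = det.spin_orbitals(n)
    ne = len(occ)
    isg = tables.supergroup_index0(det)
    out: dict[Determinant, float] = {}
    npair = ne * (ne - 1) // 2
    for a in range(ne):
        for b in range(a + 1, ne):
            I, J = occ[a], occ[b]
            pid = int(tables.pair_id[I, J])
            probs = tables.probabilities[isg][pid]
            if probs is None:
                continue
            for ab in np.nonzero(probs)[0]:
                A = int(tables.pair_A[ab])
                B = int(tables.pair_B[ab])
                if (occ_bits >> A) & 1 or (occ_bits >> B) & 1:
                    continue
                child_bits = (
                    occ_bits ^ (1 << I) ^ (1 << J) | (1 << A) | (1 << B)
                )
                child = Determinant.from_spin_orbitals(child_bits, n)
                p = tables.p_double / npair * float(probs[ab])
                out[child] = out.get(child, 0.0) + p
    for I in occ:
        mask = tables.single_hole_mask(isg, I)
        same_spin_occ = det.alpha if I < n else det.beta
        avail = mask & ~same_spin_occ
        count = avail.bit_count()
        if count == 0:
            continue
        p = (1.0 - tables.p_double) / ne / count
        x = avail
        while x:
            low = x & -x
            a_spatial = low.bit_length() - 1
            x ^= low
            A = a_spatial if I < n else n + a_spatial
            child_bits = (occ_bits ^ (1 << I)) | (1 << A)
            child = Determinant.from_spin_orbitals(child_bits, n)
            out[child] = out.get(child, 0.0) + p
    return out


@dataclass
class HarnessReport:
    chi2: float
    dof: int
    threshold: float
    n_children: int
    n_forbidden: int
    rows: list = field(default_factory=list)


def frequency_harness(
    det: Determinant,
    tables: PchbTables,
    draws: int,
    rng: np.random.Generator,
    quantile: float = 0.999,
) -> HarnessReport:
    """Sample ``draws`` events and chi-square them against exact p_gen."""
    pgen_map = enumerate_pgen(det, tables)
    children = list(pgen_map.keys())
    index = {c: i for i, c in enumerate(children)}
    observed = np.zeros(len(children) + 1)  # last slot: rejections
    n_forbidden = 0
    for _ in range(draws):
        out = sample_event(det, tables, rng)
        if isinstance(out, Rejection):
            observed[-1] += 1
            continue
        i = index.get(out.child)
        if i is None:
            n_forbidden += 1
            continue
        observed[i] += 1
    p = np.array([pgen_map[c] for c in children])
    expected = np.concatenate((p, [max(1.0 - p.sum(), 0.0)])) * draws
    live = expected > 0
    chi2 = float(((observed[live] - expected[live]) ** 2 / expected[live]).sum())
    dof = int(live.sum()) - 1
    threshold = float(scipy.stats.chi2.ppf(quantile, dof))
    rows = [
        (c.alpha, c.beta, pgen_map[c], int(observed[i]), expected[i])
        for i, c in enumerate(children)
    ]
    if tables.gas:
        for c in children:
            x = supergroup_of_determinant(c, tables.partition)
            assert tables.sg_table.contains(x)
    return HarnessReport(chi2, dof, threshold, len(children), n_forbidden, rows)
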