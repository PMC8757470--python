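"""Synthetic fixture generation: FCIDUMPs, GAS specifications, manifest.

Everything is reproducible byte-for-byte from the seed.  The constraint
specifications cover the standard desk-scale test systems used throughout the
package: the worked three-space composition example, the four-space
cumulative system with no local equivalent, the five-fragment [5*(6,6)]
aromatic-stack bands, the [4*(3,3)] tetrahedral-cluster bands, and the large
RAS counting specification (32, 34, 93 orbitals; two holes / two electrons).
The manifest records closed-form oracle values where they exist.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import yaml

from .gas_constraints import (
    CumulativeConstraints,
    GASPartition,
    build_supergroup_table,
)
from .hamiltonian import hubbard_integrals, synthetic_integrals, write_fcidump


def _tight_binding_energy(L: int, n_elec: int, t: float) -> float:
    """U = 0 ground energy: doubly fill the lowest one-electron levels."""
    h = np.zeros((L, L))
    for i in range(L - 1):
        h[i, i + 1] = h[i + 1, i] = -t
    levels = np.sort(np.linalg.eigvalsh(h))
    energy, left = 0.0, n_elec
    for e in levels:
        take = min(2, left)
        energy += take * e
        left -= take
        if left == 0:
            break
    return float(energy)


def make_fixtures(outdir: Path, seed: int) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def emit(name: str, payload: dict) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
        files.append(name)

    # Random integral tables (n electrons = n orbitals, m_s = 0).
    for i, n in enumerate((4, 6, 8)):
        table = synthetic_integrals(n, seed + i, scale=0.2)
        table.n_elec, table.ms2 = n, 0
        name = f"rand_{n}o.fcidump"
        write_fcidump(table, outdir / name)
        files.append(name)

    # Hubbard chains at half filling.
    U, t = 4.0, 1.0
    for L in (2, 4, 6):
        table = hubbard_integrals(L, U, t)
        table.n_elec, table.ms2 = L, 0
        name = f"hubbard_L{L}.fcidump"
        write_fcidump(table, outdir / name)
        files.append(name)

    # Constraint specifications.
    emit("gas_three_space.yaml", {
        "version": 1,
        "gas": {
            "spaces": [2, 2, 2],
            "constraint_kind": "cumulative",
            "min": [0, 1, 3],
            "max": [2, 2, 3],
            "n_elec": 3,
        },
    })
    emit("gas_cumulative_only.yaml", {
        "version": 1,
        "gas": {
            "spaces": [2, 2, 2, 2],
            "constraint_kind": "cumulative",
            "min": [1, 4, 5, 8],
            "max": [3, 4, 7, 8],
            "n_elec": 8,
        },
    })
    for n_exc in (0, 1, 2, 3):
        emit(f"benzene_cum_nexc{n_exc}.yaml", {
            "version": 1,
            "gas": {
                "spaces": [6] * 5,
                "constraint_kind": "cumulative",
                "neutral": [6] * 5,
                "n_exc": n_exc,
            },
        })
    emit("benzene_local_nexc1.yaml", {
        "version": 1,
        "gas": {
            "spaces": [6] * 5,
            "constraint_kind": "local",
            "neutral": [6] * 5,
            "n_exc": 1,
        },
    })
    for n_exc in (1, 2):
        emit(f"n4_local_nexc{n_exc}.yaml", {
            "version": 1,
            "gas": {
                "spaces": [3] * 4,
                "constraint_kind": "local",
                "neutral": [3] * 4,
                "n_exc": n_exc,
            },
        })
    emit("ras_porphyrin_counting.yaml", {
        "version": 1,
        "gas": {
            "spaces": [32, 34, 93],
            "constraint_kind": "cumulative",
            "min": [62, 94, 96],
            "max": [64, 96, 96],
            "n_elec": 96,
        },
    })

    ras_table = build_supergroup_table(
        GASPartition([32, 34, 93]),
        CumulativeConstraints([62, 94, 96], [64, 96, 96]),
        96,
    )
    manifest = {
        "seed": seed,
        "files": files,
        "oracles": {
            "hubbard_L2_ground_energy": (U - math.sqrt(U * U + 16 * t * t)) / 2,
            "tight_binding_L4": _tight_binding_energy(4, 4, t),
            "tight_binding_L6": _tight_binding_energy(6, 6, t),
            "ras_porphyrin_supergroups": ras_table.n_sg,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    files.append("manifest.json")
    return manifest
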