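# stochgas

Stochastic solver for **generalized active space (GAS)** configuration
interaction, built around supergroup-indexed constraint algebra and a
GAS-aware precomputed heat-bath (PCHB) excitation generator for FCIQMC.

Multiconfigurational treatments of biomolecular cofactors — stacked
aromatics, heme-type metal centers, iron–sulfur cubanes — need active
spaces far beyond the complete-active-space (CAS) limit. The GAS ansatz
partitions the active orbitals into `k` subspaces and constrains the
electron count per subspace, either per space (*local*,
`n_i^min ≤ x_i ≤ n_i^max`) or on partial sums (*cumulative*). An ordered
electron distribution `x = (x_1, …, x_k)` over the subspaces is a
*composition*; the constraint-satisfying compositions are *supergroups*,
and every Slater determinant belongs to exactly one. Whether an excitation
leaves the allowed space depends only on the parent's supergroup, so
heat-bath hole-pair distributions `p(AB | IJ, i_sg) ∝ |H_IJ^AB(i_sg)|` can
be precomputed per supergroup with forbidden moves at exactly zero weight —
the walker dynamics then *never proposes* a forbidden determinant, at the
cost of `O(n^4 · n_sg)` table memory.

The package provides, at desk scale and fully testable against exact
diagonalization:

* constraint algebra: validation, local↔cumulative conversion with a
  constructive equivalence check, occupation-band constructors, exact
  composition indexing (binomial "jump" formula + binary search);
* exact big-integer Hilbert-space counts resolved by spin projection
  (per-supergroup generating-polynomial convolution) and van Vleck–Sherman
  CSF counts;
* FCIDUMP I/O, Slater–Condon matrix elements, GAS-masked Hamiltonians,
  synthetic integral generators (random tables, Hubbard chains), and a
  sparse exact-diagonalization oracle;
* FCI-PCHB and GAS-PCHB excitation generators with exact `p_gen`
  bookkeeping, an alias-method sampler, and a discarding baseline;
* FCIQMC walker dynamics: spawning/death/annihilation, population-control
  shift, initiator and adaptive-shift refinements, semistochastic core
  projection, projected energy with Flyvbjerg–Petersen blocking errors;
* exact and stochastically sampled 1-/2-RDMs, energy reconstruction,
  `⟨S²⟩`, and pseudonatural orbitals.

See `docs/methods.md` for the model, conventions, defaults and known
limitations.

## Worked example

Counting (exact integers, any size — `python examples/01_supergroups_and_counting.py`):

```
CAS(30, 30), m_s = 0:            2.41e+16 determinants
disconnected (n_exc = 0)        1 supergroups, 1.32e+14 determinants (0.6% of CAS)
local band, n_exc = 1          51 supergroups, 4.25e+15 determinants (17.7% of CAS)
cumulative band, n_exc = 1     81 supergroups, 5.22e+15 determinants (21.7% of CAS)
```

Five six-orbital fragments with six electrons each: disconnected spaces
admit a single electron distribution and shrink the space 200-fold; one
interspace excitation admits 51 (local) or 81 (cumulative) distributions
and keeps ~20% of the CAS determinants.

Stochastic dynamics against the exact answer
(`python examples/04_fciqmc_dynamics.py`, ~2 minutes):

```
exact ground energy:      -4.462097
projected energy:         -4.466345 +- 0.002324
stationary shift (mean):  -1.077212
exact correlation energy: -1.077947
deviation from exact:     -4.25 mHa (1.8 error bars)
walkers at the end:       20190 on 384 determinants
```

2·10^4 walkers propagate a random six-orbital problem; the projected energy
agrees with exact diagonalization within its blocking error bar, and the
stationary population-control shift reproduces the correlation energy — the
two independent FCIQMC energy estimators.

The other examples cover excitation-generator calibration (χ² of sampled
frequencies against exact generation probabilities, zero forbidden
proposals) and RDM properties (energy reconstruction, `⟨S²⟩`, block-diagonal
1-RDMs for disconnected spaces).

## Command line

A thin CLI wraps the library for shell use:

```sh
stochgas supergroups --spaces 6 --spaces 6 ... --neutral 6 ... --n-exc 1 --kind cumulative
stochgas count --config gas.yaml --ms 0
stochgas convert ...          # local <-> cumulative + equivalence flag
stochgas exact --fcidump x.fcidump ...
stochgas run --config run.yaml
stochgas excitgen-validate --fcidump x.fcidump ... --draws 100000
stochgas rdm-tools rdms.h5 --fcidump x.fcidump
stochgas make-fixtures --outdir fixtures/
```

Exit codes: 0 success, 1 runtime error, 2 configuration error. Runs write a
per-iteration TSV, a JSON summary and a provenance header (config hash,
seed, version).

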