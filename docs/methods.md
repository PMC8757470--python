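# Methods

`stochgas` implements a stochastic solver for generalized-active-space (GAS)
configuration-interaction problems: the constraint algebra that defines the
truncated determinant space, exact counting and small-scale enumeration of
that space, a GAS-aware precomputed heat-bath excitation generator, full
FCIQMC walker dynamics with the initiator, adaptive-shift and semistochastic
refinements, and reduced-density-matrix properties. Everything is sized for
desk-scale systems (up to roughly 16 spatial orbitals for dynamics), where
exact diagonalization is available as an internal oracle; the combinatorial
layer works at arbitrary size because it only counts.

## GAS constraint algebra

The active spatial orbitals are partitioned into `k` subspaces. A
*composition* is an ordered distribution `x = (x_1, …, x_k)` of the `N`
active electrons over the subspaces; the GAS constraints select a subset of
compositions, the *supergroups*. Local constraints bound each `x_i`
directly; cumulative constraints bound the partial sums `x_1 + … + x_i`.
Every determinant belongs to exactly one supergroup (count electrons per
space), and whether an excitation stays inside the GAS space depends only on
the supergroup of the parent and the spaces touched by the excitation —
never on the individual determinant. That observation is what makes
per-supergroup precomputation possible.

Supergroups are ordered lexicographically decreasing. The index of a
composition in the full decreasing-lex list of all `C(N+k−1, k−1)`
compositions is computed by "jumping over" the blocks of compositions with a
larger leading entry at each position — a sum of binomial-table lookups.
Supergroup lookup is then one composition-index evaluation plus a binary
search over the stored (strictly increasing) composition indices of the
allowed set. The allowed set itself is enumerated once at setup by filtering
all capacity-feasible compositions; this step does not need to be fast, only
correct.

Local and cumulative constraints are not equally expressive. Conversion uses
`n_min[i] = cum_min[i] − cum_max[i−1]`, `n_max[i] = cum_max[i] − cum_min[i−1]`
(and running sums in the other direction), and *equivalence is decided
constructively* by building both supergroup tables and comparing the sets —
the algebraic conditions under which the conversion is faithful are
existential and awkward to verify directly, while the constructive check is
cheap at any realistic `k`.

Occupation *bands* generate the constraints used throughout the test
systems: given a neutral occupation per space and an interspace excitation
level `n_exc`, the local band allows each space to deviate from neutrality
by at most `n_exc` electrons, and the cumulative band keeps each partial sum
within `n_exc` of the neutral partial sum, with the last partial sum pinned
to `N`. Both clip to spin-orbital capacity, which the usual presentations
leave implicit. The two band families differ in which multi-fragment
rearrangements they admit (the cumulative band allows, e.g., a
next-nearest-fragment double transfer that the local band forbids, and vice
versa); for five spaces of six orbitals at `n_exc = 1` they yield 51 and 81
supergroups respectively, and they coincide at `n_exc = 0` (disconnected
spaces, a single supergroup). Counts are exact arbitrary-precision integers
throughout — conceptual spaces beyond 10^16 determinants are counted, never
materialized.

## Hilbert-space counting

The number of determinants at fixed spin projection in one supergroup is
obtained by convolving per-space generating polynomials: a space of `n_i`
orbitals holding `x_i` electrons contributes `Σ_a C(n_i,a) C(n_i,x_i−a) z^a`
over its alpha count `a`, and the coefficient of `z^{n_α}` in the product
over spaces is the count. Summing over supergroups gives the GAS total; a
single unconstrained space reduces to `C(n, n_α)·C(n, n_β)`. Spin-adapted
function counts use the van Vleck–Sherman branching number
`C(n, n/2−s) − C(n, n/2−s−1)`, validated against explicit enumeration of
branching paths. Enumeration of the determinant basis (for the
exact-diagonalization oracle) is refused above a configurable cap, 10^6 by
default.

## Hamiltonian layer

Integrals live in chemists' notation `(ij|kl)` with 8-fold permutational
symmetry, matching FCIDUMP; point-group labels are read but not exploited
(C1 throughout — symmetry is orthogonal to the algorithms implemented
here). Spin orbitals are ordered alpha block then beta block, and all
fermionic phases are parities of occupied spin orbitals crossed by the
operator string in that fixed order. The Slater–Condon rules are pinned, in
the test suite, against a brute-force second-quantized oracle that applies
the Hamiltonian term by term; a vectorized batch evaluation of the same
rules (used by the walker dynamics) is pinned against the scalar rules.

Masked (GAS) Hamiltonian elements vanish whenever the target determinant's
supergroup is not allowed; restricted to the GAS-allowed basis the masked
and unmasked operators coincide, which the suite verifies by diagonalizing
both routes. Exact diagonalization assembles the sparse Hamiltonian by
excitation enumeration from each basis determinant and uses a dense solver
below dimension 300, a Lanczos solver above it.

Two synthetic generators define the study conditions. `synthetic_integrals`
draws a symmetry-complete random table whose one-electron diagonal is
dominant and ascending (spacing 0.8, off-diagonal scale 0.1–0.3), giving a
well-separated closed-shell reference — a caricature of a post-Hartree–Fock
active space. `hubbard_integrals` builds nearest-neighbor chains/rings with
on-site repulsion, contributing closed-form oracles (the two-site ground
state, the U = 0 tight-binding limit) and genuinely antiferromagnetic spin
physics for the RDM/spin tests. Neither has realistic long-range Coulomb
decay or point-group structure, so passing tests demonstrate correctness of
the algorithms, not chemical accuracy on real molecules.

## Excitation generation

Double excitations: the magnitude of a double-excitation element depends
only on the four orbitals involved, so hole-pair distributions
`p(AB|IJ) ∝ |H_IJ^AB|` are precomputed per ordered spin-orbital pair and
sampled in O(1) with Walker's alias method (the test suite reconstructs the
implied distribution from the alias structure and requires exact agreement
with the normalized weights). Under GAS, one distribution set is stored per
supergroup with forbidden moves at exactly zero weight, so forbidden
determinants are *never proposed*; the FCI generator is the single-
supergroup special case of the same code path. Particle pairs are chosen
uniformly among occupied pairs; a drawn hole pair that is already occupied
is a rejection (a normal outcome with accounted probability mass).

Single excitations cannot be usefully precomputed (their elements depend on
the full occupation), so the particle is uniform over occupied spin
orbitals and the hole uniform over the spin-compatible unoccupied orbitals
whose space move keeps the composition allowed — a bitmask per (supergroup,
source space). Every event carries its exact generation probability, and an
exhaustive enumeration check verifies that child probabilities plus
rejection mass sum to one.

The probability of attempting a double rather than a single excitation is a
configuration scalar, default 0.8. Tables are indexed over spin-orbital
pairs for clarity; the ~4× cheaper spatial indexing used by production codes
is only reflected in the memory model (`memory_estimate`, entry width 4
bytes), which also drives the build-time refusal cap.

The *discarding* baseline proposes from the unconstrained FCI distribution
and rejects forbidden children after the fact. Conditioned on a particle
pair, its accepted-hole distribution equals the a-priori masked one (an
exact statement, tested analytically); across pairs the two generators
differ by per-row normalizations, and the discarding generator wastes the
forbidden probability mass, which is why the a-priori generator is
preferred.

## Walker dynamics

Signed integer walkers sample `c ← c − Δτ (H − E_ref − S) c` with
`E_ref` the diagonal element of the initial reference — the convention
under which the population-control shift `S` equals the correlation energy
at stationarity. Per iteration each walker makes one excitation attempt;
spawns are accepted with probability `Δτ |K_ij| / p_gen` (values above one
spawn multiple children), the diagonal death/cloning probability is
`Δτ (K_jj − S)`, and opposite-sign arrivals annihilate by signed summation.
Fractional magnitudes are rounded stochastically (unbiased). The
implementation batches all attempts of an iteration into array operations,
grouping alias draws by (supergroup, particle pair); Python-level work
scales with the number of occupied determinants, not the walker count.

Population control holds `N_w = Σ|c_i|` near the target with the damped
update `S ← S − ζ/(AΔτ)·[ln(N(τ)/N(τ−AΔτ)) + r·ln(N(τ)/N_target)]`,
`ζ = 0.05`, `A = 5`, `r = 0.1` by default. The `r` term is a deliberate
extension of the classic integral-only update: the integrator telescopes to
`S(t) = S(0) − ζ/(AΔτ)·ln(N(t)/N(0))`, which pins the stationary population
at `N(0)·exp((S(0)−E_corr)·AΔτ/ζ)` — a silent drift (or collapse) whenever
the initial shift is far from the correlation energy. The weak proportional
term moves that fixed point to the target population without affecting the
stationary shift value; `r = 0` recovers the textbook update.

The time step may be given explicitly (all shipped tests do) or frozen from
a warm-up scan as `0.9 / max(|K_ij|/p_gen)` over sampled reference
excitations — a conservative choice that keeps single-spawn probabilities
below one.

Projected energy: `E = E_ref + Σ_t num_t / Σ_t den_t` with
`num_t = Σ_{j≠0} H_0j c_j(t)` and `den_t = c_0(t)` recorded separately every
iteration. Error bars come from Flyvbjerg–Petersen blocking of the
per-iteration ratio series: successive pair averaging, with the plateau
taken at the first level whose increase falls within the error-of-the-error;
if no plateau is found the maximum of the curve is reported and flagged —
treat such bars as lower bounds. Reference switching (another determinant
exceeding 1.5× the reference population for 100 consecutive iterations)
restarts the accumulation; the thresholds are package choices.

Refinements:

* **Initiator.** Spawns from parents below `n_add` (default 3) onto empty
  determinants are vetoed; the veto is applied against the pre-merge
  occupancy, so coincident spawns within one iteration do not unlock each
  other.
* **Adaptive shift.** Non-initiators receive a local shift
  `S_i = Δ + f_i (S − Δ)`, where `f_i` is the running ratio of
  initiator-surviving spawn weight to total spawn weight from `D_i`, with
  first-order-perturbation weights `|H_ji| / (H_jj − E)` (denominator
  floored at 0.01; `E` is the instantaneous projected energy). The ratio
  uses exponential forgetting with a configurable half-life (default 500
  iterations) because an exact windowing is not prescribed by the method.
  The offset can be given absolutely or as a fraction of the instantaneous
  shift (`Δ = frac·S`), which expresses the two limiting cases exactly:
  `frac = 1` reproduces conventional initiator dynamics trajectory for
  trajectory, `frac = 0` applies the full correction. Initiators die under
  the global shift, non-initiators under their local shift — one of two
  readings of the prescription; the alternative (local shifts for everyone)
  differs only for initiators, which dominate the signal, so the chosen
  reading is the conservative one.
* **Semistochastic core.** The most-populated determinants (ties broken by
  determinant hash) are frozen as a core space once, the dense core
  Hamiltonian is built, and core amplitudes are propagated exactly (as
  reals) by `1 − Δτ(H^core − E_ref − S)`; core→core stochastic spawns are
  discarded to avoid double counting, core↔outside traffic stays
  stochastic, and core death is contained in the exact update. With the
  core equal to the whole basis the dynamics degenerates to deterministic
  power iteration and reproduces exact diagonalization.

Known limitation: at moderate walker counts the projected-energy estimator
retains a small positive population-control bias (of order a few mHa at
2·10^4 walkers on the shipped six-orbital fixtures, shrinking with `1/N_w`),
and blocking bars without a detected plateau underestimate the error. The
acceptance-scale checks therefore run at 10^5 walkers.

## Reduced density matrices

Spin-orbital convention: `γ_PQ = ⟨a†_P a_Q⟩`,
`Γ_PQRS = ⟨a†_P a†_Q a_S a_R⟩`; the energy functional is
`E = E_core + Σ h γ + ½ Σ (PR|QS) Γ`. Exact RDMs contract an
eigenvector over the enumerated basis through a shared pair-expansion
routine; the spin expectation uses
`⟨S²⟩ = m_s(m_s+1) + N_β − Σ_pq Γ[pβ, qα, qβ, pα]`, validated against a
brute-force `S²` operator matrix (the working equation is the textbook
contraction; no external reference for it is bundled). Pseudonatural
orbitals diagonalize the per-space blocks of the spin-summed 1-RDM; for
disconnected spaces the interspace blocks vanish identically and
pseudonatural equals natural.

Stochastic RDMs accumulate diagonal contributions `c_i²` from populations
and off-diagonal contributions from accepted spawn events with weight
`sign(c_i)·c_j·n_spawn/(Δτ|K_ij|)` — the inverse of the expected acceptance
count, so weights sum to `c_i c_j` per iteration in expectation. The same
walkers serve bra and ket (no replica), which biases the diagonal upward by
the population variance (bounded against oracle RDMs in the tests; a few
percent at 2·10^4 walkers); the trace is renormalized to `N` exactly at
output. Hole pairs whose Hamiltonian coupling vanishes identically (pure
spin-flip blocks) are never proposed by the heat-bath generator and hence
never sampled: the energy functional touches only sampled blocks, but spin
expectations should be evaluated from exact RDMs. GAS-forbidden index
blocks are identically zero because forbidden determinants are never
occupied. Replica sampling is a noted extension, not implemented.

## Numerical choices and degenerate inputs

* Binomials come from exact integer `math.comb`; no floats enter any count.
* Empty supergroup tables, infeasible spin sectors, all-zero alias weights,
  GAS-forbidden references/cores, zero-denominator energy windows and
  blocking series shorter than 64 samples are all hard errors; infeasible
  `(n, N, m_s)` sectors count zero rather than raising.
* Constraint validation returns diagnostics instead of raising, so the CLI
  can report every violation at exit code 2.
* A fully occupied system rejects every excitation attempt; zero-weight
  rows reject with their probability mass accounted, preserving
  unbiasedness.

## Scope

Orbital optimization (any SCF loop), spin-adapted (GUGA) propagation,
point-group symmetry, distributed-memory parallelism and walker counts
beyond ~10^6 are out of scope. Cluster-scale applications (multi-fragment
stacks at full size, metal-cluster spin ladders, large RAS spaces) appear
only through their counting problems, which the combinatorial layer handles
exactly; their dynamics are represented by the desk-scale property suites.
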