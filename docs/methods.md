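# Methods

This note records the models, algorithms and numerical choices behind
`spindmrg`, in enough detail to judge what its tests do and do not
demonstrate.

## Hamiltonians and conventions

The solver treats active-space Hamiltonians with one- and two-electron
integrals in chemists' notation and the full 8-fold permutational
symmetry, read and written in the Molpro-style FCIDUMP dialect
(namelist header with NORB/NELEC/MS2; point-group labels are parsed
and ignored — the symmetry handling here is particle number and spin
only). Indices are 0-based internally and 1-based only at the file
boundary. A file whose duplicated entries disagree by more than
1e-10 Hartree is rejected as corrupt; the model generators produce
*exactly* symmetric integrals (pairwise averaging over the three
commuting orbit generators, which is exact in floating point, unlike a
single 8-term average).

Fermions are mapped to the orbital chain by a Jordan–Wigner
transformation over the mode order (orb 0 ↑, orb 0 ↓, orb 1 ↑, …).
Both the MPO builder and the full-CI oracle derive their signs from
this one convention, and a test asserts elementwise equality of the
two Hamiltonian matrices on 3-orbital systems — the sign-convention
lock that makes all later energy comparisons meaningful.

## Model generators (the study conditions)

* `hubbard_chain(n, t, u)` — open-boundary Hubbard chain, half filled
  by default. Used wherever a sparse Hamiltonian with known physics is
  wanted; the dimer's singlet energy (U − √(U²+16t²))/2 is the
  closed-form anchor.
* `random_cas(n_orb, n_elec, seed, scale)` — seeded Gaussian integrals
  projected onto the symmetric subspace; a stand-in for strongly
  correlated CAS Hamiltonians whose integral files are not available.
  Intended at ≤ 8 orbitals.
* `near_degenerate_spin_chain(5, t=0.25, u=10, delta_t=0.15)` — a
  weakly dimerized odd-site chain deep in the local-moment regime.
  The superexchange scale 4t²/U = 25 mHartree puts the lowest doublet
  and quartet ~32 mHartree apart: a desk-scale emulation of
  near-degenerate metal-centre spin states, suitable for exercising
  the spin-gap extrapolation pipeline. What it does *not* emulate:
  realistic integral distributions, orbital-energy spreads, or the
  size of real transition-metal active spaces — conclusions about
  those do not follow from these fixtures.

## Engine

Block-sparse tensors carry additive (N, 2Sz) sector labels per axis
with a per-block conservation law; a tensor-level charge supports
operators that change Sz (ladder operators). Contractions run
blockwise through BLAS; every dense multiply adds 2mnk to an integer
operation ledger (factorizations count zero by convention — retained
state counts are reported instead, keeping the ledger exact and
platform-independent). Truncations globally sort squared singular
values across sectors; ties break toward the smaller sector label so
runs are bit-reproducible.

The MPO is built symbolically: H is expanded into Jordan–Wigner
operator strings, and at every bond the crossing terms' coefficient
matrix C[prefix, suffix] (block-diagonal in the prefix charge) is
factorized by an exact-rank SVD; site tensors are recovered by a
least-squares change of basis whose residual is asserted at 1e-8.
This reproduces the complementary-operator O(N²) operator-bond
dimension automatically (bond dimension 6 for a Hubbard chain, ~10²
for dense 6–8 orbital interactions) without hand-coding the
finite-state machine.

Sweeps are two-site with density-matrix-exact truncation; two-site
updates are what lets a run discover symmetry sectors from small
starts, and what makes the discarded weights it reports meaningful.
Davidson uses a 20-vector subspace with 2-vector restarts, the exact
diagonal of the effective Hamiltonian as preconditioner (with a
raw-residual fallback when preconditioning collapses onto the Ritz
vector, as happens for exactly diagonal operators), and a per-stage
residual tolerance. An optional noise term (default 0) expands the
two-site tensor along H·ψ before truncation to escape poor local
optima at very small caps. The initial state is a seeded random MPS in
the target sector; any MPS (e.g. a determinant from
`product_state_mps`) can be passed as `initial` instead.

The **sweep energy** is recorded as the *lowest* Davidson eigenvalue
encountered during the sweep. Every such eigenvalue is the Rayleigh
quotient of a normalized global state, hence a true variational upper
bound; taking the minimum makes the record independent of sweep
direction (the final-bond eigenvalue alternates between the chain's
ends at truncated D). Between-sweep convergence (|ΔE| below the
schedule's `energy_tol`; 1e-5 Hartree is the production-scale
convention, tests use 1e-11) is checked on this record. With a fixed
cap the record is non-increasing to ~1e-14 at the fixed point; during
a cap *increase* it may transiently rise, because the pre-truncation
minimum of the small-cap sweep need not be representable after
truncation.

## Spin adaptation

The SU(2) mode targets total spin S exactly, by singlet embedding: an
inert spectator site carrying a single spin-S multiplet is appended to
the chain, and the solver optimizes the *total singlet* of physical
chain plus spectator. Coupling to the spin-S spectator forces the
physical state to total spin exactly S and leaves the energy
untouched. Three mechanisms keep everything exact:

1. **Ladder environments.** The matrix elements of left-part and
   right-part S⁻ in the current bond bases are carried along the sweep
   by transfer recursion, giving an exact total-S² operator on every
   two-site space — *provided* each bond basis is closed under the
   ladder action (complete multiplets).
2. **Löwdin projection in Davidson.** Each Davidson vector is
   projected onto the total-singlet eigenspace by a product over the
   other total-spin values present (extra factors for absent spins are
   harmless: they act as the identity on the singlet component).
3. **Multiplet-complete truncation.** For a global singlet the reduced
   density matrix of either side of any bond commutes with that side's
   spin operators. Highest-weight eigenvectors are extracted per
   sector as the kernel of the part-raising operator, partners are
   generated by exact lowering, and truncation keeps whole multiplets
   ranked by density-matrix weight (discarded weight counts each
   multiplet with its 2S+1 members). The recorded bond spectra give
   D as a multiplet count and D_U(1) = Σ multiplicity·(2S+1).

The initial state is the exact singlet embedding of the high-spin
reference determinant (all unpaired spins up), whose projection
partners are generated by exact total-S⁻ application; a two-way
canonicalization pass trims the bond bases to the singlet's Schmidt
support, which is multiplet-complete — a one-way pass would keep
spectator directions with no support on the other side of the bond and
silently break ladder closure (a failure mode caught by the su(2)
commutator test). The alternative design — reduced Wigner–Eckart
tensors with 6j/9j recoupling — would be the right choice for
performance at scale; at this package's correctness scale the embedded
formulation needs no recoupling coefficients at all and is verified
against the spin-resolved oracle for 2S ∈ {0, 1, 2, 3}.

## Cost benchmarking

The production-benchmark claim "the dominant cost grows as D³ once the
performance plateau is reached" is, in operation counts, a statement
about the effective-Hamiltonian application with every symmetry sector
populated. Three desk-scale artifacts hide it if measured naively:
converged small-molecule states exhaust their Schmidt rank (cost
flattens); global-sort truncation concentrates weight in few sectors
(growth spreads to new rank-1 sectors instead of deepening existing
ones); and on a short chain most bonds sit at their structural fusion
caps 4^k. The bundled benchmark therefore measures fixed-Davidson-
effort sweeps on *sector-saturated* random states (every reachable
sector filled in proportion to its full fusion rank, min(D, full rank)
states per bond) on a 16-site chain, tallying only bulk bonds whose
neighbours stay below their structural caps across the scan. Per-step
decomposition confirms the L·ψ and ψ·R contractions are cubic (slope
3.0–3.1 at a single bond pair); the sweep-level exponent over
D ∈ {128…384} is 2.78, the deficit coming from the sub-leading
O(w²D²) MPO-tensor contractions of the two-site algorithm. An exact
c·D³ count model fits to 3.0 to machine precision.

## Analysis

Extrapolation fits are unweighted least squares of E against 1/D
(second order by default), with D the SU(2) multiplet count in
spin-adapted runs and D_U(1) — labelled as such — otherwise; the two
conventions are never mixed in one fit. The fitted intercept must not
sit above the best computed energy beyond a slack of
max(1e-9, 10·rms residual); a series violating that is rejected rather
than silently extrapolated, since the model assumes a variational,
monotone sequence. Spin gaps are 1000·(a0_b − a0_a) mHartree. Scaling
fits are first-order in log–log with an explicit user-chosen window:
the low-D filling regime and the saturated regime have different
slopes, and choosing the split point is a judgement call the code does
not automate. Fit residuals are always reported.

## Problem sizes

Tests and the acceptance script run full-bond-dimension (exact) DMRG
on chains of 2–6 sites and random tables of 3–6 orbitals (both
symmetry modes, against full CI at ≤ 1e-8 Hartree), truncation scans
on 6–8 site chains, and the cost benchmark on a 16-site chain at
D ≤ 384. These sizes keep the whole suite in minutes on one CPU while
covering every code path; the random-table grid uses five seeds at 3–4
orbitals and three at 5–6. The 1/D-extrapolation demonstration uses
the 8-site chain because 6-orbital fixtures reach machine-precision
convergence within a handful of multiplets, leaving no truncated tail
to extrapolate.

## Known limitations

* Two-site updates carry an O(w²D²) term that dominates at small D;
  production-style one-site + perturbation updates are out of scope.
* No orbital reordering or point-group symmetry; orbital order is
  taken from the input as-is.
* The oracle is capped at 1e5 determinants; beyond ~8 orbitals there
  is no independent energy check.
* Excited states (beyond targeting different spin sectors), state
  averaging, and dynamical-correlation post-processing are not
  implemented.
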