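# Methods

## Model

`tetrafold` predicts coarse-grained backbone conformations of short protein
binding-site fragments by exact or variational minimization of a diagonal
spin Hamiltonian.

**Geometry.** An L-residue peptide is a walk on the diamond (tetrahedral)
lattice. Step k picks one of four directions `a_d ∈ {(1,1,1), (1,-1,-1),
(-1,1,-1), (-1,-1,1)}/√3` and advances `p_{k+1} = p_k + (-1)^k a_d`. The
alternating sign is what makes this the diamond lattice: bonds have unit
length, distinct consecutive directions meet at arccos(-1/3) ≈ 109.47°
(the tetrahedral Cα virtual-bond angle), and repeating a direction is the
backtracking move `p_{k+2} = p_k`. Positions are stored as integer triples
(multiples of 1/√3), so self-avoidance and contact detection are exact
integer arithmetic, never tolerance comparisons. Side chains are not
modeled; one bead per residue.

**Encoding.** Each of the L-1 turns is stored densely in two qubits,
`d = d0 + 2·d1` with d0 on the lower-indexed qubit. Single-qubit projectors
are `P¹ = (I+Z)/2`, `P⁰ = (I-Z)/2` — i.e. the logical bit 1 corresponds to
the Z = +1 eigenstate. Because hardware conventions put |0⟩ at Z = +1, the
measured bit m maps to the logical bit 1-m; that flip lives in exactly one
place (`structure.DecodeConvention`) and every other component works with
whichever representation is natural to it. The two-qubit indicator
`Π_t^(d)` is the product of the two projectors and satisfies
`Σ_d Π_t^(d) = I` and `Π^(d)Π^(e) = δ_de Π^(d)` as exact operator
identities. Optionally turns 0 and 1 are pinned to directions 0 and 1,
quotienting the 12 proper lattice rotations; this is the default in the
solver pipeline (the rotation group acts simply transitively on ordered
distinct direction pairs, so no conformation class is lost) and off in the
algebra layer. A four-qubit one-hot encoding of the same choice exists in
the literature; this package implements the dense two-qubit form throughout.

**Energy terms.** The total operator is
`H = λ_c·H_chirality + λ_g·H_geometric + λ_d·H_steric + λ_i·H_interaction`,
assembled purely from indicator products, so it is Z-only (diagonal) and
basis-state evaluation is classical and exact.

* `H_geometric`: a one-hot penalty `μ_oh Σ_t (I - Σ_d Π_t^(d))²` plus an
  angle penalty `μ_ang` on adjacent-turn pairs outside the allowed set A.
  Under the dense encoding the one-hot term cancels exactly; it is still
  constructed and simplified to the zero operator rather than skipped, as a
  standing check on the algebra. A is all 12 ordered distinct pairs — every
  distinct pair realizes the 109.47° angle — so the angle term shares
  support with the backtrack term (their coefficients add).
* `H_chirality`: `κ_bt` per adjacent equal pair (immediate reversal) and
  `κ_χ` per forbidden handedness triple. For three consecutive turns
  (d,e,f), all distinct, the handedness is the sign of
  `(-1)^t · det[a_d, a_e, a_f]` with t the middle turn index (bond vectors
  alternate sign with parity, hence the factor); negative-handedness
  triples are penalized. This uniform local chirality bias is an explicit
  modeling choice: exactly half (12/24) of the distinct triples are
  forbidden, and swapping two directions (a mirror operation) always flips
  the status.
* `H_steric`: `η Σ_{t<u} C(u-t, t mod 2, d, e) Π_t^(d) Π_u^(e)` within a
  window `w_steric = 4`. The collision mask C is defined by exact
  marginalization: for turn separation 1 it is the backtrack indicator
  δ_de; for larger separations it is the fraction of backtrack-free
  assignments of the intermediate turns whose sub-path revisits a lattice
  site. All values are brute-force enumerated and cached per
  (separation, parity, d, e).
* `H_interaction`: `Σ_{t<u} J[s_t][s_{u+1}] · M(u-t, t mod 2, d, e)
  Π_t^(d) Π_u^(e)` within `w_contact = 7`. M is the fraction of
  backtrack-free, self-avoiding completions that place residues t and u+1
  at unit lattice distance; it vanishes for even residue separations and
  separations below 5 (diamond sublattice parity — the enumeration
  reproduces this, it is not special-cased). J is the Miyazawa–Jernigan
  20×20 statistical contact-energy table (1996 revision, RT units),
  embedded as packaged text; any whitespace-delimited 20×20 table with a
  one-letter header can be substituted.

Energies are dimensionless model energies throughout.

**Known approximation.** A pairwise mask over turn pairs cannot encode exact
self-avoidance or exact contacts: C and M are *propensities* marginalized
over intermediate turns, so two conformations sharing end-turn assignments
receive identical steric/contact scores regardless of what the intermediate
turns actually do. Concretely, at L = 6 the minimum interaction energy of
contact-forming and contact-free conformations coincides (the means differ
in the right direction). Exact accounting is restored at decode time:
`exact_conformation_energy` scores a decoded walk by its true lattice
contacts (+∞ if self-intersecting) and is available for re-ranking sampled
bitstrings (`select_structure(mode="rerank")`).

## Ground-state search

Three backends share one result contract (best bitstring, energy, trace,
histogram, seed):

* **Exhaustive** — materializes the full diagonal (guard: 24 qubits) and
  scans it; ties break toward the lexicographically smallest measured
  bitstring. This is the oracle the other backends are tested against.
* **Simulated annealing** — Metropolis walk over free-turn assignments
  (single-turn resampling moves, so every state is a well-formed encoding)
  with geometric cooling `T_k = T0·α^k`; defaults T0 = 20 (the penalty
  scale), α = 0.9995, 20 000 steps. Seeded-deterministic; at L ≤ 5 it
  reaches the exhaustive minimum in ≥ 9/10 seeds (calibration property).
* **Two-stage VQE** — a numpy statevector simulation of a layered
  hardware-efficient ansatz: a rotation layer, then `reps` repetitions of
  (CX chain, rotation layer). Defaults: Ry-only rotations (real amplitudes
  suffice for a diagonal Hamiltonian), linear entanglement, reps = 3, so
  the parameter count is `n_qubits·(reps+1)`; an Ry+Rz variant and circular
  entanglement are available. Stage 1 minimizes the expectation with
  COBYLA (derivative-free; default 200 iterations, 2000 shots per
  estimate, or the analytic expectation with `shots_opt = 0`); stage 2
  freezes the optimal parameters and samples 20 000 measurement shots from
  |ψ|², from which the structural bitstring is selected (most-frequent by
  default, with energy then lexicographic tie-breaks). The statevector
  guard is 20 qubits; larger problems go to annealing or the window
  assembler.

One master seed fans out to parameter initialization, shot sampling, and
annealing through fixed sub-seed offsets, making every backend bit-
reproducible for a given (config, seed).

## Decoding and structure output

The selected bitstring is flipped to logical bits, fixed turns are
re-inserted, and each 2-bit group becomes a direction. Coordinates are the
lattice walk scaled by 3.8 Å per bond (the standard Cα–Cα virtual bond
length; configurable). Self-intersecting decodes are flagged, never
discarded silently. Output is a Cα-only PDB trace (chain A, one ATOM record
per residue) written and read through biotite; full-atom completion,
protonation, and charges are downstream concerns. RMSD between traces uses
a Kabsch superposition with the SVD determinant sign rule, so reflections
are excluded and mirror images of chiral chains score strictly positive.

## Sliding-window assembly

Sequences beyond direct solver capacity are processed in overlapping
windows (default 7 residues, stride 1 — every interior bond is then seen by
up to 6 windows). Each window runs the direct pipeline independently
(default: annealing; VQE uses 30 iterations per window) under sub-seed
`master + offset`. Each window's predicted unit bond vectors live in an
arbitrary global orientation, so windows are merged in offset order and
each one is first rigidly rotated (vector Kabsch, no translation) onto the
current consensus over its already-covered bonds; merging is therefore
invariant to the order predictions are supplied in. Per bond, contributors
are combined by weighted average (triangular weights peaking at the window
center by default, since central bonds see the most sequence context;
uniform available) and renormalized; an exactly cancelling average is a
reported error, not a silent NaN. The weighted mean squared angular
deviation per bond is returned as a variance map — low variance flags bonds
on which repeated overlapping predictions agree. Integrating the merged
unit vectors (× 3.8 Å) yields the full backbone; merged directions are
generally off-lattice by construction. With a single window the procedure
degenerates to the direct pipeline exactly.

## Evaluation utilities

Docking pose tables (columns run, rank, affinity, rmsd_lb, rmsd_ub) are
parsed with validation (lower bound ≤ upper bound per row, reported with
line numbers) and aggregated into mean affinity / mean RMSD lower bound /
mean RMSD upper bound over all records — e.g. 20 runs × 9 poses = 180
records — with a completeness flag rather than imputation. A seeded fixture
generator produces plausible synthetic tables (affinity ∈ [-10, 0]
kcal/mol, 0 ≤ lb ≤ ub ≤ 15 Å) so the aggregation math is testable without
any docking binary. `compare_structures` reports Kabsch RMSD plus a
per-residue deviation profile for equal-length Cα traces.

## Problem sizes and numerical choices

* Direct builds are guarded at 13 residues (24 qubits); statevector
  simulation at 20 qubits; dense diagonals at 24 qubits; full conformation
  enumeration at 13 residues. Test and acceptance runs use fragments of
  4–7 residues for exhaustive cross-checks and the 42-residue amyloid-β
  chain for window assembly, sizes at which every oracle comparison is
  exact.
* Operator canonicalization drops coefficients below 1e-12 so exact
  rational cancellations (the one-hot penalty) collapse to the true zero
  operator.
* Default weights: λ = 1 for all four groups, μ_oh = 50, μ_ang = 20,
  κ_bt = 20, κ_χ = 10, η = 20. The binding constraint is that penalties
  dominate the largest attainable contact reward (max |J| = 7.37); the
  builder warns if a weight configuration breaks this, and the dominance is
  verified exhaustively in the tests. A consequence of the defaults: for
  L ≤ 5 no contact is geometrically possible (contacts need odd residue
  separation ≥ 5), so the valid-conformation ground-state energy floor is
  exactly 0 there.
* Masks are pure functions of (separation, parity, d, e) with an
  lru-cache; windows w_steric = 4, w_contact = 7.
* Annealing energy evaluation uses a precomputed dense diagonal lookup up
  to 20 qubits, term-wise evaluation beyond.

## What the synthetic inputs do and do not show

Test sequences are real binding-site fragments (antibody loop YAGYS, GluK2
GAVEDGATMTFF, BACE1 KSIVDSG, amyloid-β 1-42) but the model they exercise is
a coarse single-bead lattice: passing tests demonstrate that the encoding,
algebra, solvers, decoding, and assembly are internally exact and mutually
consistent, not that predicted conformations match experimental structures.
The docking fixtures are synthetic tables with plausible ranges; they
validate parsing and aggregation arithmetic, not docking physics.

## Limitations

* Pairwise masks approximate many-body self-avoidance (see above); exact
  screening happens only at decode/re-rank time.
* The chirality criterion is a uniform local handedness bias, not a
  residue-specific stereochemistry model.
* No hardware execution, transpilation, noise model, or error mitigation;
  the VQE backend is an ideal statevector simulation.
* Window merging assumes neighboring windows agree up to a rigid rotation;
  strongly conflicting window predictions surface as large variance rather
  than being reconciled.
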