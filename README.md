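# tetrafold

Coarse-grained structure prediction for short protein binding-site fragments
by ground-state search of a diagonal spin Hamiltonian on the tetrahedral
(diamond) lattice.

An L-residue peptide backbone is modeled as a self-avoiding walk whose L-1
steps each choose one of four tetrahedral directions (unit Cα–Cα bonds,
109.47° vertex angles). Each turn is stored in two qubits; stereochemical
constraints and residue–residue energetics become a Z-only (Ising-type)
operator

```
H = λ_c·H_chirality + λ_g·H_geometric + λ_d·H_steric + λ_i·H_interaction
```

built from two-qubit indicator projectors Π_t^(d) = P^(d0)_{t,0} P^(d1)_{t,1},
with Miyazawa–Jernigan contact energies J_ab weighting a brute-force-derived
contact-propensity mask. Because H is diagonal, basis states evaluate
classically and exactly; the ground state is found with one of three
interchangeable backends — exhaustive scan (oracle), simulated annealing, or
a two-stage variational quantum eigensolver (statevector-simulated Ry/CX
ansatz + COBYLA, then fixed-parameter sampling of 20 000 measurement shots).
The winning bitstring is reverse-mapped to a 3-D Cα trace (3.8 Å per bond)
and written as PDB. Sequences beyond direct solver capacity are assembled
from overlapping 7-residue windows whose predicted bond vectors are rigidly
re-aligned and merged by weighted averaging, with a per-bond variance map.

Intended for method development in lattice protein folding and
quantum/Ising-style optimization: every operator is sparse and exact, every
backend is seeded-deterministic, and every approximation has a brute-force
oracle next to it in the test suite.

## Worked example

Predict the 5-residue antibody loop fragment YAGYS with the exact backend
and write the Cα trace:

```
$ tetrafold solve YAGYS --backend exact --out yagys.pdb
sequence       : YAGYS
backend        : exhaustive
bitstring      : 0001
model energy   : 0.0000
turns          : [0, 1, 3, 1]
self-avoiding  : True
wrote yagys.pdb
```

The bitstring is the measured outcome over the 4 free qubits (turns 0 and 1
are pinned to quotient global lattice rotations); it decodes to the turn
sequence (0, 1, 3, 1), a backtrack-free self-avoiding walk. The model energy
0.0 is the valid-conformation floor: below 6 residues no lattice contact is
geometrically possible, so nothing can score below zero. With a 6-residue
fragment the interaction term becomes active:

```
$ tetrafold solve GAVEDG --backend exact
...
model energy   : -0.2240
```

the reward coming from Miyazawa–Jernigan contact propensities (dimensionless
model energy; more negative = more stabilizing).

A 42-residue chain (amyloid-β 1-42) goes through the sliding-window
assembler:

```
$ tetrafold window DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA --seed 1 --out ab42.pdb
residues        : 42
windows         : 36
mean bond var   : 0.341 rad^2
wrote ab42.pdb
```

The variance is the weighted mean squared angular disagreement between
overlapping windows per bond — the data behind a backbone-direction density
map; low-variance bonds are those on which repeated overlapping predictions
agree.

Docking pose tables (from any docking tool, columns
`run,rank,affinity,rmsd_lb,rmsd_ub`) aggregate into the three-metric score:

```
$ tetrafold evaluate --dock-table dock.csv
records        : 180 (complete: True)
mean affinity  : -4.911 kcal/mol
mean RLB       : 3.692 A
mean RUB       : 7.056 A
```

The same operations are available as a library (`tetrafold.build_total`,
`tetrafold.solve`, `tetrafold.predict_structure`,
`tetrafold.predict_long_sequence`, ...); see `docs/methods.md` for the model
details, parameter meanings, and limitations.

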