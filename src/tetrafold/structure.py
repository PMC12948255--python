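"""Bitstring decoding, C-alpha backbone construction, PDB I/O, and RMSD.

The decode convention is the single place where hardware measurement outcomes
are turned back into logical encoding bits: the projector convention assigns
the logical bit 1 to the Z = +1 eigenstate |0>, so the measured bit m maps to
the logical bit 1 - m.  Everything downstream (turn digits, fixed-turn
insertion, digit significance) is deterministic bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .lattice import TurnSequence, is_self_avoiding, turns_to_coordinates
from .pauli import QubitLayout

__all__ = [
    "DecodeConvention",
    "BackboneStructure",
    "bitstring_to_turns",
    "turns_to_bitstring",
    "turns_to_backbone",
    "write_pdb",
    "read_pdb_ca",
    "kabsch_rmsd",
]

#: standard C-alpha virtual bond length, Angstrom per lattice bond
DEFAULT_SCALE = 3.8

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_ONE = {v: k for k, v in _THREE.items()}


@dataclass(frozen=True)
class DecodeConvention:
    """How measured bitstrings map back to turn sequences.

    * ``flip_measured``: apply m -> 1 - m before reading logical digits
      (True for the projector convention used throughout the package).
    * digit significance: d = d0 + 2*d1 with d0 on qubit (t, 0).
    * bitstrings are written least qubit index first.
    """

    flip_measured: bool = True

    def measured_to_logical(self, bits: Sequence[int]) -> list[int]:
        if self.flip_measured:
            return [1 - int(b) for b in bits]
        return [int(b) for b in bits]

    def logical_to_measured(self, bits: Sequence[int]) -> list[int]:
        return self.measured_to_logical(bits)  # the flip is an involution


def bitstring_to_turns(
    bits: str | Sequence[int],
    layout: QubitLayout,
    convention: DecodeConvention | None = None,
) -> TurnSequence:
    """Reverse-map a measured bitstring to the full turn sequence.

    Fixed-turn values from the layout are re-inserted; each free turn reads
    its two logical bits as d = d0 + 2*d1.
    """
    convention = convention or DecodeConvention()
    bitlist = [int(b) for b in bits]
    if len(bitlist) != layout.n_qubits:
        raise ValueError(
            f"bitstring length {len(bitlist)} != free qubit count {layout.n_qubits}"
        )
    logical = convention.measured_to_logical(bitlist)
    turns = []
    for t in range(layout.n_turns):
        if layout.is_fixed(t):
            turns.append(layout.fixed[t])
        else:
            d0 = logical[layout.qubit(t, 0)]
            d1 = logical[layout.qubit(t, 1)]
            turns.append(d0 + 2 * d1)
    return TurnSequence(tuple(turns))


def turns_to_bitstring(
    turns: TurnSequence | Sequence[int],
    layout: QubitLayout,
    convention: DecodeConvention | None = None,
) -> str:
    """Encode a turn sequence as the measured bitstring the hardware would emit.

    Inverse of :func:`bitstring_to_turns`; fixed turns must match the layout.
    """
    convention = convention or DecodeConvention()
    if not isinstance(turns, TurnSequence):
        turns = TurnSequence(tuple(turns))
    if len(turns) != layout.n_turns:
        raise ValueError("turn count does not match layout")
    logical = [0] * layout.n_qubits
    for t, d in enumerate(turns):
        if layout.is_fixed(t):
            if layout.fixed[t] != d:
                raise ValueError(
                    f"turn {t} is fixed to {layout.fixed[t]} but sequence has {d}"
                )
            continue
        logical[layout.qubit(t, 0)] = d & 1
        logical[layout.qubit(t, 1)] = (d >> 1) & 1
    measured = convention.logical_to_measured(logical)
    return "".join(str(b) for b in measured)


@dataclass(frozen=True)
class BackboneStructure:
    """C-alpha trace in Angstrom with sequence annotation and provenance."""

    sequence: str
    ca_coords: np.ndarray
    scale: float = DEFAULT_SCALE
    valid: bool = True
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=float)
        if coords.shape != (len(self.sequence), 3):
            raise ValueError("coordinate count must match sequence length")
        object.__setattr__(self, "ca_coords", coords)

    @property
    def residue_count(self) -> int:
        return len(self.sequence)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.ca_coords, axis=0), axis=1)


def turns_to_backbone(
    turns: TurnSequence | Sequence[int],
    sequence: str,
    scale: float = DEFAULT_SCALE,
    provenance: Mapping[str, object] | None = None,
) -> BackboneStructure:
    """Build the C-alpha backbone from a turn sequence.

    Consecutive C-alpha distances equal ``scale`` exactly.  Invalid
    (self-intersecting) conformations are flagged, never rejected — the
    selection policy upstream decides what to do with them.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if not isinstance(turns, TurnSequence):
        turns = TurnSequence(tuple(turns))
    if turns.residue_count != len(sequence):
        raise ValueError("sequence length must equal turn count + 1")
    conf = turns_to_coordinates(turns)
    coords = conf.positions * scale
    prov = dict(provenance or {})
    prov.setdefault("turns", list(turns.turns))
    return BackboneStructure(
        sequence=sequence.upper(),
        ca_coords=coords,
        scale=scale,
        valid=is_self_avoiding(conf),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# PDB I/O (C-alpha traces)
# ---------------------------------------------------------------------------


def write_pdb(structure: BackboneStructure, path) -> None:
    """Write one CA ATOM record per residue (chain A, standard PDB columns)."""
    L = structure.residue_count
    atoms = struc.AtomArray(L)
    atoms.coord = structure.ca_coords
    atoms.atom_name = np.full(L, "CA")
    atoms.element = np.full(L, "C")
    atoms.chain_id = np.full(L, "A")
    atoms.res_id = np.arange(1, L + 1)
    try:
        atoms.res_name = np.array([_THREE[a] for a in structure.sequence])
    except KeyError as exc:
        raise ValueError(f"unknown residue code {exc.args[0]!r}") from None
    atoms.hetero = np.full(L, False)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb_ca(path) -> BackboneStructure:
    """Read a C-alpha trace back from a PDB file (first model, CA atoms only)."""
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from exc
    ca = atoms[atoms.atom_name == "CA"]
    if len(ca) == 0:
        raise ValueError(f"no CA atoms found in {path}")
    try:
        seq = "".join(_ONE[rn] for rn in ca.res_name)
    except KeyError as exc:
        raise ValueError(f"non-standard residue name {exc.args[0]!r}") from None
    return BackboneStructure(
        sequence=seq,
        ca_coords=np.asarray(ca.coord, dtype=float),
        provenance={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def kabsch_rotation(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Proper rotation matrix aligning centered ``coords_a`` onto ``coords_b``.

    SVD of the covariance with the determinant sign rule: if det(V U^T) < 0
    the smallest singular direction is flipped, which excludes reflections
    (degenerate/collinear sets inherit this rule deterministically).
    """
    h = coords_a.T @ coords_b
    u, _, vt = np.linalg.svd(h)
    d = 1.0 if np.linalg.det(vt.T @ u.T) >= 0 else -1.0
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD over proper rigid motions (rotation + translation).

    Reflections are not allowed, so mirror images of chiral point sets give a
    strictly positive value.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must share the same (N, 3) shape")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 points for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot = kabsch_rotation(ac, bc)
    diff = ac @ rot.T - bc
    return float(np.sqrt((diff**2).sum() / a.shape[0]))
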