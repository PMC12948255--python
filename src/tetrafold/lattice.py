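"""Tetrahedral (diamond) lattice geometry for coarse-grained peptide backbones.

A peptide of L residues is represented as a self-avoiding walk on the diamond
lattice: each of the L-1 backbone steps ("turns") picks one of four tetrahedral
directions, and successive steps alternate between the direction set and its
negation, which yields the stereochemical ~109.47 deg C-alpha virtual bond
angle.  Positions are stored as integer triples (multiples of 1/sqrt(3)) so
that self-avoidance and contact detection are exact; real-valued unit-bond
coordinates are produced only at the boundary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DIRECTION_VECTORS_INT",
    "TurnSequence",
    "LatticeConformation",
    "direction_vector",
    "vertex_angle",
    "turns_to_coordinates",
    "is_self_avoiding",
    "find_contacts",
    "enumerate_conformations",
]

# The four tetrahedral directions: (+-1,+-1,+-1) with an even number of minus
# signs.  Same direction twice in a row is the backtracking move because of the
# alternating-sign stepping p_{k+1} = p_k + (-1)^k a_d.
DIRECTION_VECTORS_INT: tuple[tuple[int, int, int], ...] = (
    (1, 1, 1),
    (1, -1, -1),
    (-1, 1, -1),
    (-1, -1, 1),
)

_SQRT3 = math.sqrt(3.0)

# Full enumeration above this length is refused unless explicitly overridden.
ENUMERATION_GUARD = 13


def direction_vector(d: int) -> np.ndarray:
    """Unit 3-vector for direction ``d`` in {0,1,2,3}.

    Distinct directions have pairwise dot product -1/3 (tetrahedral geometry).
    """
    if d not in (0, 1, 2, 3):
        raise ValueError(f"direction must be in {{0,1,2,3}}, got {d!r}")
    return np.asarray(DIRECTION_VECTORS_INT[d], dtype=float) / _SQRT3


def vertex_angle(d_prev: int, d_next: int) -> float:
    """Bond angle (degrees) at a residue between consecutive turns.

    Under alternating-sign stepping the two bonds meeting at residue k+1 are
    -(-1)^k a_{d_prev} and (-1)^{k+1} a_{d_next}; the angle between them is
    arccos(a_prev . a_next), independent of parity.  Distinct directions give
    arccos(-1/3) ~ 109.47 deg; equal directions give 0 deg (backtrack:
    p_{k+2} == p_k).
    """
    a = direction_vector(d_prev)
    b = direction_vector(d_next)
    cosang = float(np.clip(np.dot(a, b), -1.0, 1.0))
    # angle between (-1)^{k+1} a_prev and (-1)^{k+1} a_next
    return math.degrees(math.acos(cosang)) if d_prev != d_next else 0.0


@dataclass(frozen=True)
class TurnSequence:
    """Ordered tetrahedral direction choices for the L-1 steps of an L-mer."""

    turns: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "turns", tuple(int(t) for t in self.turns))
        if len(self.turns) < 1:
            raise ValueError("a peptide needs at least 2 residues (1 turn)")
        for t in self.turns:
            if t not in (0, 1, 2, 3):
                raise ValueError(f"invalid direction {t!r} in turn sequence")

    @property
    def residue_count(self) -> int:
        return len(self.turns) + 1

    def __len__(self) -> int:
        return len(self.turns)

    def __iter__(self) -> Iterator[int]:
        return iter(self.turns)

    def __getitem__(self, i):
        return self.turns[i]

    def is_backtrack_free(self) -> bool:
        return all(a != b for a, b in zip(self.turns, self.turns[1:]))


@dataclass(frozen=True)
class LatticeConformation:
    """Integer-scaled lattice path induced by a turn sequence.

    ``positions_int`` are integer triples; real coordinates (unit bond length)
    are ``positions_int / sqrt(3)``.
    """

    positions_int: tuple[tuple[int, int, int], ...]
    parity_start: int = 0

    @property
    def residue_count(self) -> int:
        return len(self.positions_int)

    @property
    def positions(self) -> np.ndarray:
        """Real coordinates with unit bond length."""
        return np.asarray(self.positions_int, dtype=float) / _SQRT3


def turns_to_coordinates(
    turns: TurnSequence | Sequence[int],
    origin: Sequence[int] = (0, 0, 0),
    parity_start: int = 0,
) -> LatticeConformation:
    """Map a turn sequence to lattice positions: p_{k+1} = p_k + (-1)^k a_d.

    ``parity_start`` shifts the alternating sign, which matters for sub-paths
    starting at an odd residue index.  Backtracking sequences are representable
    (validity is checked separately by :func:`is_self_avoiding`).
    """
    if not isinstance(turns, TurnSequence):
        turns = TurnSequence(tuple(turns))
    pos = [tuple(int(x) for x in origin)]
    for k, d in enumerate(turns):
        sign = -1 if (k + parity_start) % 2 else 1
        a = DIRECTION_VECTORS_INT[d]
        p = pos[-1]
        pos.append((p[0] + sign * a[0], p[1] + sign * a[1], p[2] + sign * a[2]))
    return LatticeConformation(tuple(pos), parity_start=parity_start)


def is_self_avoiding(conf: LatticeConformation) -> bool:
    """True iff no two residues occupy the same lattice site (exact)."""
    if conf.residue_count < 2:
        raise ValueError("need at least 2 positions")
    return len(set(conf.positions_int)) == conf.residue_count


def _unit_lattice_distance(p: tuple[int, int, int], q: tuple[int, int, int]) -> bool:
    # one lattice bond = integer vector with |.|^2 == 3
    dx, dy, dz = p[0] - q[0], p[1] - q[1], p[2] - q[2]
    return dx * dx + dy * dy + dz * dz == 3


def find_contacts(
    conf: LatticeConformation, min_separation: int = 3
) -> list[tuple[int, int]]:
    """Non-bonded residue pairs (i, j), j-i >= min_separation, at unit distance.

    A sublattice parity argument restricts realized contacts to odd j-i >= 5;
    that is a property of the lattice, not enforced here.
    """
    if not is_self_avoiding(conf):
        raise ValueError("contacts are only defined for self-avoiding conformations")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    out = []
    pts = conf.positions_int
    for i in range(len(pts)):
        for j in range(i + min_separation, len(pts)):
            if _unit_lattice_distance(pts[i], pts[j]):
                out.append((i, j))
    return out


def enumerate_conformations(
    L: int,
    fix_first_turns: bool = False,
    backtrack_free: bool = False,
    allow_large: bool = False,
) -> Iterator[TurnSequence]:
    """Yield all turn sequences for an L-mer.

    Counts: 4^(L-1) in full, 4*3^(L-2) when ``backtrack_free``, quotiented by
    turns[0]=0 (and turns[1]=1 for L >= 3) when ``fix_first_turns`` (this fixes
    the 12 global lattice rotations).
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if L > ENUMERATION_GUARD and not allow_large:
        raise ResourceWarning(
            f"full enumeration at L={L} exceeds the guard ({ENUMERATION_GUARD}); "
            "pass allow_large=True to override"
        )
    n_turns = L - 1

    first_choices = (0,) if fix_first_turns else (0, 1, 2, 3)
    for first in first_choices:
        if n_turns == 1:
            yield TurnSequence((first,))
            continue
        second_choices: Sequence[int]
        if fix_first_turns:
            second_choices = (1,)
        elif backtrack_free:
            second_choices = tuple(d for d in range(4) if d != first)
        else:
            second_choices = (0, 1, 2, 3)
        for second in second_choices:
            prefix = (first, second)
            if n_turns == 2:
                yield TurnSequence(prefix)
                continue
            for rest in _extend(prefix, n_turns - 2, backtrack_free):
                yield TurnSequence(rest)


def _extend(
    prefix: tuple[int, ...], remaining: int, backtrack_free: bool
) -> Iterator[tuple[int, ...]]:
    if remaining == 0:
        yield prefix
        return
    last = prefix[-1]
    for d in range(4):
        if backtrack_free and d == last:
            continue
        yield from _extend(prefix + (d,), remaining - 1, backtrack_free)


def conformation_to_json_dict(turns: TurnSequence, conf: LatticeConformation) -> dict:
    """JSON-ready export: turn indices plus real coordinates."""
    return {
        "turns": list(turns.turns),
        "coordinates": conf.positions.tolist(),
    }
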