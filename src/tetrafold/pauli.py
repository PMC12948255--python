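"""Sparse algebra of real linear combinations of Z-only Pauli strings.

Everything in the energy model is diagonal in the computational basis, so an
operator is fully described by a map ``frozenset(qubit indices) -> real
coefficient`` (the Z support of each Pauli string).  Products use Z.Z = I on
shared support, i.e. the symmetric difference of supports.

Bit/eigenvalue convention: projectors are built literally as
P^1 = (I + Z)/2 and P^0 = (I - Z)/2, so the *logical* bit 1 corresponds to the
Z eigenvalue +1.  A hardware measurement outcome m (|0> has eigenvalue +1)
therefore maps to the logical bit 1 - m; that flip lives in exactly one place,
:mod:`tetrafold.structure` (the decode convention), never inside the algebra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MERGE_TOL",
    "PauliZOperator",
    "QubitLayout",
    "projector",
    "indicator",
    "eval_basis",
    "to_dense_diagonal",
]

#: coefficients below this magnitude are dropped on canonicalization; exact
#: cancellations (e.g. the one-hot penalty) must collapse to the zero operator
MERGE_TOL = 1e-12

#: dense-diagonal export guard
DENSE_GUARD = 24


class PauliZOperator:
    """Real linear combination of Z-only Pauli strings on ``n_qubits``.

    Terms are kept canonical: unique supports, near-zero coefficients dropped.
    Immutable by convention; all arithmetic returns new operators.
    """

    __slots__ = ("n_qubits", "terms")

    def __init__(
        self,
        n_qubits: int,
        terms: Mapping[frozenset, float] | Iterable[tuple[Iterable[int], float]] = (),
    ):
        if n_qubits < 0:
            raise ValueError("n_qubits must be >= 0")
        self.n_qubits = int(n_qubits)
        canon: dict[frozenset, float] = {}
        items = terms.items() if isinstance(terms, Mapping) else terms
        for support, coeff in items:
            s = frozenset(int(q) for q in support)
            for q in s:
                if not (0 <= q < self.n_qubits):
                    raise ValueError(f"qubit index {q} out of range for n={n_qubits}")
            canon[s] = canon.get(s, 0.0) + float(coeff)
        self.terms: dict[frozenset, float] = {
            s: c for s, c in canon.items() if abs(c) > MERGE_TOL
        }

    # -- constructors -------------------------------------------------------
    @classmethod
    def zero(cls, n_qubits: int) -> "PauliZOperator":
        return cls(n_qubits)

    @classmethod
    def identity(cls, n_qubits: int, coeff: float = 1.0) -> "PauliZOperator":
        return cls(n_qubits, [((), coeff)])

    @classmethod
    def z(cls, n_qubits: int, qubit: int, coeff: float = 1.0) -> "PauliZOperator":
        return cls(n_qubits, [((qubit,), coeff)])

    # -- algebra ------------------------------------------------------------
    def __add__(self, other: "PauliZOperator") -> "PauliZOperator":
        self._check(other)
        merged = dict(self.terms)
        for s, c in other.terms.items():
            merged[s] = merged.get(s, 0.0) + c
        return PauliZOperator(self.n_qubits, merged)

    def __sub__(self, other: "PauliZOperator") -> "PauliZOperator":
        return self + (other * -1.0)

    def __mul__(self, other):
        if isinstance(other, PauliZOperator):
            return self._op_mul(other)
        return PauliZOperator(
            self.n_qubits, {s: c * float(other) for s, c in self.terms.items()}
        )

    __rmul__ = __mul__

    def _op_mul(self, other: "PauliZOperator") -> "PauliZOperator":
        self._check(other)
        out: dict[frozenset, float] = {}
        for s1, c1 in self.terms.items():
            for s2, c2 in other.terms.items():
                s = s1 ^ s2  # Z^2 = I on shared support
                out[s] = out.get(s, 0.0) + c1 * c2
        return PauliZOperator(self.n_qubits, out)

    def _check(self, other: "PauliZOperator") -> None:
        if self.n_qubits != other.n_qubits:
            raise ValueError(
                f"qubit count mismatch: {self.n_qubits} vs {other.n_qubits}"
            )

    @property
    def num_terms(self) -> int:
        return len(self.terms)

    def is_zero(self) -> bool:
        return not self.terms

    def __eq__(self, other) -> bool:
        if not isinstance(other, PauliZOperator):
            return NotImplemented
        return (self - other).is_zero() and self.n_qubits == other.n_qubits

    def __repr__(self) -> str:
        return f"PauliZOperator(n_qubits={self.n_qubits}, num_terms={self.num_terms})"

    # -- evaluation ---------------------------------------------------------
    def eval_logical_bits(self, bits: Sequence[int]) -> float:
        """Diagonal value on a basis state given as *logical* bits.

        Logical bit 1 maps to Z eigenvalue +1 (projector convention above).
        """
        if len(bits) != self.n_qubits:
            raise ValueError(
                f"bitstring length {len(bits)} != n_qubits {self.n_qubits}"
            )
        z = [1.0 if int(b) else -1.0 for b in bits]
        total = 0.0
        for support, coeff in self.terms.items():
            v = coeff
            for q in support:
                v *= z[q]
            total += v
        return total

    def to_dense_diagonal(self) -> np.ndarray:
        """Full diagonal, indexed by the *measured* bit pattern.

        Index i has measured bit (i >> q) & 1 on qubit q; measured bit 0 is
        the Z = +1 eigenstate, so diag[0...0] evaluates all-logical-ones.
        """
        n = self.n_qubits
        if n > DENSE_GUARD:
            raise ValueError(f"dense diagonal refused for n_qubits={n} > {DENSE_GUARD}")
        size = 1 << n
        diag = np.zeros(size)
        idx = np.arange(size)
        zcache = {}
        for support, coeff in self.terms.items():
            v = np.full(size, coeff)
            for q in support:
                if q not in zcache:
                    zcache[q] = 1.0 - 2.0 * ((idx >> q) & 1)
                v = v * zcache[q]
            diag += v
        return diag

    # -- serialization ------------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "n_qubits": self.n_qubits,
            "terms": [
                {"support": sorted(s), "coeff": c}
                for s, c in sorted(self.terms.items(), key=lambda kv: sorted(kv[0]))
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PauliZOperator":
        return cls(d["n_qubits"], [(t["support"], t["coeff"]) for t in d["terms"]])

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict())

    @classmethod
    def from_json(cls, s: str) -> "PauliZOperator":
        return cls.from_json_dict(json.loads(s))


@dataclass(frozen=True)
class QubitLayout:
    """Two qubits per turn, q(t, b) = 2*rank(t) + b over the free turns.

    ``fixed`` maps turn index -> pinned direction (used to quotient global
    lattice rotations: turn 0 -> 0 and turn 1 -> 1 by default in solvers).
    Fixed turns consume no qubits.
    """

    residue_count: int
    fixed: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residue_count < 2:
            raise ValueError("residue_count must be >= 2")
        fx = {int(t): int(d) for t, d in dict(self.fixed).items()}
        for t, d in fx.items():
            if not (0 <= t < self.n_turns):
                raise ValueError(f"fixed turn {t} out of range")
            if d not in (0, 1, 2, 3):
                raise ValueError(f"fixed direction {d} invalid")
        object.__setattr__(self, "fixed", fx)
        free = tuple(t for t in range(self.n_turns) if t not in fx)
        object.__setattr__(self, "_free_turns", free)
        object.__setattr__(self, "_rank", {t: i for i, t in enumerate(free)})

    @property
    def n_turns(self) -> int:
        return self.residue_count - 1

    @property
    def free_turns(self) -> tuple[int, ...]:
        return self._free_turns  # type: ignore[attr-defined]

    @property
    def n_qubits(self) -> int:
        return 2 * len(self.free_turns)

    def is_fixed(self, t: int) -> bool:
        return t in self.fixed

    def qubit(self, t: int, b: int) -> int:
        """Qubit index for bit b of free turn t."""
        if b not in (0, 1):
            raise ValueError("bit must be 0 or 1")
        rank = self._rank.get(t)  # type: ignore[attr-defined]
        if rank is None:
            raise ValueError(f"turn {t} is fixed or out of range")
        return 2 * rank + b

    @classmethod
    def with_symmetry_fixing(cls, residue_count: int) -> "QubitLayout":
        """Layout quotienting the 12 global rotations: turn0=0, turn1=1."""
        fixed = {0: 0}
        if residue_count >= 3:
            fixed[1] = 1
        return cls(residue_count, fixed)


def projector(layout: QubitLayout, t: int, b: int, bitval: int) -> PauliZOperator:
    """Single-qubit projector P^1 = (I + Z)/2, P^0 = (I - Z)/2 on qubit (t, b)."""
    if bitval not in (0, 1):
        raise ValueError("bitval must be 0 or 1")
    q = layout.qubit(t, b)
    s = 1.0 if bitval == 1 else -1.0
    n = layout.n_qubits
    return PauliZOperator(n, [((), 0.5), ((q,), 0.5 * s)])


def indicator(layout: QubitLayout, t: int, d: int) -> PauliZOperator:
    """Two-qubit indicator Pi_t^(d) selecting direction d = d0 + 2*d1 on turn t.

    d0 (the least-significant digit) lives on qubit (t, 0).  For a fixed turn
    the indicator degenerates to the identity (d matches the pin) or the zero
    operator.  By construction sum_d Pi_t^(d) = I and Pi^(d) Pi^(e) =
    delta_de Pi^(d).
    """
    if d not in (0, 1, 2, 3):
        raise ValueError(f"invalid direction {d!r}")
    n = layout.n_qubits
    if layout.is_fixed(t):
        if layout.fixed[t] == d:
            return PauliZOperator.identity(n)
        return PauliZOperator.zero(n)
    d0, d1 = d & 1, (d >> 1) & 1
    return projector(layout, t, 0, d0) * projector(layout, t, 1, d1)


def eval_basis(op: PauliZOperator, bits: Sequence[int]) -> float:
    """Functional form of :meth:`PauliZOperator.eval_logical_bits`."""
    return op.eval_logical_bits(bits)


def to_dense_diagonal(op: PauliZOperator) -> np.ndarray:
    """Functional form of :meth:`PauliZOperator.to_dense_diagonal`."""
    return op.to_dense_diagonal()
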