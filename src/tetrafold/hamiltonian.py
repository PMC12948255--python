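"""Assembly of the total diagonal Hamiltonian H_t = lc*Hc + lg*Hg + ld*Hd + li*Hi.

Four energy groups act on the turn-encoded backbone:

* geometric (Hg): a one-hot penalty per turn (identically zero under the dense
  2-qubit encoding — it is still constructed and simplified, never skipped)
  plus an angle penalty on adjacent-turn pairs outside the allowed set A;
* chirality/backtracking (Hc): immediate reversals (d, d) and forbidden
  handedness triples of consecutive turns;
* steric (Hd): a pairwise collision-propensity mask C over nearby turn pairs;
* interaction (Hi): Miyazawa-Jernigan contact energies J weighted by a
  contact-propensity mask M.

A pairwise mask cannot encode exact self-avoidance, so C and M are defined by
exact marginalization over the intermediate turns (brute-force enumeration,
cached); exact steric/contact accounting is restored at decode time via
:func:`exact_conformation_energy`.  Energies are dimensionless model energy.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .lattice import (
    DIRECTION_VECTORS_INT,
    LatticeConformation,
    TurnSequence,
    find_contacts,
    is_self_avoiding,
    turns_to_coordinates,
)
from .pauli import PauliZOperator, QubitLayout, indicator

__all__ = [
    "PenaltyWeights",
    "BuildConfig",
    "MJMatrix",
    "ProblemHamiltonian",
    "ALLOWED_PAIRS",
    "FORBIDDEN_BACKTRACK_PAIRS",
    "chirality_forbidden_triples",
    "steric_mask",
    "contact_mask",
    "build_geometric",
    "build_chirality",
    "build_steric",
    "build_interaction",
    "build_total",
    "exact_conformation_energy",
    "parse_sequence",
]

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PenaltyWeights:
    """All strictly positive; penalties must dominate contact rewards."""

    lambda_c: float = 1.0
    lambda_g: float = 1.0
    lambda_d: float = 1.0
    lambda_i: float = 1.0
    mu_oh: float = 50.0
    mu_ang: float = 20.0
    kappa_bt: float = 20.0
    kappa_chi: float = 10.0
    eta: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "lambda_c", "lambda_g", "lambda_d", "lambda_i",
            "mu_oh", "mu_ang", "kappa_bt", "kappa_chi", "eta",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"penalty weight {name} must be > 0")


@dataclass(frozen=True)
class BuildConfig:
    """Builder settings: mask windows, size guard, symmetry fixing."""

    w_steric: int = 4
    w_contact: int = 7
    fix_first_turns: bool = False
    max_residues: int = 13

    def layout_for(self, L: int) -> QubitLayout:
        if self.fix_first_turns:
            return QubitLayout.with_symmetry_fixing(L)
        return QubitLayout(L)


# ---------------------------------------------------------------------------
# Miyazawa-Jernigan contact energies
# ---------------------------------------------------------------------------

MJ_ALPHABET = "CMFILVWYAGTSNQDEHRKP"

# Published 20x20 contact-energy table (e_ij, RT units), upper triangle in the
# row order above; mirrored to a symmetric matrix at load time.
_MJ_UPPER = """
-5.44 -4.99 -5.80 -5.50 -5.83 -4.96 -4.95 -4.16 -3.57 -3.16 -3.11 -2.86 -2.59 -2.85 -2.41 -2.27 -3.60 -2.57 -1.95 -3.07
-5.46 -6.56 -6.02 -6.41 -5.32 -5.55 -4.91 -3.94 -3.39 -3.51 -3.03 -2.95 -3.30 -2.57 -2.89 -3.98 -3.12 -2.48 -3.45
-7.26 -6.84 -7.28 -6.29 -6.16 -5.66 -4.81 -4.13 -4.28 -4.02 -3.75 -4.10 -3.48 -3.56 -4.77 -3.98 -3.36 -4.25
-6.54 -7.04 -6.05 -5.78 -5.25 -4.58 -3.78 -4.03 -3.52 -3.24 -3.67 -3.17 -3.27 -4.14 -3.63 -3.01 -3.76
-7.37 -6.48 -6.14 -5.67 -4.91 -4.16 -4.34 -3.92 -3.74 -4.04 -3.40 -3.59 -4.54 -4.03 -3.37 -4.20
-5.52 -5.18 -4.62 -4.04 -3.38 -3.46 -3.05 -2.83 -3.07 -2.48 -2.67 -3.58 -3.07 -2.49 -3.32
-5.06 -4.66 -3.82 -3.42 -3.22 -2.99 -3.07 -3.11 -2.84 -2.99 -3.98 -3.41 -2.69 -3.73
-4.17 -3.36 -3.01 -3.01 -2.78 -2.76 -2.97 -2.76 -2.79 -3.52 -3.16 -2.60 -3.19
-2.72 -2.31 -2.32 -2.01 -1.84 -1.89 -1.70 -1.51 -2.41 -1.83 -1.31 -2.03
-2.24 -2.08 -1.82 -1.74 -1.66 -1.59 -1.22 -2.15 -1.72 -1.15 -1.87
-2.12 -1.96 -1.88 -1.90 -1.80 -1.74 -2.42 -1.90 -1.31 -1.90
-1.67 -1.58 -1.49 -1.63 -1.48 -2.11 -1.62 -1.05 -1.57
-1.68 -1.71 -1.68 -1.51 -2.08 -1.64 -1.21 -1.53
-1.54 -1.46 -1.42 -1.98 -1.80 -1.29 -1.73
-1.21 -1.02 -2.32 -2.29 -1.68 -1.33
-0.91 -2.15 -2.27 -1.80 -1.26
-3.05 -2.16 -1.35 -2.25
-1.55 -0.59 -1.70
-0.12 -0.97
-1.75
"""


class MJMatrix:
    """20x20 symmetric residue-residue contact-energy matrix."""

    def __init__(self, matrix: np.ndarray, alphabet: str = MJ_ALPHABET):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(alphabet), len(alphabet)):
            raise ValueError("matrix shape must match alphabet length")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("contact-energy matrix must be symmetric")
        if len(set(alphabet)) != 20 or set(alphabet) != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("alphabet must cover the 20 canonical residues")
        self.alphabet = alphabet
        self.matrix = matrix
        self._index = {a: i for i, a in enumerate(alphabet)}

    def energy(self, a: str, b: str) -> float:
        try:
            return float(self.matrix[self._index[a.upper()], self._index[b.upper()]])
        except KeyError as exc:
            raise KeyError(f"unknown residue code {exc.args[0]!r}") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.energy(*pair)

    @classmethod
    def default(cls) -> "MJMatrix":
        rows = [r.split() for r in _MJ_UPPER.strip().splitlines()]
        n = len(MJ_ALPHABET)
        m = np.zeros((n, n))
        for i, row in enumerate(rows):
            vals = [float(x) for x in row]
            if len(vals) != n - i:
                raise RuntimeError("malformed packaged contact-energy table")
            for k, v in enumerate(vals):
                m[i, i + k] = v
                m[i + k, i] = v
        return cls(m)

    @classmethod
    def from_file(cls, path) -> "MJMatrix":
        """Load a whitespace-delimited 20x20 table with one-letter header row/column."""
        with open(path) as fh:
            lines = [ln.split() for ln in fh if ln.strip()]
        header = [c.upper() for c in lines[0]]
        if len(header) != 20:
            raise ValueError("header row must list 20 one-letter residue codes")
        n = 20
        m = np.zeros((n, n))
        for i, row in enumerate(lines[1 : n + 1]):
            if row[0].upper() != header[i]:
                raise ValueError(f"row {i + 1}: header column mismatch")
            m[i] = [float(x) for x in row[1 : n + 1]]
        return cls(m, "".join(header))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(self.alphabet) + "\n")
            for i, a in enumerate(self.alphabet):
                fh.write(a + " " + " ".join(f"{v:.2f}" for v in self.matrix[i]) + "\n")


# ---------------------------------------------------------------------------
# constraint sets
# ---------------------------------------------------------------------------

#: ordered adjacent-turn pairs realizing the tetrahedral 109.47 deg angle
ALLOWED_PAIRS = frozenset((d, e) for d in range(4) for e in range(4) if d != e)

#: immediate reversals (same direction twice under alternating-sign stepping)
FORBIDDEN_BACKTRACK_PAIRS = frozenset((d, d) for d in range(4))


def _det3(d: int, e: int, f: int) -> int:
    a, b, c = (
        DIRECTION_VECTORS_INT[d],
        DIRECTION_VECTORS_INT[e],
        DIRECTION_VECTORS_INT[f],
    )
    return (
        a[0] * (b[1] * c[2] - b[2] * c[1])
        - a[1] * (b[0] * c[2] - b[2] * c[0])
        + a[2] * (b[0] * c[1] - b[1] * c[0])
    )


@functools.lru_cache(maxsize=None)
def chirality_forbidden_triples(parity: int) -> frozenset:
    """Forbidden all-distinct turn triples (d, e, f) for a given middle-turn parity.

    Handedness of three consecutive turns is the sign of
    (-1)^t * det[a_d, a_e, a_f] with t the middle turn index; the
    negative-handedness triples are penalized.  Triples with any repeated
    direction are excluded (the backtrack/angle terms already cover them).
    The sign alternates with step parity because bond vectors alternate sign.
    """
    sign = -1 if parity % 2 else 1
    out = set()
    for d, e, f in itertools.permutations(range(4), 3):
        if sign * _det3(d, e, f) < 0:
            out.add((d, e, f))
    return frozenset(out)


# ---------------------------------------------------------------------------
# brute-force mask tables
# ---------------------------------------------------------------------------


def _backtrack_free_completions(sep: int, d: int, e: int):
    """Yield intermediate-turn tuples making (d, m1..m_{sep-1}, e) backtrack-free."""
    if sep < 2:
        raise ValueError("completions defined for sep >= 2")
    slots = sep - 1

    def rec(prefix: tuple[int, ...]):
        if len(prefix) == slots:
            if prefix[-1] != e if slots else d != e:
                yield prefix
            return
        last = prefix[-1] if prefix else d
        for m in range(4):
            if m != last:
                yield from rec(prefix + (m,))

    yield from rec(())


@functools.lru_cache(maxsize=None)
def _mask_pair(sep: int, parity: int, d: int, e: int) -> tuple[float, float]:
    """(collision propensity, contact propensity) for turn pair at separation sep.

    Enumerates all backtrack-free assignments of the sep-1 intermediate turns
    of the sub-path carrying residues t .. u+1 (turn t = d, turn u = e, start
    parity = t mod 2).  Collision: fraction of backtrack-free completions whose
    partial path revisits a site.  Contact: fraction of backtrack-free,
    self-avoiding completions placing residues t and u+1 at unit distance.
    """
    if sep == 1:
        return (1.0 if d == e else 0.0, 0.0)
    n_bt_free = 0
    n_collide = 0
    n_self_avoiding = 0
    n_contact = 0
    for mids in _backtrack_free_completions(sep, d, e):
        turns = (d,) + mids + (e,)
        n_bt_free += 1
        conf = turns_to_coordinates(turns, parity_start=parity % 2)
        pts = conf.positions_int
        if len(set(pts)) < len(pts):
            n_collide += 1
        else:
            n_self_avoiding += 1
            dx = pts[0][0] - pts[-1][0]
            dy = pts[0][1] - pts[-1][1]
            dz = pts[0][2] - pts[-1][2]
            if dx * dx + dy * dy + dz * dz == 3:
                n_contact += 1
    coll = n_collide / n_bt_free if n_bt_free else 0.0
    cont = n_contact / n_self_avoiding if n_self_avoiding else 0.0
    return (coll, cont)


def steric_mask(sep: int, parity: int, d: int, e: int, w_steric: int = 4) -> float:
    """Collision propensity C(sep, parity, d, e) in [0, 1]; 0 beyond the window."""
    if sep < 1:
        raise ValueError("sep must be >= 1")
    if sep > w_steric:
        return 0.0
    return _mask_pair(sep, parity % 2, d, e)[0]


def contact_mask(sep: int, parity: int, d: int, e: int, w_contact: int = 7) -> float:
    """Contact propensity M(sep, parity, d, e) in [0, 1].

    Vanishes whenever the residue separation sep+1 is even or below 5 (diamond
    sublattice parity), which the enumeration reproduces exactly.
    """
    if sep < 2:
        return 0.0
    if sep > w_contact:
        return 0.0
    return _mask_pair(sep, parity % 2, d, e)[1]


# ---------------------------------------------------------------------------
# Hamiltonian terms
# ---------------------------------------------------------------------------


def build_geometric(layout: QubitLayout, weights: PenaltyWeights) -> PauliZOperator:
    """Hg = mu_oh * sum_t (I - sum_d Pi_t^d)^2 + mu_ang * sum over pairs not in A.

    Under the dense 2-qubit encoding sum_d Pi_t^d == I, so the one-hot term is
    constructed and then provably simplifies to the zero operator.
    """
    n = layout.n_qubits
    onehot = PauliZOperator.zero(n)
    for t in range(layout.n_turns):
        s = PauliZOperator.identity(n)
        for d in range(4):
            s = s - indicator(layout, t, d)
        onehot = onehot + s * s
    angle = PauliZOperator.zero(n)
    for t in range(1, layout.n_turns):
        for d in range(4):
            for e in range(4):
                if (d, e) not in ALLOWED_PAIRS:
                    angle = angle + indicator(layout, t - 1, d) * indicator(layout, t, e)
    return weights.mu_oh * onehot + weights.mu_ang * angle


def build_chirality(layout: QubitLayout, weights: PenaltyWeights) -> PauliZOperator:
    """Hc: backtrack pairs (kappa_bt) plus forbidden handedness triples (kappa_chi)."""
    n = layout.n_qubits
    bt = PauliZOperator.zero(n)
    for t in range(1, layout.n_turns):
        for d, e in FORBIDDEN_BACKTRACK_PAIRS:
            bt = bt + indicator(layout, t - 1, d) * indicator(layout, t, e)
    chi = PauliZOperator.zero(n)
    for t in range(1, layout.n_turns - 1):
        forbidden = chirality_forbidden_triples(t % 2)
        for d, e, f in forbidden:
            chi = chi + (
                indicator(layout, t - 1, d)
                * indicator(layout, t, e)
                * indicator(layout, t + 1, f)
            )
    return weights.kappa_bt * bt + weights.kappa_chi * chi


def build_steric(
    layout: QubitLayout, weights: PenaltyWeights, config: BuildConfig | None = None
) -> PauliZOperator:
    """Hd = eta * sum_{t<u, u-t<=w_steric} C(u-t, t%2, d, e) Pi_t^d Pi_u^e."""
    config = config or BuildConfig()
    n = layout.n_qubits
    op = PauliZOperator.zero(n)
    for t in range(layout.n_turns):
        for u in range(t + 1, min(layout.n_turns, t + config.w_steric + 1)):
            for d in range(4):
                for e in range(4):
                    c = steric_mask(u - t, t % 2, d, e, config.w_steric)
                    if c:
                        op = op + c * (indicator(layout, t, d) * indicator(layout, u, e))
    return weights.eta * op


def build_interaction(
    layout: QubitLayout,
    sequence: str,
    mj: MJMatrix,
    config: BuildConfig | None = None,
) -> PauliZOperator:
    """Hi = sum_{t<u} J[res t][res u+1] * M(u-t, t%2, d, e) Pi_t^d Pi_u^e.

    The residue pair scored for turn pair (t, u) is (t, u+1): the residues
    whose spatial proximity the contact mask measures.
    """
    config = config or BuildConfig()
    sequence = sequence.upper()
    if len(sequence) != layout.residue_count:
        raise ValueError("sequence length does not match layout residue count")
    for i, aa in enumerate(sequence):
        if aa not in mj.alphabet:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
    n = layout.n_qubits
    op = PauliZOperator.zero(n)
    for t in range(layout.n_turns):
        for u in range(t + 1, min(layout.n_turns, t + config.w_contact + 1)):
            j = mj.energy(sequence[t], sequence[u + 1])
            if j == 0.0:
                continue
            for d in range(4):
                for e in range(4):
                    m = contact_mask(u - t, t % 2, d, e, config.w_contact)
                    if m:
                        op = op + (j * m) * (
                            indicator(layout, t, d) * indicator(layout, u, e)
                        )
    return op


@dataclass(frozen=True)
class ProblemHamiltonian:
    """Assembled Z-only energy model for one sequence.

    Sub-operators are retained for diagnostics; ``operator`` equals
    lc*Hc + lg*Hg + ld*Hd + li*Hi within the canonicalization tolerance.
    """

    operator: PauliZOperator
    layout: QubitLayout
    sequence: str
    weights: PenaltyWeights
    config: BuildConfig
    mj: MJMatrix
    h_geometric: PauliZOperator
    h_chirality: PauliZOperator
    h_steric: PauliZOperator
    h_interaction: PauliZOperator

    @property
    def n_qubits(self) -> int:
        return self.layout.n_qubits


def build_total(
    sequence: str,
    weights: PenaltyWeights | None = None,
    config: BuildConfig | None = None,
    mj: MJMatrix | None = None,
) -> ProblemHamiltonian:
    """Assemble the total Hamiltonian for an amino-acid sequence.

    Deterministic for a fixed configuration.  A warning-level check compares
    the largest attainable contact reward against the smallest active penalty
    (penalties must dominate for constraint violations to stay excited).
    """
    sequence = parse_sequence(sequence)
    weights = weights or PenaltyWeights()
    config = config or BuildConfig()
    mj = mj or MJMatrix.default()
    L = len(sequence)
    if L < 2:
        raise ValueError("sequence must have at least 2 residues")
    if L > config.max_residues:
        raise ValueError(
            f"sequence length {L} exceeds the builder guard "
            f"({config.max_residues}); use the sliding-window assembler"
        )
    layout = config.layout_for(L)
    hg = build_geometric(layout, weights)
    hc = build_chirality(layout, weights)
    hd = build_steric(layout, weights, config)
    hi = build_interaction(layout, sequence, mj, config)

    max_reward = float(np.abs(mj.matrix).max()) * max(0, L - 5)
    min_penalty = min(
        weights.lambda_c * weights.kappa_bt,
        weights.lambda_g * weights.mu_ang,
    )
    if max_reward > 0 and weights.lambda_i * max_reward > min_penalty:
        import warnings

        warnings.warn(
            "attainable contact reward exceeds the smallest active penalty; "
            "constraint-violating states may become ground states",
            stacklevel=2,
        )

    total = (
        weights.lambda_c * hc
        + weights.lambda_g * hg
        + weights.lambda_d * hd
        + weights.lambda_i * hi
    )
    return ProblemHamiltonian(
        operator=total,
        layout=layout,
        sequence=sequence,
        weights=weights,
        config=config,
        mj=mj,
        h_geometric=hg,
        h_chirality=hc,
        h_steric=hd,
        h_interaction=hi,
    )


# ---------------------------------------------------------------------------
# exact conformation-level energy (decode-side oracle)
# ---------------------------------------------------------------------------


def exact_conformation_energy(
    sequence: str,
    turns: TurnSequence | Sequence[int],
    mj: MJMatrix | None = None,
    weights: PenaltyWeights | None = None,
) -> float:
    """Exact model energy of a decoded conformation; +inf if not self-avoiding.

    Sums the contact energies over exact lattice contacts (separation >= 3)
    and adds kappa_chi per forbidden handedness triple.  Used to re-rank
    sampled bitstrings and to validate the pairwise-mask approximation.
    """
    if not isinstance(turns, TurnSequence):
        turns = TurnSequence(tuple(turns))
    sequence = parse_sequence(sequence)
    if turns.residue_count != len(sequence):
        raise ValueError("turn count does not match sequence length")
    mj = mj or MJMatrix.default()
    weights = weights or PenaltyWeights()
    conf = turns_to_coordinates(turns)
    if not is_self_avoiding(conf):
        return math.inf
    energy = 0.0
    for i, j in find_contacts(conf, min_separation=3):
        energy += mj.energy(sequence[i], sequence[j])
    for t in range(1, len(turns) - 1):
        triple = (turns[t - 1], turns[t], turns[t + 1])
        if triple in chirality_forbidden_triples(t % 2):
            energy += weights.kappa_chi
    return energy


# ---------------------------------------------------------------------------
# sequence input
# ---------------------------------------------------------------------------


def parse_sequence(text: str) -> str:
    """Accept a plain one-letter string or a single-record FASTA block."""
    text = text.strip()
    if text.startswith(">"):
        lines = text.splitlines()
        body = "".join(ln.strip() for ln in lines[1:] if not ln.startswith(">"))
        if any(ln.startswith(">") for ln in lines[1:]):
            raise ValueError("expected a single FASTA record")
        text = body
    seq = "".join(text.split()).upper()
    if not seq:
        raise ValueError("empty sequence")
    return seq
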