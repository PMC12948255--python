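"""Ground-state search for the diagonal Hamiltonian.

Three interchangeable backends behind one result contract:

* ``exhaustive_ground_state`` — exact scan of the full diagonal (oracle);
* ``simulated_annealing`` — Metropolis walk in turn space with geometric
  cooling (the classical baseline);
* two-stage VQE — stage 1 optimizes a layered Ry(/Rz) + CX ansatz with a
  derivative-free COBYLA loop over the statevector expectation; stage 2
  freezes the parameters and samples a measurement histogram from which the
  structural bitstring is selected.

Bitstrings everywhere in this module are *measured* bitstrings: character i is
the measurement outcome of qubit i (|0> = Z eigenvalue +1).  The measured ->
logical flip happens once, in :mod:`tetrafold.structure`.

All randomness flows from one master seed, fanned out to parameter
initialization, shot sampling, and annealing via fixed sub-seed offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .hamiltonian import ProblemHamiltonian, exact_conformation_energy
from .pauli import PauliZOperator

__all__ = [
    "AnsatzSpec",
    "VQEConfig",
    "AnnealSchedule",
    "SolverResult",
    "exhaustive_ground_state",
    "simulated_annealing",
    "ansatz_state",
    "expectation",
    "vqe_optimize",
    "sample_measurements",
    "select_structure",
    "solve",
]

#: statevector backends refuse more free qubits than this
STATEVECTOR_GUARD = 20

_SUBSEED_PARAMS = 101
_SUBSEED_SHOTS = 211
_SUBSEED_MEAS = 307
_SUBSEED_ANNEAL = 401


# ---------------------------------------------------------------------------
# contracts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnsatzSpec:
    """Hardware-efficient layered ansatz: rotation layers interleaved with CX.

    ``reps`` entangling blocks give ``reps + 1`` rotation layers, so the
    parameter count is n_qubits * (reps + 1) * n_rotations, with n_rotations
    1 for "ry" and 2 for "ry+rz".  The "ry"-only variant produces real
    amplitudes, which suffices for a diagonal Hamiltonian.
    """

    n_qubits: int
    reps: int = 3
    rotation_set: str = "ry"
    entanglement: str = "linear"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.rotation_set not in ("ry", "ry+rz"):
            raise ValueError("rotation_set must be 'ry' or 'ry+rz'")
        if self.entanglement not in ("linear", "circular"):
            raise ValueError("entanglement must be 'linear' or 'circular'")

    @property
    def n_rotations(self) -> int:
        return 1 if self.rotation_set == "ry" else 2

    @property
    def n_params(self) -> int:
        return self.n_qubits * (self.reps + 1) * self.n_rotations


@dataclass(frozen=True)
class VQEConfig:
    """Two-stage execution settings.

    ``shots_opt = 0`` (or ``exact_expectation=True``) uses the analytic
    statevector expectation during optimization; stage 2 always samples
    ``shots_meas`` measurement bitstrings from the frozen circuit.
    """

    shots_opt: int = 2000
    shots_meas: int = 20000
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    exact_expectation: bool = False
    restarts: int = 1

    def __post_init__(self) -> None:
        if self.shots_opt < 0 or self.shots_meas < 0:
            raise ValueError("shot counts must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling: T_k = t0 * alpha^k over ``steps`` single-turn moves."""

    t0: float = 20.0
    alpha: float = 0.9995
    steps: int = 20000

    def __post_init__(self) -> None:
        if self.t0 <= 0 or not (0 < self.alpha < 1) or self.steps < 1:
            raise ValueError("invalid annealing schedule")


@dataclass(frozen=True)
class SolverResult:
    """Outcome of one ground-state search."""

    best_bitstring: str
    best_energy: float
    energy_trace: tuple[float, ...]
    histogram: Mapping[str, int]
    backend_name: str
    seed: int | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "best_bitstring": self.best_bitstring,
            "best_energy": self.best_energy,
            "energy_trace": list(self.energy_trace),
            "histogram": dict(self.histogram),
            "backend_name": self.backend_name,
            "seed": self.seed,
            "metadata": dict(self.metadata),
        }


# ---------------------------------------------------------------------------
# measured-bitstring helpers
# ---------------------------------------------------------------------------


def index_to_bitstring(index: int, n_qubits: int) -> str:
    """Measured bitstring, written least qubit index first."""
    return "".join("1" if (index >> q) & 1 else "0" for q in range(n_qubits))


def bitstring_to_index(bits: str) -> int:
    return sum(1 << q for q, b in enumerate(bits) if b == "1")


def energy_of_measured(op: PauliZOperator, bits: str) -> float:
    """Diagonal value for a measured bitstring (|0> = +1 eigenvalue)."""
    return op.eval_logical_bits([1 - int(b) for b in bits])


def _diag(op: PauliZOperator) -> np.ndarray:
    return op.to_dense_diagonal()


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def exhaustive_ground_state(problem: ProblemHamiltonian | PauliZOperator) -> SolverResult:
    """Exact global minimum over all basis states.

    Ties are broken toward the lexicographically smallest measured bitstring
    (equivalently the smallest basis index, since strings are written least
    qubit first).
    """
    op = problem.operator if isinstance(problem, ProblemHamiltonian) else problem
    diag = _diag(op)
    best_idx = None
    best_bits = None
    best_e = math.inf
    for idx in np.flatnonzero(diag == diag.min()):
        bits = index_to_bitstring(int(idx), op.n_qubits)
        if best_bits is None or bits < best_bits:
            best_bits, best_idx = bits, int(idx)
    best_e = float(diag[best_idx])
    return SolverResult(
        best_bitstring=best_bits,
        best_energy=best_e,
        energy_trace=(best_e,),
        histogram={best_bits: 1},
        backend_name="exhaustive",
        metadata={"n_states": int(diag.size)},
    )


# ---------------------------------------------------------------------------
# simulated annealing in turn space
# ---------------------------------------------------------------------------


def simulated_annealing(
    problem: ProblemHamiltonian,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
) -> SolverResult:
    """Metropolis search with single-turn resampling moves; seeded-deterministic.

    The walk lives in the space of free-turn assignments (a bijection with the
    measured basis states), so every visited state is a well-formed encoding.
    """
    schedule = schedule or AnnealSchedule()
    op = problem.operator
    n = op.n_qubits
    rng = np.random.default_rng(seed + _SUBSEED_ANNEAL)
    use_diag = n <= STATEVECTOR_GUARD
    diag = _diag(op) if use_diag else None

    n_free = n // 2

    def turn_index(turn_vals: np.ndarray) -> int:
        # measured bits: logical digit x -> measured 1-x on each of two qubits
        idx = 0
        for r, d in enumerate(turn_vals):
            m0 = 1 - (d & 1)
            m1 = 1 - ((d >> 1) & 1)
            idx |= m0 << (2 * r)
            idx |= m1 << (2 * r + 1)
        return idx

    def energy(turn_vals: np.ndarray) -> float:
        i = turn_index(turn_vals)
        if use_diag:
            return float(diag[i])
        return energy_of_measured(op, index_to_bitstring(i, n))

    state = rng.integers(0, 4, size=n_free)
    e = energy(state)
    best_state, best_e = state.copy(), e
    trace = [e]
    temp = schedule.t0
    for _ in range(schedule.steps):
        pos = int(rng.integers(n_free))
        new_d = int(rng.integers(4))
        old_d = int(state[pos])
        if new_d != old_d:
            state[pos] = new_d
            e_new = energy(state)
            if e_new <= e or rng.random() < math.exp(-(e_new - e) / temp):
                e = e_new
                if e < best_e:
                    best_e, best_state = e, state.copy()
            else:
                state[pos] = old_d
        temp *= schedule.alpha
        trace.append(e)
    best_bits = index_to_bitstring(turn_index(best_state), n)
    return SolverResult(
        best_bitstring=best_bits,
        best_energy=float(best_e),
        energy_trace=tuple(trace),
        histogram={best_bits: 1},
        backend_name="anneal",
        seed=seed,
        metadata={"schedule": {"t0": schedule.t0, "alpha": schedule.alpha,
                               "steps": schedule.steps}},
    )


# ---------------------------------------------------------------------------
# statevector simulation
# ---------------------------------------------------------------------------


def _apply_ry(state: np.ndarray, q: int, theta: float) -> np.ndarray:
    c, s = math.cos(theta / 2.0), math.sin(theta / 2.0)
    shaped = state.reshape(-1, 2, 1 << q)
    a0 = shaped[:, 0, :].copy()
    a1 = shaped[:, 1, :].copy()
    shaped[:, 0, :] = c * a0 - s * a1
    shaped[:, 1, :] = s * a0 + c * a1
    return state


def _apply_rz(state: np.ndarray, q: int, theta: float) -> np.ndarray:
    if not np.iscomplexobj(state):
        raise TypeError("Rz needs a complex statevector")
    shaped = state.reshape(-1, 2, 1 << q)
    shaped[:, 0, :] *= np.exp(-0.5j * theta)
    shaped[:, 1, :] *= np.exp(0.5j * theta)
    return state


def _apply_cx(state: np.ndarray, control: int, target: int) -> np.ndarray:
    n_qubits = state.size.bit_length() - 1
    idx = np.arange(state.size)
    ctrl_on = (idx >> control) & 1 == 1
    partner = idx ^ (1 << target)
    flipped = state[partner]
    state[ctrl_on] = flipped[ctrl_on]
    return state


def ansatz_state(params: Sequence[float], spec: AnsatzSpec) -> np.ndarray:
    """Deterministic normalized statevector for the layered ansatz.

    Layer order: rotation layer, then ``reps`` repetitions of (CX chain,
    rotation layer).  All-zero parameters with "ry" give |0...0>.
    """
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValueError(
            f"expected {spec.n_params} parameters, got {params.size}"
        )
    n = spec.n_qubits
    if n > STATEVECTOR_GUARD:
        raise ValueError(f"statevector refused for n_qubits={n} > {STATEVECTOR_GUARD}")
    complex_amp = spec.rotation_set == "ry+rz"
    state = np.zeros(1 << n, dtype=complex if complex_amp else float)
    state[0] = 1.0
    it = iter(params)

    def rotation_layer():
        for q in range(n):
            _apply_ry(state, q, next(it))
            if complex_amp:
                _apply_rz(state, q, next(it))

    rotation_layer()
    for _ in range(spec.reps):
        for q in range(n - 1):
            _apply_cx(state, q, q + 1)
        if spec.entanglement == "circular" and n > 1:
            _apply_cx(state, n - 1, 0)
        rotation_layer()
    return state


def expectation(
    op: PauliZOperator,
    state: np.ndarray,
    shots: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """<psi|H|psi> for a diagonal H: analytic for shots=0, sampled otherwise."""
    diag = _diag(op)
    probs = np.abs(state) ** 2
    probs = probs / probs.sum()
    if shots == 0:
        return float(np.dot(probs, diag))
    if rng is None:
        raise ValueError("sampled expectation needs an rng")
    counts = rng.multinomial(shots, probs)
    return float(np.dot(counts, diag) / shots)


def vqe_optimize(
    problem: ProblemHamiltonian | PauliZOperator,
    spec: AnsatzSpec | None = None,
    config: VQEConfig | None = None,
) -> tuple[np.ndarray, tuple[float, ...]]:
    """Stage 1: COBYLA minimization of the ansatz expectation.

    Returns the best parameter vector over ``config.restarts`` seeded restarts
    and the concatenated per-evaluation energy trace.  Seeded-deterministic
    when ``exact_expectation`` (the sampled objective is also seeded, but its
    noise makes the landscape stochastic by design).
    """
    op = problem.operator if isinstance(problem, ProblemHamiltonian) else problem
    config = config or VQEConfig()
    spec = spec or AnsatzSpec(n_qubits=op.n_qubits)
    if spec.n_qubits != op.n_qubits:
        raise ValueError("ansatz qubit count must match the Hamiltonian")
    exact = config.exact_expectation or config.shots_opt == 0

    trace: list[float] = []
    best_params = None
    best_e = math.inf
    for r in range(config.restarts):
        rng_init = np.random.default_rng(config.seed + _SUBSEED_PARAMS + 7919 * r)
        rng_shots = np.random.default_rng(config.seed + _SUBSEED_SHOTS + 7919 * r)
        x0 = rng_init.uniform(0.0, 2.0 * math.pi, size=spec.n_params)

        def objective(x: np.ndarray) -> float:
            state = ansatz_state(x, spec)
            e = expectation(
                op, state,
                shots=0 if exact else config.shots_opt,
                rng=None if exact else rng_shots,
            )
            trace.append(e)
            return e

        res = minimize(
            objective,
            x0,
            method="COBYLA",
            options={"maxiter": config.max_iter, "tol": config.tol},
        )
        final_e = expectation(op, ansatz_state(res.x, spec), shots=0)
        if final_e < best_e:
            best_e = final_e
            best_params = np.array(res.x)
    return best_params, tuple(trace)


def sample_measurements(
    params: Sequence[float],
    spec: AnsatzSpec,
    shots_meas: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Stage 2: sample measured bitstrings from the frozen circuit.

    The parameters are not modified (no further optimization); counts sum to
    ``shots_meas``.
    """
    params = np.asarray(params, dtype=float)
    frozen = params.copy()
    state = ansatz_state(frozen, spec)
    probs = np.abs(state) ** 2
    probs = probs / probs.sum()
    counts = rng.multinomial(shots_meas, probs)
    hist = {
        index_to_bitstring(int(i), spec.n_qubits): int(c)
        for i, c in enumerate(counts)
        if c > 0
    }
    if not np.array_equal(params, frozen):  # pragma: no cover - contract guard
        raise RuntimeError("stage-2 sampling must not mutate parameters")
    return hist


def select_structure(
    histogram: Mapping[str, int],
    problem: ProblemHamiltonian,
    mode: str = "top",
    top_k: int = 10,
) -> str:
    """Pick the structural bitstring from a measurement histogram.

    * ``top``: most frequent bitstring; ties break toward lower diagonal
      energy, then lexicographic order.
    * ``filtered``: most frequent whose decoded conformation is backtrack-free
      and self-avoiding.
    * ``rerank``: lowest exact conformation energy among the ``top_k`` most
      frequent.
    """
    if not histogram:
        raise ValueError("empty histogram")
    op = problem.operator

    def sort_key(item):
        bits, count = item
        return (-count, energy_of_measured(op, bits), bits)

    ranked = sorted(histogram.items(), key=sort_key)
    if mode == "top":
        return ranked[0][0]

    from .structure import DecodeConvention, bitstring_to_turns
    from .lattice import is_self_avoiding, turns_to_coordinates

    conv = DecodeConvention()
    if mode == "filtered":
        for bits, _ in ranked:
            turns = bitstring_to_turns(bits, problem.layout, conv)
            if turns.is_backtrack_free() and is_self_avoiding(
                turns_to_coordinates(turns)
            ):
                return bits
        raise ValueError(
            "no sampled bitstring decodes to a valid conformation; "
            "try mode='rerank' or increase shots"
        )
    if mode == "rerank":
        best_bits, best_e = None, math.inf
        for bits, _ in ranked[:top_k]:
            turns = bitstring_to_turns(bits, problem.layout, conv)
            e = exact_conformation_energy(
                problem.sequence, turns, problem.mj, problem.weights
            )
            if e < best_e:
                best_bits, best_e = bits, e
        if best_bits is None or math.isinf(best_e):
            best_bits = ranked[0][0]
        return best_bits
    raise ValueError(f"unknown selection mode {mode!r}")


# ---------------------------------------------------------------------------
# unified front end
# ---------------------------------------------------------------------------


def solve(
    problem: ProblemHamiltonian,
    backend: str = "exact",
    seed: int = 0,
    vqe_config: VQEConfig | None = None,
    ansatz: AnsatzSpec | None = None,
    schedule: AnnealSchedule | None = None,
    select_mode: str = "top",
) -> SolverResult:
    """Run one backend end to end and return a :class:`SolverResult`."""
    if backend == "exact":
        return exhaustive_ground_state(problem)
    if backend == "anneal":
        return simulated_annealing(problem, schedule, seed=seed)
    if backend == "vqe":
        config = vqe_config or VQEConfig(seed=seed)
        if config.seed != seed:
            config = VQEConfig(**{**config.__dict__, "seed": seed})
        spec = ansatz or AnsatzSpec(n_qubits=problem.n_qubits)
        params, trace = vqe_optimize(problem, spec, config)
        rng_meas = np.random.default_rng(seed + _SUBSEED_MEAS)
        hist = sample_measurements(params, spec, config.shots_meas, rng_meas)
        bits = select_structure(hist, problem, mode=select_mode)
        return SolverResult(
            best_bitstring=bits,
            best_energy=energy_of_measured(problem.operator, bits),
            energy_trace=trace,
            histogram=hist,
            backend_name="vqe",
            seed=seed,
            metadata={
                "shots_opt": config.shots_opt,
                "shots_meas": config.shots_meas,
                "max_iter": config.max_iter,
                "restarts": config.restarts,
                "optimal_params": params.tolist(),
                "ansatz": {
                    "reps": spec.reps,
                    "rotation_set": spec.rotation_set,
                    "entanglement": spec.entanglement,
                },
            },
        )
    raise ValueError(f"unknown backend {backend!r}")
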