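"""Execution backends for the pattern-search circuits.

Two backends:

* :func:`run_dense` — a dense statevector simulator for arbitrary gate
  lists.  General but exponential in qubit count; capped (default 24
  qubits) to keep memory bounded.
* :func:`run_effective` — exact reduced dynamics of a Grover iteration
  acting on the index register alone.  Because each compute–phase–
  uncompute iteration returns the target and pattern registers to their
  initial product state, the full circuit acts on the S index amplitudes
  as (reflect about the mean) o (negate marked); tracking only those S
  numbers is exact and scales to long targets.

:func:`analytic_success` is the closed-form Grover success probability
sin^2((2r+1) arcsin sqrt(k/S)), used as an independent oracle.
"""

from __future__ import annotations

import math

import numpy as np

from .circuit_model import Gate, QuantumCircuit

__all__ = [
    "ResourceCapError",
    "DEFAULT_QUBIT_CAP",
    "run_dense",
    "index_marginal",
    "sample_counts",
    "run_effective",
    "analytic_success",
    "total_variation",
]

DEFAULT_QUBIT_CAP = 24

_SQRT1_2 = 1.0 / math.sqrt(2.0)


class ResourceCapError(RuntimeError):
    """Raised when a circuit exceeds the dense-backend qubit cap."""


def _apply_gate(psi: np.ndarray, gate: Gate, circuit: QuantumCircuit) -> np.ndarray:
    """Apply one gate to a (2,)*n shaped statevector (qubit 0 = axis 0 = MSB)."""
    n = psi.ndim
    gi = circuit.global_index
    kind = gate.kind

    if kind == "MEASURE":
        # measurement is realized downstream by marginalization
        return psi

    if kind == "X":
        return np.flip(psi, axis=gi(gate.targets[0]))

    if kind == "H":
        ax = gi(gate.targets[0])
        a = psi.take(0, axis=ax)
        b = psi.take(1, axis=ax)
        return np.stack(((a + b) * _SQRT1_2, (a - b) * _SQRT1_2), axis=ax)

    if kind in ("CZ", "MCZ"):
        qubits = [gi(q) for q in gate.qubits]
        state = gate.ctrl_state if gate.ctrl_state is not None else (1,) * len(qubits)
        idx: list = [slice(None)] * n
        for ax, bit in zip(qubits, state):
            idx[ax] = bit
        psi = psi.copy()
        psi[tuple(idx)] *= -1.0
        return psi

    if kind in ("CNOT", "TOFFOLI", "MCX"):
        ctrls = [gi(q) for q in gate.controls]
        state = gate.ctrl_state if gate.ctrl_state is not None else (1,) * len(ctrls)
        tgt = gi(gate.targets[0])
        idx = [slice(None)] * n
        for ax, bit in zip(ctrls, state):
            idx[ax] = bit
        # axes with integer indices disappear from the sub-view
        adj = tgt - sum(1 for ax in ctrls if ax < tgt)
        psi = psi.copy()
        # .copy() avoids aliasing: the flipped view shares the buffer
        psi[tuple(idx)] = np.flip(psi[tuple(idx)], axis=adj).copy()
        return psi

    if kind == "CSWAP":
        c = gi(gate.controls[0])
        t1, t2 = (gi(q) for q in gate.targets)
        i01: list = [slice(None)] * n
        i01[c] = 1
        i10 = list(i01)
        i01[t1], i01[t2] = 0, 1
        i10[t1], i10[t2] = 1, 0
        psi = psi.copy()
        tmp = psi[tuple(i01)].copy()
        psi[tuple(i01)] = psi[tuple(i10)]
        psi[tuple(i10)] = tmp
        return psi

    raise ValueError(f"unsupported gate kind {kind!r}")  # pragma: no cover


def run_dense(
    circuit: QuantumCircuit,
    qubit_cap: int = DEFAULT_QUBIT_CAP,
    check_norm: bool = False,
) -> np.ndarray:
    """Simulate from |0...0>; returns the flat 2^n statevector.

    Amplitude index bit order: registers in declaration order, qubit 0 of
    each register most significant.  MEASURE gates are skipped (the index
    marginal realizes measurement).  ``check_norm`` asserts unit norm to
    1e-12 after every gate.
    """
    n = circuit.n_qubits
    if n > qubit_cap:
        raise ResourceCapError(
            f"{n} qubits exceeds the dense-backend cap of {qubit_cap}; "
            "use the effective backend (run_effective) for long targets"
        )
    psi = np.zeros((2,) * n if n else (1,), dtype=np.complex128)
    psi.flat[0] = 1.0
    for gate in circuit.gates:
        psi = _apply_gate(psi, gate, circuit)
        if check_norm:
            norm2 = float(np.vdot(psi, psi).real)
            if abs(norm2 - 1.0) >= 1e-12:
                raise AssertionError(f"norm drift after {gate.kind}: {norm2}")
    return psi.reshape(-1)


def index_marginal(
    state: np.ndarray, circuit: QuantumCircuit, register: str = "index"
) -> dict[int, float]:
    """Probability of each value of one register, marginalizing the rest."""
    n = circuit.n_qubits
    probs = np.abs(state.reshape((2,) * n if n else (1,))) ** 2
    reg_axes = [circuit.global_index(q) for q in circuit.register_qubits(register)]
    other = tuple(ax for ax in range(n) if ax not in reg_axes)
    marg = probs.sum(axis=other) if other else probs
    # reg_axes are contiguous and ascending; axis order already MSB-first
    flat = marg.reshape(-1)
    return {r: float(p) for r, p in enumerate(flat)}


def sample_counts(
    distribution: dict[int, float], shots: int, seed: int
) -> dict[int, int]:
    """Multinomial shot sampling of a measured distribution (seed mandatory)."""
    rng = np.random.default_rng(seed)
    values = sorted(distribution)
    p = np.array([distribution[v] for v in values], dtype=float)
    p = p / p.sum()
    draws = rng.multinomial(shots, p)
    return {v: int(c) for v, c in zip(values, draws) if c}


def run_effective(
    target_positions: int, marked: set[int] | frozenset[int], iterations: int
) -> dict[int, float]:
    """Exact index-register dynamics of the Grover-style search.

    Starts from the uniform amplitude vector over ``S = target_positions``
    shifts; each iteration negates the marked amplitudes (oracle) and
    reflects about the mean (diffusion D = 2|phi><phi| - I).  Returns the
    squared magnitudes as a shift -> probability map.
    """
    S = int(target_positions)
    if S < 1 or (S & (S - 1)):
        raise ValueError(f"target_positions must be a power of two, got {S}")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    marked = set(marked)
    if not marked <= set(range(S)):
        raise ValueError(f"marked shifts must lie in 0..{S - 1}")
    amp = np.full(S, 1.0 / math.sqrt(S))
    marked_idx = sorted(marked)
    for _ in range(iterations):
        amp[marked_idx] *= -1.0
        amp = 2.0 * amp.mean() - amp
    probs = amp**2
    return {r: float(p) for r, p in enumerate(probs)}


def analytic_success(S: int, k: int, r: int) -> float:
    """Closed-form total probability on marked states after r iterations.

    sin^2((2r+1) * theta) with theta = arcsin(sqrt(k/S)).  For k = 0 the
    distribution stays uniform on nothing marked, so the limit is 0.
    """
    if not (0 <= k <= S):
        raise ValueError("need 0 <= k <= S")
    if k == 0:
        return 0.0
    theta = math.asin(math.sqrt(k / S))
    return math.sin((2 * r + 1) * theta) ** 2


def total_variation(p: dict[int, float], q: dict[int, float]) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(r, 0.0) - q.get(r, 0.0)) for r in keys)
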