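"""Truth-table based circuit optimization (OPTIQUE).

In the full search circuit only the first ``k*M`` target qubits are ever
compared against the pattern, yet the shift network touches the whole
``k*N``-bit target register.  The optimizer drops the unused target
qubits and re-synthesizes each retained one directly as a Boolean
function of the index register:

1.  Tabulate the cyclic shift: row ``r`` of the truth table is the
    encoded target rotated left by ``unit * r`` bits.
2.  Keep only the first ``k*M`` columns (the simplified truth table);
    column ``c`` is the bit-vector ``values[r]`` = bit ``c`` of row ``r``.
3.  For each column, run the counting-table subroutine: visit index
    values in ascending order, predict the current circuit's output on
    ``r`` from the parity of the counting-table row, and where the
    prediction disagrees with ``values[r]`` add a multi-controlled-X
    whose controls are the index qubits corresponding to the set bits of
    ``r`` (Rule 1), then propagate a +1 count along the forward pointers
    to every row ``k > r`` with ``bits(r) ⊆ bits(k)`` (Rule 2).

The subroutine is incremental positive-polarity Reed–Muller (ANF)
synthesis: the emitted monomial set equals the Möbius transform of the
column, which is the independent oracle used in the tests.  The
reassembled circuit needs ``log2(N) + 2*k*M`` qubits instead of
``log2(N) + k*N + k*M``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circuit_model import Gate, QuantumCircuit, Qubit, inverse
from .qgsa_builder import (
    QgsaInstance,
    build_comparison,
    build_diffusion,
    build_oracle,
)

__all__ = [
    "ShiftTruthTable",
    "SimplifiedColumn",
    "CountingTable",
    "SynthesizedColumnCircuit",
    "build_truth_table",
    "simplify",
    "synthesize_column",
    "column_gates",
    "assemble_optimized",
    "optimize",
]


@dataclass(frozen=True)
class ShiftTruthTable:
    """Map from index value r to the cyclically shifted target bit string."""

    rows: tuple[str, ...]
    unit: int

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class SimplifiedColumn:
    """One retained target qubit as a bit-vector over index values."""

    qubit_index: int
    values: tuple[int, ...]


@dataclass(frozen=True)
class CountingTable:
    """Final counting-table state of one synthesis run.

    ``counts[r][j-1]`` accumulates, for row ``r`` and popcount column
    ``j``, the monomials of popcount ``j`` added at earlier rows that are
    subsets of ``bits(r)``.  ``pointers[(i, j)]`` lists the forward rows
    ``k > i`` with ``bits(i) ⊆ bits(k)`` that an addition at row ``i``
    increments.  ``row_parities[r]`` records the parity consulted when
    row ``r`` was visited (the predicted circuit output before any
    correction at ``r``).
    """

    counts: tuple[tuple[int, ...], ...]
    pointers: dict
    row_parities: tuple[int, ...]


@dataclass(frozen=True)
class SynthesizedColumnCircuit:
    """A column as constant XOR of AND-monomials over index-value bits.

    ``monomials`` holds frozensets of *bit weights* w (bit w of the index
    value, weight 2^w); each becomes a multi-controlled X from the
    corresponding index qubits onto the target qubit.  ``table`` is the
    counting-table trace for auditing.
    """

    has_constant_x: bool
    monomials: tuple[frozenset[int], ...]
    n_index_bits: int
    table: CountingTable

    def evaluate(self, r: int) -> int:
        out = int(self.has_constant_x)
        for mono in self.monomials:
            if all(r >> w & 1 for w in mono):
                out ^= 1
        return out


def _rotate_left(bits: str, amount: int) -> str:
    amount %= len(bits)
    return bits[amount:] + bits[:amount]


def build_truth_table(encoded_target, shift_unit: int) -> ShiftTruthTable:
    """Row r = encoded target rotated left by shift_unit * r bits."""
    bits = encoded_target if isinstance(encoded_target, str) else encoded_target.bits
    if shift_unit < 1 or len(bits) % shift_unit:
        raise ValueError(
            f"target length {len(bits)} is not a multiple of unit {shift_unit}"
        )
    n_rows = len(bits) // shift_unit
    if n_rows & (n_rows - 1):
        raise ValueError(f"number of addressable positions {n_rows} not a power of two")
    rows = tuple(_rotate_left(bits, shift_unit * r) for r in range(n_rows))
    return ShiftTruthTable(rows=rows, unit=shift_unit)


def simplify(table: ShiftTruthTable, keep: int) -> list[SimplifiedColumn]:
    """Drop unused target qubits: keep the first ``keep`` columns."""
    if not 1 <= keep <= table.width:
        raise ValueError(f"keep must be in 1..{table.width}, got {keep}")
    return [
        SimplifiedColumn(
            qubit_index=c, values=tuple(int(row[c]) for row in table.rows)
        )
        for c in range(keep)
    ]


def synthesize_column(column: SimplifiedColumn) -> SynthesizedColumnCircuit:
    """Counting-table synthesis of one column (see module docstring).

    Deterministic: index values are visited in ascending order and
    monomials are emitted in that order.
    """
    values = column.values
    S = len(values)
    if S < 1 or S & (S - 1):
        raise ValueError(f"column length must be a power of two, got {S}")
    n = S.bit_length() - 1
    has_constant_x = values[0] == 1
    counts = [[0] * max(n, 1) for _ in range(S)]
    pointers = {
        (i, bin(i).count("1")): tuple(
            k for k in range(i + 1, S) if i & k == i
        )
        for i in range(1, S)
    }
    monomials: list[frozenset[int]] = []
    parities = [0] * S
    for r in range(1, S):
        parity = sum(counts[r]) & 1
        parities[r] = parity
        temp = int(values[0]) ^ parity
        if temp != values[r]:
            mono = frozenset(w for w in range(n) if r >> w & 1)
            monomials.append(mono)
            j = len(mono)
            for k in pointers[(r, j)]:
                counts[k][j - 1] += 1
    table = CountingTable(
        counts=tuple(tuple(row) for row in counts),
        pointers=pointers,
        row_parities=tuple(parities),
    )
    return SynthesizedColumnCircuit(
        has_constant_x=has_constant_x,
        monomials=tuple(monomials),
        n_index_bits=n,
        table=table,
    )


def column_gates(
    synth: SynthesizedColumnCircuit, target_qubit: int, n_index: int
) -> list[Gate]:
    """Gates writing one synthesized column onto a target qubit.

    Bit weight w of the index value corresponds to index qubit
    ``n_index - 1 - w`` (qubit 0 is the most significant).  One monomial
    becomes CNOT / Toffoli / MCX by control count; the constant becomes
    a plain X.
    """
    if synth.n_index_bits > n_index:
        raise ValueError("column uses more index bits than the register has")
    tgt = (Qubit("target", target_qubit),)
    gates: list[Gate] = []
    if synth.has_constant_x:
        gates.append(Gate("X", targets=tgt))
    for mono in synth.monomials:
        ctrls = tuple(
            Qubit("index", n_index - 1 - w) for w in sorted(mono, reverse=True)
        )
        if len(ctrls) == 1:
            gates.append(Gate("CNOT", controls=ctrls, targets=tgt))
        elif len(ctrls) == 2:
            gates.append(Gate("TOFFOLI", controls=ctrls, targets=tgt))
        else:
            gates.append(Gate("MCX", controls=ctrls, targets=tgt))
    return gates


def assemble_optimized(
    instance: QgsaInstance,
    columns: list[SynthesizedColumnCircuit],
    diffusion_style: str = "mcz",
    include_measure: bool = True,
) -> QuantumCircuit:
    """Reassemble the reduced circuit from per-column syntheses.

    Registers shrink to (index n, target k*M, pattern k*M).  Each Grover
    iteration computes the shifted target prefix directly from the index
    register (synthesized gates), compares, phase-flips, then uncomputes
    the comparison and the synthesis before the diffusion.
    """
    width = len(instance.pattern.bits)
    if width == 0:
        raise ValueError("empty pattern")
    if len(columns) != width:
        raise ValueError(
            f"need one synthesized column per retained target qubit "
            f"({width}), got {len(columns)}"
        )
    circuit = QuantumCircuit(
        {"index": instance.n_index, "target": width, "pattern": width}
    )
    circuit.extend(
        Gate("H", targets=(Qubit("index", q),)) for q in range(instance.n_index)
    )
    synth_gates: list[Gate] = []
    for c, synth in enumerate(columns):
        synth_gates.extend(column_gates(synth, c, instance.n_index))
    circuit.extend(
        Gate("X", targets=(Qubit("pattern", i),))
        for i, bit in enumerate(instance.pattern.bits)
        if bit == "1"
    )
    compare = build_comparison(instance)
    oracle = build_oracle(instance)
    diffusion = build_diffusion(instance, style=diffusion_style)
    for _ in range(instance.iterations):
        circuit.extend(synth_gates)
        circuit.extend(compare)
        circuit.extend(oracle)
        circuit.extend(inverse(compare))
        circuit.extend(inverse(synth_gates))
        circuit.extend(diffusion)
    if include_measure:
        circuit.extend(
            Gate("MEASURE", targets=(Qubit("index", q),))
            for q in range(instance.n_index)
        )
    return circuit


def optimize(
    instance: QgsaInstance,
    diffusion_style: str = "mcz",
    include_measure: bool = True,
) -> QuantumCircuit:
    """Full optimization pipeline: truth table -> simplify -> synthesize ->
    reassemble.  Qubit count drops to n_index + 2*k*M."""
    table = build_truth_table(instance.target.bits, shift_unit=instance.k)
    columns = simplify(table, keep=len(instance.pattern.bits))
    synthesized = [synthesize_column(col) for col in columns]
    return assemble_optimized(
        instance,
        synthesized,
        diffusion_style=diffusion_style,
        include_measure=include_measure,
    )
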