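"""Gate-list circuits over named qubit registers.

A circuit is an ordered list of :class:`Gate` records over immutable,
named registers (for the search circuits: ``index``, ``target``,
``pattern``).  Resource accounting follows the one-symbol-per-gate
convention: every gate record counts once regardless of arity, so a
CSWAP is one gate and a multi-controlled Z is one gate.

The multi-controlled Z admits an optional control-state (polarity)
pattern over *all* of its qubits, matching the common drawn notation of
open/closed control dots: ``ctrl_state`` of all zeros is the phase flip
on |0...0> used by the Grover diffusion reflection.  MCZ is symmetric in
its qubits, so the controls/target split is purely notational.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

__all__ = [
    "Qubit",
    "Gate",
    "QuantumCircuit",
    "ResourceCount",
    "count_resources",
    "inverse",
    "to_qasm",
    "from_qasm",
    "to_gatelist",
    "from_gatelist",
]


class Qubit(NamedTuple):
    register: str
    index: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.register}[{self.index}]"


# kind -> (n_controls, n_targets); None = one or more
_ARITY = {
    "X": (0, 1),
    "H": (0, 1),
    "MEASURE": (0, 1),
    "CNOT": (1, 1),
    "CZ": (1, 1),
    "CSWAP": (1, 2),
    "TOFFOLI": (2, 1),
    "MCX": (None, 1),
    "MCZ": (None, 1),
}

GATE_KINDS = frozenset(_ARITY)


@dataclass(frozen=True)
class Gate:
    """One circuit operation.

    ``ctrl_state`` (optional, MCZ/MCX only) gives the qubit values that
    activate the gate; default is all ones.  For MCZ it spans all qubits
    (controls then targets) since the gate is qubit-symmetric; for MCX it
    spans the controls.
    """

    kind: str
    controls: tuple[Qubit, ...] = ()
    targets: tuple[Qubit, ...] = ()
    ctrl_state: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in _ARITY:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        object.__setattr__(self, "controls", tuple(self.controls))
        object.__setattr__(self, "targets", tuple(self.targets))
        nc, nt = _ARITY[self.kind]
        if nc is None:
            # MCZ degenerates gracefully to Z (qubit-symmetric); MCX needs a control
            if self.kind == "MCX" and len(self.controls) < 1:
                raise ValueError(f"{self.kind} needs at least one control")
        elif len(self.controls) != nc:
            raise ValueError(f"{self.kind} takes {nc} controls, got {len(self.controls)}")
        if len(self.targets) != nt:
            raise ValueError(f"{self.kind} takes {nt} targets, got {len(self.targets)}")
        qubits = self.controls + self.targets
        if len(set(qubits)) != len(qubits):
            raise ValueError(f"repeated qubit in {self.kind} gate: {qubits}")
        if self.ctrl_state is not None:
            if self.kind not in ("MCZ", "MCX"):
                raise ValueError("ctrl_state is only supported on MCZ/MCX")
            want = len(qubits) if self.kind == "MCZ" else len(self.controls)
            state = tuple(int(b) for b in self.ctrl_state)
            if len(state) != want or set(state) - {0, 1}:
                raise ValueError(f"ctrl_state must be {want} bits of 0/1")
            object.__setattr__(self, "ctrl_state", state)

    @property
    def qubits(self) -> tuple[Qubit, ...]:
        return self.controls + self.targets


class QuantumCircuit:
    """Ordered gate list over named registers (sizes fixed at construction).

    Qubit-to-amplitude mapping: registers in declaration order, qubit 0 of
    a register is the most-significant bit of ket notation (index |100>
    means index qubit 0 is set).
    """

    def __init__(self, registers: dict[str, int] | Sequence[tuple[str, int]]):
        regs = dict(registers)
        for name, size in regs.items():
            if size < 0:
                raise ValueError(f"register {name!r} has negative size")
        self._registers: dict[str, int] = regs
        self._offsets: dict[str, int] = {}
        off = 0
        for name, size in regs.items():
            self._offsets[name] = off
            off += size
        self._n_qubits = off
        self.gates: list[Gate] = []

    @property
    def registers(self) -> dict[str, int]:
        return dict(self._registers)

    @property
    def n_qubits(self) -> int:
        return self._n_qubits

    def global_index(self, qubit: Qubit) -> int:
        try:
            size = self._registers[qubit.register]
        except KeyError:
            raise ValueError(f"no register named {qubit.register!r}") from None
        if not (0 <= qubit.index < size):
            raise ValueError(
                f"qubit {qubit.index} out of range for register "
                f"{qubit.register!r} of size {size}"
            )
        return self._offsets[qubit.register] + qubit.index

    def register_qubits(self, name: str) -> list[Qubit]:
        return [Qubit(name, i) for i in range(self._registers[name])]

    def append(self, gate: Gate) -> "QuantumCircuit":
        for q in gate.qubits:
            self.global_index(q)  # validates
        self.gates.append(gate)
        return self

    def extend(self, gates: Iterable[Gate]) -> "QuantumCircuit":
        for g in gates:
            self.append(g)
        return self

    def copy_empty(self) -> "QuantumCircuit":
        return QuantumCircuit(self._registers)


@dataclass(frozen=True)
class ResourceCount:
    n_qubits: int
    n_gates: int
    gates_by_kind: dict

    def __post_init__(self) -> None:
        assert self.n_gates == sum(self.gates_by_kind.values())


def count_resources(
    circuit: QuantumCircuit, include_measure: bool = False
) -> ResourceCount:
    """Count qubits and gate symbols (each gate record counts once)."""
    by_kind: dict[str, int] = {}
    for g in circuit.gates:
        if g.kind == "MEASURE" and not include_measure:
            continue
        by_kind[g.kind] = by_kind.get(g.kind, 0) + 1
    return ResourceCount(
        n_qubits=circuit.n_qubits,
        n_gates=sum(by_kind.values()),
        gates_by_kind=by_kind,
    )


def inverse(segment: Sequence[Gate]) -> list[Gate]:
    """Adjoint of a measurement-free gate segment.

    Every supported unitary kind is self-inverse (X, H, CNOT, CZ, CSWAP,
    Toffoli, MCX, MCZ), so inversion is just order reversal.
    """
    for g in segment:
        if g.kind == "MEASURE":
            raise ValueError("cannot invert a segment containing MEASURE")
    return list(reversed(segment))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_QASM_NAMES = {
    "X": "x",
    "H": "h",
    "CNOT": "cx",
    "CZ": "cz",
    "CSWAP": "cswap",
    "TOFFOLI": "ccx",
}
_QASM_KINDS = {v: k for k, v in _QASM_NAMES.items()}


def _opaque_name(gate: Gate) -> str:
    base = gate.kind.lower() + str(len(gate.qubits))
    if gate.ctrl_state is not None and set(gate.ctrl_state) != {1}:
        base += "_s" + "".join(str(b) for b in gate.ctrl_state)
    return base


def to_qasm(circuit: QuantumCircuit) -> str:
    """OpenQASM 2.0 text.  MCX/MCZ (and polarity variants) are emitted as
    opaque gate declarations so that re-parsing preserves the gate list."""
    lines = ['OPENQASM 2.0;', 'include "qelib1.inc";']
    opaques: dict[str, int] = {}
    for g in circuit.gates:
        if g.kind in ("MCX", "MCZ"):
            opaques.setdefault(_opaque_name(g), len(g.qubits))
    for name, nq in sorted(opaques.items()):
        args = ", ".join(f"q{i}" for i in range(nq))
        lines.append(f"opaque {name} {args};")
    for reg, size in circuit.registers.items():
        if size:
            lines.append(f"qreg {reg}[{size}];")
    n_meas = sum(1 for g in circuit.gates if g.kind == "MEASURE")
    if n_meas:
        lines.append(f"creg c[{n_meas}];")
    cbit = 0
    for g in circuit.gates:
        qs = ", ".join(str(q) for q in g.qubits)
        if g.kind == "MEASURE":
            lines.append(f"measure {g.targets[0]} -> c[{cbit}];")
            cbit += 1
        elif g.kind in _QASM_NAMES:
            lines.append(f"{_QASM_NAMES[g.kind]} {qs};")
        else:
            lines.append(f"{_opaque_name(g)} {qs};")
    return "\n".join(lines) + "\n"


_QREF = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)\[(\d+)\]")


def _parse_qubits(arg_text: str) -> list[Qubit]:
    return [Qubit(m.group(1), int(m.group(2))) for m in _QREF.finditer(arg_text)]


def from_qasm(text: str) -> QuantumCircuit:
    """Parse the strict OpenQASM 2.0 subset written by :func:`to_qasm`."""
    registers: dict[str, int] = {}
    opaques: dict[str, tuple[str, Optional[tuple[int, ...]]]] = {}
    gates: list[tuple[str, list[Qubit], Optional[tuple[int, ...]]]] = []
    for raw in text.splitlines():
        line = raw.split("//")[0].strip().rstrip(";").strip()
        if not line or line.startswith(("OPENQASM", "include", "creg")):
            continue
        if line.startswith("qreg"):
            m = _QREF.search(line)
            registers[m.group(1)] = int(m.group(2))
            continue
        if line.startswith("opaque"):
            name = line.split()[1]
            m = re.fullmatch(r"(mcx|mcz)(\d+)(?:_s([01]+))?", name)
            if not m:
                raise ValueError(f"unrecognized opaque gate {name!r}")
            state = tuple(int(b) for b in m.group(3)) if m.group(3) else None
            opaques[name] = (m.group(1).upper(), state)
            continue
        if line.startswith("measure"):
            q = _parse_qubits(line.split("->")[0])[0]
            gates.append(("MEASURE", [q], None))
            continue
        name, _, rest = line.partition(" ")
        qs = _parse_qubits(rest)
        if name in _QASM_KINDS:
            gates.append((_QASM_KINDS[name], qs, None))
        elif name in opaques:
            kind, state = opaques[name]
            gates.append((kind, qs, state))
        else:
            raise ValueError(f"unrecognized instruction {name!r}")
    circuit = QuantumCircuit(registers)
    for kind, qs, state in gates:
        nc, nt = _ARITY[kind]
        if nc is None:
            nc = len(qs) - nt
        circuit.append(
            Gate(kind, controls=tuple(qs[:nc]), targets=tuple(qs[nc:]), ctrl_state=state)
        )
    return circuit


def to_gatelist(circuit: QuantumCircuit) -> str:
    """Line-oriented text form: one gate per line, ``KIND controls ; targets``."""
    lines = [
        "# registers: " + " ".join(f"{n}:{s}" for n, s in circuit.registers.items())
    ]
    for g in circuit.gates:
        ctrl = " ".join(str(q) for q in g.controls)
        tgt = " ".join(str(q) for q in g.targets)
        suffix = ""
        if g.ctrl_state is not None:
            suffix = " @" + "".join(str(b) for b in g.ctrl_state)
        lines.append(f"{g.kind} {ctrl} ; {tgt}{suffix}")
    return "\n".join(lines) + "\n"


def from_gatelist(text: str) -> QuantumCircuit:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0]
    if not header.startswith("# registers:"):
        raise ValueError("missing register header line")
    registers = {}
    for tok in header.split(":", 1)[1].split():
        name, size = tok.rsplit(":", 1)
        registers[name] = int(size)
    circuit = QuantumCircuit(registers)
    for ln in lines[1:]:
        state = None
        if "@" in ln:
            ln, state_text = ln.rsplit("@", 1)
            state = tuple(int(b) for b in state_text.strip())
        kind, _, rest = ln.strip().partition(" ")
        ctrl_text, _, tgt_text = rest.partition(";")
        circuit.append(
            Gate(
                kind,
                controls=tuple(_parse_qubits(ctrl_text)),
                targets=tuple(_parse_qubits(tgt_text)),
                ctrl_state=state,
            )
        )
    return circuit
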