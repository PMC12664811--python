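"""I/O, fixtures, reports and the reference experiment suite.

The reference experiments bundled here are the published demonstrations
of the search method: the four single-base searches against the 4-base
target ACGT (simulated densely with both the full and the optimized
circuit), and two long-target runs on the effective backend — a 64-base
target with a 9-base interferon-fragment pattern (1 Grover iteration,
match at position 1) and a 128-base target with pattern ``tgta``
(4 iterations, co-maximal matches at positions 32 and 65).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from Bio import SeqIO

from .circuit_model import ResourceCount, count_resources
from .optique import optimize
from .qgsa_builder import (
    QgsaInstance,
    MatchResult,
    build_full_circuit,
    classical_match,
    match,
)
from .seqcodec import SCHEME_2BIT, SCHEME_3BIT, EncodingScheme
from .simulators import index_marginal, run_dense

__all__ = [
    "EXP_ONE_TARGET",
    "EXP_ONE_PATTERN",
    "EXP_TWO_TARGET",
    "EXP_TWO_PATTERN",
    "FixtureSpec",
    "RunReport",
    "generate_fixture",
    "read_fasta",
    "load_config",
    "render_report",
    "distribution_tsv",
    "run_reference_experiments",
    "SCHEMES",
]

logger = logging.getLogger("qgsa")

SCHEMES: dict[str, EncodingScheme] = {"2bit": SCHEME_2BIT, "3bit": SCHEME_3BIT}

# 64-base target, 9-base pattern, matching at position 1 (1 iteration).
EXP_ONE_TARGET = (
    "ccaaaggtaattctaacctgatgcttctggatgtaaatgttttctaaaaaatcatataaatcta"
)
EXP_ONE_PATTERN = "ccaaaggta"

# 128-base target (printed across a line break in the source; stored
# de-hyphenated), 4-base pattern matching at positions 32 and 65.
EXP_TWO_TARGET = (
    "ccaaaggtaattctaacctgatgcttctggatgtaaatgttttctaaaaaatcatataaatcta"
    "tgtatttgattgtttttgacccaaaccgtttacagagccccgggttctgctgcaccgttgggat"
)
EXP_TWO_PATTERN = "tgta"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic search instance with planted matches."""

    target_length: int
    pattern_length: int
    n_planted: int
    seed: int


def generate_fixture(spec: FixtureSpec) -> tuple[str, str, tuple[int, ...]]:
    """Random ACGT target with non-overlapping planted pattern copies.

    Returns (target, pattern, 1-based planted positions).  Deterministic
    for a given seed.  The background is uniform random, so chance
    occurrences of the pattern besides the planted ones are possible (and
    legitimate matches).
    """
    L, m = spec.target_length, spec.pattern_length
    if m < 1 or L < 1:
        raise ValueError("lengths must be positive")
    if m > L:
        raise ValueError(f"pattern length {m} exceeds target length {L}")
    if spec.n_planted < 1:
        raise ValueError("need at least one planted copy")
    if spec.n_planted * m > L:
        raise ValueError(
            f"cannot place {spec.n_planted} non-overlapping copies of a "
            f"{m}-base pattern in {L} bases"
        )
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    pattern = "".join(rng.choice(bases, size=m))
    target = list(rng.choice(bases, size=L))
    # greedy placement over a shuffled candidate list is deterministic
    candidates = rng.permutation(L - m + 1)
    placed: list[int] = []
    for start in candidates:
        if all(start + m <= p or p + m <= start for p in placed):
            placed.append(int(start))
            if len(placed) == spec.n_planted:
                break
    if len(placed) < spec.n_planted:
        raise ValueError(
            f"could not place {spec.n_planted} non-overlapping copies"
        )
    for start in placed:
        target[start : start + m] = pattern
    return "".join(target), pattern, tuple(sorted(p + 1 for p in placed))


def read_fasta(path, record: int = 1) -> str:
    """Sequence of the selected record (1-based), uppercased, ACGT-only."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if not 1 <= record <= len(records):
        raise ValueError(
            f"record {record} requested but {path} has {len(records)} record(s)"
        )
    seq = str(records[record - 1].seq).upper()
    for pos, sym in enumerate(seq, start=1):
        if sym not in "ACGT":
            raise ValueError(
                f"non-ACGT character {sym!r} at position {pos} of {path}"
            )
    return seq


def load_config(path) -> dict:
    """YAML key/value defaults (scheme, backend, iterations); CLI overrides."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


@dataclass(frozen=True)
class RunReport:
    """One experiment run, rendered to plain text by :func:`render_report`."""

    name: str
    target: str
    pattern: str
    backend: str
    iterations: int
    result: MatchResult
    resources_before: Optional[ResourceCount] = None
    resources_after: Optional[ResourceCount] = None


def distribution_tsv(distribution: dict[int, float]) -> str:
    """Tab-separated (1-based position, probability) lines."""
    lines = ["position\tprobability"]
    for r in sorted(distribution):
        lines.append(f"{r + 1}\t{distribution[r]:.12g}")
    return "\n".join(lines) + "\n"


def render_report(report: RunReport) -> str:
    res = report.result
    total = sum(res.distribution.values())
    lines = [
        f"# {report.name}",
        f"target ({len(report.target)} bases): {report.target}",
        f"pattern ({len(report.pattern)} bases): {report.pattern}",
        f"backend: {report.backend}   iterations: {report.iterations}",
        f"reported positions (1-based): "
        + ", ".join(map(str, res.reported_positions)),
        f"probability at reported positions: "
        + ", ".join(
            f"{res.distribution[p - 1]:.6f}" for p in res.reported_positions
        ),
        f"distribution total: {total:.9f}",
    ]
    if report.resources_before is not None and report.resources_after is not None:
        rb, ra = report.resources_before, report.resources_after
        lines.append(
            f"resources: {rb.n_qubits} qubits / {rb.n_gates} gates unoptimized"
            f" -> {ra.n_qubits} qubits / {ra.n_gates} gates optimized"
        )
    return "\n".join(lines) + "\n"


def run_reference_experiments() -> list[RunReport]:
    """The published demonstration suite (all noiseless simulations)."""
    reports: list[RunReport] = []
    for pat in "ACGT":
        instance = QgsaInstance.from_strings("ACGT", pat, iterations=1)
        full = build_full_circuit(instance)
        reduced = optimize(instance)
        for label, circuit in (("full", full), ("optimized", reduced)):
            logger.info(
                "ACGT/%s %s circuit: %d qubits, %d gates",
                pat,
                label,
                circuit.n_qubits,
                count_resources(circuit, include_measure=True).n_gates,
            )
            dist = index_marginal(run_dense(circuit), circuit)
            result = MatchResult(
                distribution=dist,
                reported_positions=tuple(
                    sorted(
                        r + 1
                        for r, p in dist.items()
                        if p >= max(dist.values()) - 1e-9
                    )
                ),
                iterations_used=1,
                backend="dense",
            )
            reports.append(
                RunReport(
                    name=f"ACGT/{pat} ({label} circuit, dense)",
                    target="ACGT",
                    pattern=pat,
                    backend="dense",
                    iterations=1,
                    result=result,
                    resources_before=count_resources(full, include_measure=True),
                    resources_after=count_resources(reduced, include_measure=True),
                )
            )
    for name, target, pattern, iters in (
        ("Experiment One (64-base target)", EXP_ONE_TARGET, EXP_ONE_PATTERN, 1),
        ("Experiment Two (128-base target)", EXP_TWO_TARGET, EXP_TWO_PATTERN, 4),
    ):
        result = match(target, pattern, iterations=iters, backend="effective")
        logger.info(
            "%s: classical occurrences at %s",
            name,
            sorted(p + 1 for p in classical_match(target, pattern)),
        )
        reports.append(
            RunReport(
                name=name,
                target=target,
                pattern=pattern,
                backend="effective",
                iterations=iters,
                result=result,
            )
        )
    return reports
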