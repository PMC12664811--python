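# qgsa — Grover-search DNA pattern matching with truth-table circuit optimization

`qgsa` builds, optimizes and classically simulates quantum circuits that
locate a known DNA motif (the *pattern*, M bases — e.g. an interferon
gene fragment) inside an unannotated sequence (the *target*, N bases).
It is aimed at people studying quantum acceleration of the seed-lookup
step of BLAST-style sequence annotation: the package gives a complete,
tested, desk-scale implementation of the search circuit, an optimizer
that shrinks it from O(N) to O(M + log N) qubits, and two simulation
backends that reproduce the reference virtual-quantum-computer
experiments exactly.

## The method

Sequences are binary encoded (A=00, C=01, G=10, T=11; optionally 3
bits/base with a terminator `$`=100 that pads targets to a power-of-two
length and blocks wrap-around pseudo-matches). The circuit uses three
registers — index (n = log₂N qubits), target (kN qubits), pattern
(kM qubits) — and runs Grover amplitude amplification over shifts:

* initialization: H on the index register, |φ⟩ = (1/√N)·Σᵣ|r⟩; X gates
  write the encoded target and pattern;
* each iteration: a CSWAP network conditionally rotates the target left
  by k·r bits, kM CNOTs compare the prefix against the pattern, an
  X-conjugated multi-controlled Z flips the phase of exact-match
  branches (the oracle U_f), the comparison and shift are uncomputed,
  and the diffusion D = 2|φ⟩⟨φ|−I reflects the index register;
* after ⌊(π/4)√(N/M)+1⌋ iterations (overridable) the index register is
  measured; the observed shift r reports match position r+1.

The optimizer (`qgsa.optique`) tabulates the cyclic shift, keeps only
the kM target columns the comparison reads, and re-synthesizes each as
an XOR of AND-monomials over the index qubits via a counting-table
procedure (equivalent to positive-polarity Reed–Muller synthesis, and
verified against a brute-force Möbius transform). The rebuilt circuit
needs n + 2kM qubits instead of n + kN + kM and is exactly
distribution-equivalent to the full one.

## Worked example

Search the 4-base target `ACGT` for pattern `T` (dense statevector
simulation of the full 12-qubit circuit, one Grover iteration):

```text
$ qgsa match --target ACGT --pattern T --iterations 1 --backend dense
# match T in 4-base target
target (4 bases): ACGT
pattern (1 bases): T
backend: dense   iterations: 1
reported positions (1-based): 4
probability at reported positions: 1.000000
distribution total: 1.000000000
```

One iteration is exact here: with 1 marked shift among 4,
θ = arcsin(√(1/4)) = π/6 and sin²(3θ) = 1, so the correct position (the
4th) is observed with probability 1. Comparing circuit sizes before and
after optimization:

```text
$ qgsa optimize --target ACGT --pattern A --iterations 1
unoptimized: 12 qubits, 42 gates
optimized:   6 qubits, 22 gates
```

A long-target run on the effective backend (exact reduced dynamics of
the index register, linear cost in N) — pattern `tgta` against a
128-base target in which it occurs twice:

```text
$ qgsa match --target ccaaaggtaattctaacctgatgcttctggatgtaaatgttttctaaaaaatcatataaatctatgtatttgattgtttttgacccaaaccgtttacagagccccgggttctgctgcaccgttgggat --pattern tgta --iterations 4
# match tgta in 128-base target
...
reported positions (1-based): 32, 65
probability at reported positions: 0.408189, 0.408189
distribution total: 1.000000000
```

Four iterations amplify the two true occurrences (positions 32 and 65)
to 0.408 each — together 0.816 = sin²(9·arcsin√(2/128)) — versus
0.0015 for each of the 126 other shifts. Targets and patterns can also
be FASTA paths (`--target seqs.fasta --record 2`), and
`qgsa experiments` runs the whole bundled reference suite.

The same is available as a library:

```python
from qgsa import match
result = match("ACGT", "G", iterations=1, backend="dense")
result.reported_positions   # (3,)
```

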