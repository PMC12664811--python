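# Methods

## Problem and model

The package implements exact pattern location in DNA by Grover amplitude
amplification. A target sequence of N bases (an unannotated genomic
sequence) and a pattern of M bases (a known motif, e.g. an interferon
gene fragment) are binary encoded; a quantum circuit prepares a uniform
superposition over all candidate shift positions r, conditionally
rotates the encoded target by r symbols, marks the shifts whose prefix
equals the pattern with a phase flip, and amplifies the marked
amplitudes. Measuring the index register returns a matching position
with amplified probability. This replaces the seed-lookup step of a
BLAST-style pipeline (finding where a screened word occurs in the
database sequence); word screening and match extension are out of scope.

### Registers and encoding

* **Index register** — n = log2(N) qubits enumerating shifts 0..N−1.
  Qubit 0 is the most significant bit throughout (state |100⟩ means
  index qubit 0 is set), for circuits, simulators and serialization
  alike, so cross-backend comparisons are bit-exact.
* **Target register** — k·N qubits holding the encoded target, k = 2
  (A=00, C=01, G=10, T=11) or k = 3 (codes zero-extended, plus the
  terminator `$` = 100). The source material fixes only the 2-bit codes
  and the terminator code; the 3-bit base codes are zero-extended 2-bit
  codes by our choice.
* **Pattern register** — k·M qubits holding the encoded pattern.

The index register addresses *symbol* positions: a shift moves whole
symbols (k·2^q bits, the legal shift ladder), so the power-of-two length
requirement applies to the symbol count. Targets whose length is not a
power of two are padded with `$` under the 3-bit scheme; the terminator
matches no base, which simultaneously blocks the wrap-around
pseudo-matches that a cyclic shift otherwise produces for shifts past
N − M. Under the plain 2-bit scheme such wrap matches are faithful
circuit behaviour; `classical_match` (the no-wraparound scan) is kept
separate from `circuit_marked_shifts` (the set the oracle actually
phase-flips) so both semantics are explicit and testable.

### One Grover iteration

Each iteration is compute–phase–uncompute–diffuse:

1. controlled cyclic shift (CSWAP network; index qubit of binary weight
   2^w controls rotate-left by k·2^w bits),
2. comparison (k·M CNOTs, target prefix onto pattern register),
3. oracle (X-conjugated multi-controlled Z: phase −1 exactly on
   branches whose pattern register is all zero),
4. inverse comparison and inverse shift,
5. diffusion on the index register, H^n (reflection about |0…0⟩) H^n.

The uncompute step is essential: without it the index register stays
entangled with the shifted targets, the diffusion is not a reflection in
the index subspace, and no amplification occurs (a one-iteration
simulation then returns the uniform distribution). With it, the
non-index registers return to a product state every iteration, which is
also what makes the reduced "effective" simulator exact.

The shift network decomposes each controlled rotation into its
permutation cycles, one CSWAP per transposition — L − gcd(L, d) CSWAPs
for a rotation by d of L wires, the minimum. Layers commute, and the
network's action on every computational-basis index value is tested
against the rotation truth table.

### Iteration count

The default is ⌊(π/4)·√(N/M) + 1⌋ (N addressable positions, M pattern
bases). The bundled reference experiments override it explicitly — 1
iteration for the 4-base demos (where sin²(3·arcsin(1/2)) = 1 exactly)
and for the 64-base run, 4 for the 128-base run — so `iterations` is an
explicit argument everywhere, with `"auto"` meaning the formula.

## Truth-table circuit optimization

Only the first k·M target qubits are ever compared, yet the shift
network permutes all k·N. The optimizer removes the unused qubits and
re-synthesizes each retained qubit directly as a Boolean function of the
index register:

1. **Truth table** — row r is the encoded target rotated left by
   k·r bits.
2. **Simplify** — keep the first k·M columns; column c is a bit vector
   values[r] over index values.
3. **Counting-table synthesis** — visit r = 1 … S−1 ascending. The
   parity of row r of the counting table predicts the current circuit's
   output on input r; where it disagrees with values[r], emit a
   multi-controlled X whose controls are the index qubits of the set
   bits of r, and propagate a +1 along forward pointers to every row
   k > r whose bit set contains that of r (pointer condition read as
   subset inclusion, the only type-coherent reading). The constant term
   values[0] becomes a plain X.

This procedure is incremental positive-polarity Reed–Muller (ANF)
synthesis: processing index values in ascending order visits every
subset of r before r, so the emitted monomials are exactly the non-zero
Möbius-transform coefficients of the column. The tests verify this
against a literal brute-force Möbius transform (computed from the
definition, independently of the counting-table code) on random columns,
and verify functional correctness by simulating the synthesized gates on
every basis input. Monomials are emitted in ascending index order, so
output is deterministic; each column is synthesized independently.

The reassembled circuit uses n + 2·k·M qubits instead of n + k·N + k·M:
per iteration it computes the shifted prefix from the index register
(synthesized gates), compares, phase-flips, uncomputes, and diffuses.
Because column values come from the same rotation that the shift network
implements, optimized and full circuits are exactly distribution-
equivalent, which the tests check to 1e-9 total variation.

## Gate-counting convention

Resource counts follow the drawn-symbol convention: every gate record
counts once regardless of arity (a CSWAP is 1, a multi-controlled Z
is 1); measurement symbols are included when `include_measure=True`.
The diffusion reflection about |0…0⟩ is emitted by default as a single
zero-polarity multi-controlled Z between the Hadamard layers
(`ctrl_state` all zeros, the open-dot drawn notation, and the form the
construction text describes); `diffusion_style="explicit-x"` expands it
into X^n · MCZ · X^n instead. Both are the same unitary including global
phase. Under the default convention the 4-base example counts
12 qubits / 42 gates unoptimized and 6 qubits / 22 gates optimized
(40/20 without measurement symbols).

## Simulators

* **Dense backend** — statevector over all registers, gates applied by
  axis arithmetic on a (2,…,2) array; capped at 24 qubits (256 MiB of
  amplitudes) with an error that points to the effective backend. Norm
  is conserved to 1e-12 per gate (assertable via `check_norm`).
  Measurement is reported as the exact index marginal; seeded shot
  sampling is available separately.
* **Effective backend** — tracks only the S index amplitudes: negate
  marked, reflect about the mean, repeat. Exact for the
  compute–phase–uncompute schedule (see above), and validated three
  ways: against the dense backend on all ≤14-qubit instances, against
  the closed form sin²((2r+1)·arcsin√(k/S)) on a (S, k, r) grid, and
  against the classical scan on the bundled long-target experiments.

## Synthetic fixtures

`generate_fixture` plants non-overlapping copies of a random pattern in
a uniform random ACGT background (seeded, deterministic). It emulates
the exact-occurrence structure the search addresses and nothing else: no
base-composition bias, repeats, indels or sequencing error. Passing the
planted-recovery tests therefore shows correct exact matching at the
tested sizes (targets up to 256 bases), not robustness to approximate
matches, which the method does not attempt.

## Problem sizes

Dense simulations in the tests stay at or below 14 qubits (4-base
targets; all four single-base searches). Long-target runs (64 and 128
bases; fixtures to 256) use the effective backend, where cost is linear
in the number of positions. The full suite runs in well under a minute
on one CPU.

## Documented, not asserted

Asymptotic claims are narrative context only: the search uses
O(√(N/M)) iterations against the O(N) classical scan, the optimizer runs
in O(N) per retained qubit (parallelizable over the 2·k·M columns, and
reusable across patterns for a fixed target), and the optimized space
complexity is O(M + log N) versus O(N + M + log N). The package computes
none of these as measured quantities and models no hardware noise;
real-device behaviour (gate errors, SWAP insertion for device
topologies) is out of scope, as is the depth-optimized fan-out variant
of the shift network, ZX-calculus-based optimization, and the word
screening / match extension steps surrounding seed lookup in a full
alignment pipeline.
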