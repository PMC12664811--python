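"""Truth-table synthesis: ANF-oracle equivalence, counting-table audit,
and optimized-vs-full circuit equivalence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qgsa.circuit_model import Gate, QuantumCircuit, Qubit, count_resources
from qgsa.optique import (
    SimplifiedColumn,
    assemble_optimized,
    build_truth_table,
    column_gates,
    optimize,
    simplify,
    synthesize_column,
)
from qgsa.qgsa_builder import (
    QgsaInstance,
    build_full_circuit,
    circuit_marked_shifts,
)
from qgsa.simulators import (
    index_marginal,
    run_dense,
    run_effective,
    total_variation,
)

# the published cyclic-shift illustration: 1-bit steps over encoded ACGT
SHIFT_TABLE_UNIT1 = {
    0b000: "00011011",
    0b001: "00110110",
    0b010: "01101100",
    0b011: "11011000",
    0b100: "10110001",
    0b101: "01100011",
    0b110: "11000110",
    0b111: "10001101",
}


def anf_brute_force(values):
    """Independent positive-polarity Reed-Muller (Moebius) transform.

    Coefficient of monomial m is the XOR of values over all subsets of m;
    computed literally from the definition, not incrementally.
    """
    S = len(values)
    coeffs = {}
    for m in range(S):
        acc = 0
        for sub in range(S):
            if sub & m == sub:
                acc ^= values[sub]
        if acc:
            coeffs[m] = 1
    constant = 1 if 0 in coeffs else 0
    monomials = {
        frozenset(w for w in range(S.bit_length() - 1) if m >> w & 1)
        for m in coeffs
        if m != 0
    }
    return constant, monomials


class TestTruthTable:
    def test_published_unit1_rows(self):
        table = build_truth_table("00011011", shift_unit=1)
        for r, expected in SHIFT_TABLE_UNIT1.items():
            assert table.rows[r] == expected

    def test_row_zero_unchanged(self):
        table = build_truth_table("00011011", shift_unit=2)
        assert table.rows[0] == "00011011"

    def test_symbol_unit_rows(self):
        table = build_truth_table("00011011", shift_unit=2)
        assert table.rows == ("00011011", "01101100", "10110001", "11000110")

    def test_bad_unit_rejected(self):
        with pytest.raises(ValueError):
            build_truth_table("00011011", shift_unit=3)
        with pytest.raises(ValueError):
            build_truth_table("000110", shift_unit=1)  # 6 rows


class TestSimplify:
    def test_acgt_first_two_columns(self):
        table = build_truth_table("00011011", shift_unit=2)
        cols = simplify(table, keep=2)
        assert cols[0].values == (0, 0, 1, 1)
        assert cols[1].values == (0, 1, 0, 1)

    def test_keep_full_width_reproduces_table(self):
        table = build_truth_table("00011011", shift_unit=2)
        cols = simplify(table, keep=8)
        for r, row in enumerate(table.rows):
            assert "".join(str(c.values[r]) for c in cols) == row

    def test_keep_out_of_range(self):
        table = build_truth_table("00011011", shift_unit=2)
        with pytest.raises(ValueError):
            simplify(table, keep=9)


class TestSynthesizeColumn:
    @pytest.mark.parametrize(
        "values,constant,monomials",
        [
            ((0, 0, 1, 1), 0, {frozenset({1})}),  # high bit (weight 2)
            ((0, 1, 0, 1), 0, {frozenset({0})}),
            ((1, 1, 1, 1), 1, set()),
            ((0, 1, 1, 1), 0, {frozenset({0}), frozenset({1}), frozenset({0, 1})}),
            ((0, 0, 0, 1), 0, {frozenset({0, 1})}),
        ],
    )
    def test_known_forms(self, values, constant, monomials):
        synth = synthesize_column(SimplifiedColumn(0, values))
        assert synth.has_constant_x == bool(constant)
        assert set(synth.monomials) == monomials

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            synthesize_column(SimplifiedColumn(0, (0, 1, 0)))

    def test_monomials_emitted_in_ascending_index_order(self):
        synth = synthesize_column(SimplifiedColumn(0, (0, 1, 1, 1)))
        as_ints = [sum(1 << w for w in m) for m in synth.monomials]
        assert as_ints == sorted(as_ints)

    def test_matches_brute_force_anf_bulk(self):
        rng = np.random.default_rng(2024)
        for length in (4, 8, 16, 32):
            for _ in range(60):
                values = tuple(int(b) for b in rng.integers(0, 2, size=length))
                synth = synthesize_column(SimplifiedColumn(0, values))
                constant, monomials = anf_brute_force(values)
                assert synth.has_constant_x == bool(constant)
                assert set(synth.monomials) == monomials

    @given(
        values=st.lists(st.integers(0, 1), min_size=8, max_size=8).map(tuple)
    )
    def test_matches_brute_force_anf_property(self, values):
        synth = synthesize_column(SimplifiedColumn(0, values))
        constant, monomials = anf_brute_force(list(values))
        assert synth.has_constant_x == bool(constant)
        assert set(synth.monomials) == monomials

    @given(
        values=st.lists(st.integers(0, 1), min_size=16, max_size=16).map(tuple)
    )
    def test_evaluate_reproduces_column(self, values):
        synth = synthesize_column(SimplifiedColumn(0, values))
        assert tuple(synth.evaluate(r) for r in range(16)) == values

    def test_counting_table_parity_audit(self):
        # parity consulted at row r must equal the number of previously
        # added monomials that are subsets of bits(r), mod 2
        rng = np.random.default_rng(7)
        for _ in range(50):
            values = tuple(int(b) for b in rng.integers(0, 2, size=16))
            synth = synthesize_column(SimplifiedColumn(0, values))
            added: list[int] = []
            for r in range(1, 16):
                expect = sum(1 for m in added if m & r == m) & 1
                assert synth.table.row_parities[r] == expect
                mono_int = next(
                    (
                        sum(1 << w for w in m)
                        for m in synth.monomials
                        if sum(1 << w for w in m) == r
                    ),
                    None,
                )
                if mono_int is not None:
                    added.append(mono_int)

    def test_pointers_only_point_forward_to_supersets(self):
        synth = synthesize_column(SimplifiedColumn(0, (0, 1, 1, 0, 1, 0, 0, 1)))
        for (i, _j), ks in synth.table.pointers.items():
            for k in ks:
                assert k > i and i & k == i


class TestColumnGates:
    def test_gate_kinds_by_arity(self):
        synth = synthesize_column(SimplifiedColumn(0, (0, 1, 1, 1)))
        gates = column_gates(synth, target_qubit=0, n_index=2)
        assert [g.kind for g in gates] == ["CNOT", "CNOT", "TOFFOLI"]

    def test_functional_correctness_exhaustive(self):
        # simulate the synthesized gates on |r>|0> for every r, S up to 64
        rng = np.random.default_rng(5)
        for S in (4, 8, 16, 32, 64):
            n = S.bit_length() - 1
            values = tuple(int(b) for b in rng.integers(0, 2, size=S))
            synth = synthesize_column(SimplifiedColumn(0, values))
            gates = column_gates(synth, target_qubit=0, n_index=n)
            for r in range(S):
                c = QuantumCircuit({"index": n, "target": 1})
                for q in range(n):
                    if r >> (n - 1 - q) & 1:
                        c.append(Gate("X", targets=(Qubit("index", q),)))
                c.extend(gates)
                state = run_dense(c)
                basis = int(np.argmax(np.abs(state)))
                assert basis & 1 == values[r], (S, r)


class TestAssembleOptimize:
    def test_acgt_a_six_qubits(self):
        reduced = optimize(QgsaInstance.from_strings("ACGT", "A", iterations=1))
        assert reduced.n_qubits == 6
        assert reduced.registers == {"index": 2, "target": 2, "pattern": 2}

    def test_qubit_arithmetic_on_long_instance(self):
        instance = QgsaInstance.from_strings("ACGT" * 32, "TGTA", iterations=4)
        reduced = optimize(instance)
        assert reduced.n_qubits == 7 + 8 + 8  # log2(128) + 2M + 2M (2-bit code)

    def test_column_count_mismatch_rejected(self):
        instance = QgsaInstance.from_strings("ACGT", "A", iterations=1)
        cols = [synthesize_column(SimplifiedColumn(0, (0, 0, 1, 1)))]
        with pytest.raises(ValueError, match="one synthesized column"):
            assemble_optimized(instance, cols)

    @pytest.mark.parametrize("pattern", ["A", "C", "G", "T"])
    def test_optimized_equals_full_for_all_four_patterns(self, pattern):
        instance = QgsaInstance.from_strings("ACGT", pattern, iterations=1)
        full = build_full_circuit(instance)
        reduced = optimize(instance)
        d_full = index_marginal(run_dense(full), full)
        d_red = index_marginal(run_dense(reduced), reduced)
        assert total_variation(d_full, d_red) < 1e-9
        shift = "ACGT".index(pattern)
        assert d_red[shift] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_optimized_equals_full_random_4base(self, seed):
        rng = np.random.default_rng(seed)
        tgt = "".join(rng.choice(list("ACGT"), size=4))
        pat = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
        r = int(rng.integers(0, 3))
        instance = QgsaInstance.from_strings(tgt, pat, iterations=r)
        full = build_full_circuit(instance)
        reduced = optimize(instance)
        d_full = index_marginal(run_dense(full), full)
        d_red = index_marginal(run_dense(reduced), reduced)
        assert total_variation(d_full, d_red) < 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_optimized_equals_reduced_dynamics_8base(self, seed):
        # the full 8-base circuit is beyond dense reach (19-23 qubits);
        # the effective backend is its exact reduced dynamics and the
        # dense-vs-effective identity is covered on 4-base instances
        rng = np.random.default_rng(1000 + seed)
        tgt = "".join(rng.choice(list("ACGT"), size=8))
        pat = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
        r = int(rng.integers(1, 3))
        instance = QgsaInstance.from_strings(tgt, pat, iterations=r)
        reduced = optimize(instance)
        d_red = index_marginal(run_dense(reduced), reduced)
        eff = run_effective(
            instance.n_positions, circuit_marked_shifts(instance), r
        )
        assert total_variation(d_red, eff) < 1e-9

    def test_resource_reduction_on_fixtures(self):
        for tgt, pat in (
            ("ACGT", "A"),
            ("ACGT", "GT"),
            ("ACGTACGT", "ACG"),
            ("TTCATGCA", "TG"),
        ):
            instance = QgsaInstance.from_strings(tgt, pat, iterations=1)
            full = build_full_circuit(instance)
            reduced = optimize(instance)
            full_rc = count_resources(full, include_measure=True)
            red_rc = count_resources(reduced, include_measure=True)
            assert red_rc.n_gates <= full_rc.n_gates
            assert red_rc.n_qubits < full_rc.n_qubits
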