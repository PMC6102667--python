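"""Prime implicants, two-symbol redescription and canalization measures."""

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from bncana import (
    CapacityError,
    LookupTable,
    StructuralError,
    WILDCARD,
    canalization_summary,
    enumerate_prime_implicants,
    schema_coverage,
    two_symbol_redescription,
)
from bncana.oracles import oracle_permutation_closure, oracle_prime_implicants
from bncana.schemata import WildcardSchema, pattern_str

from conftest import random_lut


def patterns(schemata):
    return {pattern_str(s.pattern) for s in schemata}


class TestPrimeImplicants:
    @pytest.mark.parametrize(
        "outputs,value,expected",
        [
            ((0, 0, 0, 1), 1, {"11"}),          # AND on-set
            ((0, 0, 0, 1), 0, {"0#", "#0"}),    # AND off-set
            ((0, 1, 1, 0), 1, {"01", "10"}),    # XOR
            ((0, 1, 1, 1), 1, {"1#", "#1"}),    # OR
            ((1, 1, 1, 1), 1, {"##"}),          # constant
            ((1, 1, 1, 1), 0, set()),           # empty off-set
        ],
    )
    def test_small_functions(self, outputs, value, expected):
        lut = LookupTable("f", ("a", "b"), outputs)
        assert patterns(enumerate_prime_implicants(lut, value)) == expected

    def test_floral_repressor_on_condition(self, tfl1):
        """A single conjunction of three literals turns the node on."""
        on = enumerate_prime_implicants(tfl1, 1)
        assert patterns(on) == {"#010"}
        assert {s.n_literals for s in on} == {3}

    def test_floral_repressor_off_conditions(self, tfl1):
        """Any one of three single conditions suffices to turn it off."""
        off = enumerate_prime_implicants(tfl1, 0)
        assert patterns(off) == {"#1##", "##0#", "###1"}
        assert [s.n_literals for s in off] == [1, 1, 1]

    def test_cover_completeness_and_maximality_match_oracle(self):
        """Production QM equals the brute-force maximal-pattern search."""
        rng = random.Random(20240917)
        for k in (1, 2, 3, 4):
            for _ in range(200):
                lut = random_lut(rng, k)
                for value in (0, 1):
                    assert enumerate_prime_implicants(lut, value) == (
                        oracle_prime_implicants(lut, value)
                    ), f"k={k} outputs={lut.outputs} value={value}"

    def test_union_of_expansions_is_exactly_the_value_rows(self):
        rng = random.Random(5)
        for _ in range(50):
            lut = random_lut(rng, 3)
            for value in (0, 1):
                rows = set()
                for s in enumerate_prime_implicants(lut, value):
                    rows |= s.expand()
                assert rows == {r for r, o in enumerate(lut.outputs) if o == value}

    def test_constant_node(self):
        lut = LookupTable("c", (), (1,))
        assert patterns(enumerate_prime_implicants(lut, 1)) == {""}
        assert enumerate_prime_implicants(lut, 0) == frozenset()


class TestSchemaCoverage:
    def test_wildcard_expansion(self, tfl1):
        schema = WildcardSchema((WILDCARD, 0, 1, 0), 1)
        rows = schema_coverage(schema, tfl1)
        # LFY=0, EMF1=1, AP1=0 with AP2 free: rows 0010 and 1010
        assert rows == {0b0010, 0b1010}
        assert all(tfl1.outputs[r] == 1 for r in rows)

    def test_full_wildcard_covers_everything(self):
        lut = LookupTable("c", ("a", "b"), (0, 0, 0, 0))
        schema = WildcardSchema((WILDCARD, WILDCARD), 0)
        assert schema_coverage(schema, lut) == {0, 1, 2, 3}

    def test_single_wildcard(self, and2):
        assert schema_coverage(WildcardSchema((0, WILDCARD), 0), and2) == {0, 1}

    def test_length_mismatch_rejected(self, and2):
        with pytest.raises(StructuralError):
            schema_coverage(WildcardSchema((0,), 0), and2)


class TestTwoSymbol:
    def test_xor_on_schemata_merge_into_one_group(self, xor2):
        on = [s for s in two_symbol_redescription(xor2) if s.output == 1]
        assert len(on) == 1
        (schema,) = on
        assert schema.pattern == (0, 1)
        assert schema.groups == frozenset({frozenset({0, 1})})

    def test_and_off_schemata_merge(self, and2):
        off = [s for s in two_symbol_redescription(and2) if s.output == 0]
        assert len(off) == 1
        assert off[0].pattern == (0, WILDCARD)
        assert off[0].groups == frozenset({frozenset({0, 1})})

    def test_identity_node_has_no_groups(self):
        lut = LookupTable("id", ("x",), (0, 1))
        schemata = two_symbol_redescription(lut)
        assert {s.pattern for s in schemata} == {(0,), (1,)}
        assert all(not s.groups for s in schemata)

    def test_every_row_covered_and_closure_holds(self):
        rng = random.Random(99)
        for k in (2, 3, 4):
            for _ in range(40):
                lut = random_lut(rng, k)
                schemata = two_symbol_redescription(lut)
                covered = set()
                for s in schemata:
                    assert oracle_permutation_closure(s, lut), str(s)
                    covered |= {r for r in s.expand()}
                assert covered == set(range(2 ** k))

    def test_deterministic_canonical_order(self):
        rng = random.Random(3)
        lut = random_lut(rng, 3)
        assert two_symbol_redescription(lut) == two_symbol_redescription(lut)

    def test_capacity_guard(self):
        lut = LookupTable("big", tuple(f"i{j}" for j in range(5)), (0,) * 32)
        with pytest.raises(CapacityError, match="4"):
            two_symbol_redescription(lut, k_limit=4)


class TestMeasures:
    def test_parity_has_zero_redundancy(self, xor2):
        s = canalization_summary(xor2)
        assert s.k_r == 0 and s.k_e == 2

    def test_parity3_has_zero_redundancy(self):
        lut = LookupTable.from_function(
            "xor3", ("a", "b", "c"), lambda a, b, c: a ^ b ^ c
        )
        assert canalization_summary(lut).k_r == 0

    def test_constant_node_is_fully_redundant(self):
        lut = LookupTable("c", ("a", "b", "c"), (1,) * 8)
        s = canalization_summary(lut)
        assert s.k_r == 3 and s.k_e == 0
        assert all(r == 1 for r in s.r)

    def test_and_gate_values(self, and2):
        """Hand-enumerated: rows 00/01/10 are covered by one-wildcard schemata;
        row 00 is covered by both off-schemata so per-input averages halve."""
        s = canalization_summary(and2)
        assert s.k_r == Fraction(3, 4)
        assert s.k_e == Fraction(5, 4)
        assert s.r == (Fraction(3, 8), Fraction(3, 8))
        assert s.e == (Fraction(5, 8), Fraction(5, 8))

    def test_majority_is_fully_symmetric(self, majority3):
        assert canalization_summary(majority3).k_s == 3

    def test_fully_redundant_input(self, tfl1):
        """An input the output never depends on has r=1, e=0."""
        s = canalization_summary(tfl1)
        ap2 = s.input_names.index("AP2")
        assert s.r[ap2] == 1 and s.e[ap2] == 0

    def test_mean_norm_recovers_sum_identity(self):
        rng = random.Random(7)
        for _ in range(25):
            lut = random_lut(rng, 3)
            s = canalization_summary(lut, norm="mean")
            assert s.k_r == s.sum_r
            assert s.k_s == s.sum_s
            assert s.k_e == s.k - s.k_r

    def test_zero_in_degree_convention(self):
        s = canalization_summary(LookupTable("c", (), (0,)))
        assert (s.k_r, s.k_e, s.k_s) == (0, 0, 0)

    @given(outputs=st.lists(st.integers(0, 1), min_size=8, max_size=8))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_measure_bounds_hold_for_any_lut(self, outputs):
        lut = LookupTable("f", ("a", "b", "c"), tuple(outputs))
        for norm in ("max", "mean"):
            s = canalization_summary(lut, norm=norm)
            assert 0 <= s.k_r <= s.k and 0 <= s.k_s <= s.k
            assert s.k_e + s.k_r == s.k
            assert all(0 <= x <= 1 for x in s.r + s.s)
            assert all(e == 1 - r for e, r in zip(s.e, s.r))
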