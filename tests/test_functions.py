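"""The 25-function algebra: semantics, totality, exact pushforwards."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epihier import (
    DiscreteDistribution,
    FUNCTION_NAMES,
    FUNCTIONS,
    apply_function,
    function_output_distribution,
    normalize_function_name,
)
from epihier.functions import INT_MAX, INT_MIN

GROUPS = {
    "Basic": {"ADD", "SUB", "MULT", "DIV", "MOD", "MOD2"},
    "Logical": {"GT", "LT", "AND", "OR", "XOR"},
    "Bitwise": {"BITA", "BITO", "BITX"},
    "Unary": {"ABS", "NOT", "FAC", "LEFT", "RIGHT"},
    "Large": {"POW", "LOG", "PER", "CHS"},
    "Miscellaneous": {"MIN", "MAX"},
}


def test_registry_is_bijective_and_grouped():
    assert len(FUNCTIONS) == 25
    assert len(set(FUNCTION_NAMES)) == 25
    for i, name in enumerate(FUNCTION_NAMES):
        assert FUNCTIONS[name].index == i
    for group, members in GROUPS.items():
        assert {n for n, f in FUNCTIONS.items() if f.group == group} == members


@pytest.mark.parametrize(
    "name,a,b,expected",
    [
        ("ADD", 2, 2, 4),
        ("SUB", 3, 5, -2),
        ("MULT", -3, 4, -12),
        ("DIV", 7, 2, 3),
        ("DIV", -7, 2, -3),  # truncation toward zero
        ("DIV", 1, 0, 0),
        ("MOD", 7, 3, 1),
        ("MOD", -7, 3, 2),  # result takes the sign of b
        ("MOD", 7, -3, -2),
        ("MOD", 5, 0, 0),
        ("MOD2", 1, 1, 0),
        ("MOD2", 0, 1, 1),
        ("GT", 2, 1, 1),
        ("GT", 1, 1, 0),
        ("LT", -1, 0, 1),
        ("AND", 2, -3, 1),
        ("AND", 2, 0, 0),
        ("OR", 0, 0, 0),
        ("OR", 0, 5, 1),
        ("XOR", 1, 1, 0),  # arithmetic parity
        ("XOR", 1, 2, 1),
        ("XOR", 2, 2, 0),
        ("BITA", 6, 3, 2),
        ("BITO", 6, 3, 7),
        ("BITX", 1, 2, 3),
        ("ABS", -5, 99, 5),
        ("NOT", 2, 99, -3),  # bitwise complement -(a+1)
        ("FAC", 4, 99, 24),
        ("FAC", -1, 99, 0),
        ("FAC", 13, 99, INT_MAX),  # saturates past 12!
        ("LEFT", 5, -2, 5),
        ("RIGHT", 5, -2, -2),
        ("POW", 2, 10, 1024),
        ("POW", 0, 0, 1),
        ("POW", 2, -1, 0),
        ("POW", -2, 3, -8),
        ("LOG", 8, 99, 3),  # floor(log2 |a|)
        ("LOG", -9, 99, 3),
        ("LOG", 0, 99, 0),
        ("PER", 4, 2, 12),
        ("PER", 2, 3, 0),
        ("CHS", 2, 1, 2),
        ("CHS", 5, 2, 10),
        ("CHS", 1, 2, 0),
        ("MIN", -4, 2, -4),
        ("MAX", -4, 2, 2),
    ],
)
def test_function_semantics(name, a, b, expected):
    assert apply_function(name, a, b) == expected


def test_saturation_bounds_chained_growth():
    assert apply_function("POW", 10, 1000) == INT_MAX
    assert apply_function("POW", -10, 999) == INT_MIN
    assert apply_function("PER", 10**6, 10**6) == INT_MAX
    assert apply_function("CHS", 10**6, 500_000) == INT_MAX
    assert apply_function("MULT", INT_MAX, INT_MAX) == INT_MAX
    assert apply_function("NOT", INT_MIN, 0) == INT_MAX


def test_name_normalization_accepts_symbols_and_case():
    assert normalize_function_name("add") == "ADD"
    assert normalize_function_name("+") == "ADD"
    assert normalize_function_name("^^") == "XOR"
    assert normalize_function_name("^") == "BITX"
    assert normalize_function_name("&&") == "AND"
    assert normalize_function_name("&") == "BITA"
    assert normalize_function_name("!") == "FAC"
    with pytest.raises(KeyError, match="SQRT"):
        normalize_function_name("SQRT")


@settings(max_examples=300, derandomize=True)
@given(
    name=st.sampled_from(FUNCTION_NAMES),
    a=st.integers(-(10**6), 10**6),
    b=st.integers(-(10**6), 10**6),
)
def test_totality_over_large_integers(name, a, b):
    """No function ever raises, and every result is a saturated integer."""
    result = apply_function(name, a, b)
    assert isinstance(result, int)
    assert INT_MIN <= result <= INT_MAX


def _brute_force_pushforward(name, dist_a, dist_b):
    out = {}
    for u, pu in dist_a.items():
        for v, pv in dist_b.items():
            x = apply_function(name, u, v)
            out[x] = out.get(x, 0.0) + pu * pv
    return out


@pytest.mark.parametrize("name", FUNCTION_NAMES)
def test_pushforward_matches_exhaustive_enumeration(name, genotype_dist):
    env = DiscreteDistribution({v: 0.2 for v in (-2, -1, 0, 1, 2)})
    for da, db in [(genotype_dist, genotype_dist), (genotype_dist, env), (env, env)]:
        expected = _brute_force_pushforward(name, da, db)
        result = function_output_distribution(name, da, db)
        assert set(result.support) == {v for v, p in expected.items() if p > 0}
        for v, p in expected.items():
            assert result[v] == pytest.approx(p, abs=1e-12)


def test_mod2_pushforward_is_balanced(genotype_dist):
    out = function_output_distribution("MOD2", genotype_dist, genotype_dist)
    assert out[0] == pytest.approx(0.5, abs=1e-12)
    assert out[1] == pytest.approx(0.5, abs=1e-12)


def test_mod2_conditional_determinism(genotype_dist):
    """For any fixed a, MOD2(a, B) is 50/50 over the genotype distribution;
    for fixed (a, b) it is a point mass — the pure-epistasis mechanism."""
    for a in (0, 1, 2):
        point = DiscreteDistribution({a: 1.0})
        cond = function_output_distribution("MOD2", point, genotype_dist)
        assert cond[0] == pytest.approx(0.5, abs=1e-12)
        assert cond[1] == pytest.approx(0.5, abs=1e-12)
        for b in (0, 1, 2):
            fixed = function_output_distribution(
                "MOD2", point, DiscreteDistribution({b: 1.0})
            )
            assert len(fixed) == 1


def test_add_with_point_mass_is_identity(genotype_dist):
    zero = DiscreteDistribution({0: 1.0})
    assert function_output_distribution("ADD", zero, genotype_dist) == genotype_dist


def test_mult_pushforward_derived_values(genotype_dist):
    out = function_output_distribution("MULT", genotype_dist, genotype_dist)
    assert dict(out.items()) == pytest.approx(
        {0: 0.4375, 1: 0.25, 2: 0.25, 4: 0.0625}, abs=1e-12
    )


def test_chs_matches_math_comb_on_small_values():
    for a in range(0, 13):
        for b in range(0, a + 1):
            assert apply_function("CHS", a, b) == math.comb(a, b)
            assert apply_function("PER", a, b) == math.perm(a, b)
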