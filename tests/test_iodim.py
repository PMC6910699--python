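"""Coefficient maps, elementary symmetric polynomials, Methods 1 and 2."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from identikit import (
    coefficient_fixture,
    elementary_symmetric,
    fixture,
    method1_dimension,
    method2_dimension,
)
from identikit.model_core import random_complex
from identikit.poly import Poly


def brute_force_esym(k, values):
    return sum(np.prod(c) for c in combinations(values, k)) if k else 1


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.integers(0, 5))
def test_elementary_symmetric_against_enumeration(seed, k):
    rg = np.random.default_rng(seed)
    vals = list(rg.normal(size=5))
    assert elementary_symmetric(k, vals) == pytest.approx(brute_force_esym(k, vals))


def test_elementary_symmetric_examples():
    assert elementary_symmetric(1, [1, 2, 3]) == 6
    assert elementary_symmetric(2, [1, 2, 3]) == 11  # 1*2 + 1*3 + 2*3
    assert elementary_symmetric(3, [1, 2, 3]) == 6
    assert elementary_symmetric(0, [5, 5]) == 1
    with pytest.raises(ValueError):
        elementary_symmetric(4, [1, 2, 3])


def test_noleak13_map_exact_value(noleak13_c):
    """Worked benchmark point: c(-1, -2, 5, -1, -3) = (-2, -31, 5, -1, -30)
    in exact integer arithmetic."""
    vals = noleak13_c.evaluate([-1, -2, 5, -1, -3])
    assert vals == [-2, -31, 5, -1, -30]
    assert all(isinstance(v, int) for v in vals)


def test_noleak13_map_exact_rational_point(noleak13_c):
    vals = noleak13_c.evaluate([Fraction(1, 2), 1, 1, 1, 1])
    assert vals[0] == Fraction(9, 2)


def test_linear3_first_coefficient_is_trace(linear3_c):
    """c_1 is the first elementary symmetric polynomial of the negated
    compartment-matrix column sums."""
    names = linear3_c.params
    expected = -(
        Poly.var("k01")
        + Poly.var("k21")
        + Poly.var("k02")
        + Poly.var("k12")
        + Poly.var("k32")
        + Poly.var("k03")
        + Poly.var("k13")
    )
    assert (linear3_c.coeffs[0][0] - expected).is_zero()


def test_fourcomp_map_shape(fourcomp_c):
    assert fourcomp_c.m1 == 10 and fourcomp_c.m2 == 7
    # last coefficient is the trace of the submodel seen from the output
    expected = Poly.var("a22") + Poly.var("a33") + Poly.var("a44")
    assert (fourcomp_c.coeffs[6][0] - expected).is_zero()


def test_unknown_coefficient_fixture():
    with pytest.raises(ValueError, match="unknown"):
        coefficient_fixture("nope_c")


@pytest.mark.parametrize(
    "name,expected",
    [("linear3_c", 2), ("linear3_noleak13_c", 0), ("fourcomp_c", 4), ("identity4_c", 0)],
)
def test_method1_dimension(name, expected, rng):
    ell, report = method1_dimension(coefficient_fixture(name), rng)
    assert ell == expected
    assert report.rank + report.corank == coefficient_fixture(name).m1


def test_method2_linear3_full_table(linear3_model, rng):
    """The order-by-order corank table of the 3-compartment model, with the
    d-sequence 7,7,7,6,5,4,3,2,2 stabilising at 2."""
    table = method2_dimension(linear3_model, rng, force_r=10)
    expected = [
        (0, 13, 9, 2, 7),
        (1, 16, 8, 1, 7),
        (2, 19, 7, 0, 7),
        (3, 22, 6, 0, 6),
        (4, 25, 5, 0, 5),
        (5, 28, 4, 0, 4),
        (6, 31, 3, 0, 3),
        (7, 34, 2, 0, 2),
        (8, 37, 2, 0, 2),
        (9, 40, 2, 0, 2),
        (10, 43, 2, 0, 2),
    ]
    assert table.rows == expected
    assert table.stabilized and table.final_dimension == 2
    assert table.d_sequence[:9] == [7, 7, 7, 6, 5, 4, 3, 2, 2]


def test_method2_threecomp_with_and_without_constraint(rng):
    plain = method2_dimension(fixture("threecomp"), rng)
    assert plain.final_dimension == 0
    assert plain.d_sequence[:6] == [3, 3, 3, 2, 1, 0]
    constrained = method2_dimension(fixture("threecomp", constraints=["x3(0)=0"]), rng)
    assert constrained.final_dimension == 1
    assert constrained.d_sequence[:5] == [3, 3, 2, 1, 1]


def test_method2_hiv(hiv_model, rng):
    table = method2_dimension(hiv_model, rng)
    assert table.final_dimension == 0
    assert table.d_sequence[:8] == [5, 5, 5, 4, 3, 2, 1, 0]
    assert table.stop_r == 7


def test_d_sequence_monotone_nonincreasing(rng):
    for name in ("linear3", "threecomp", "hiv"):
        table = method2_dimension(fixture(name), rng)
        d = table.d_sequence
        assert all(a >= b for a, b in zip(d, d[1:]))
        assert all(v >= 0 for v in d)


def test_methods_agree_on_printed_maps(rng):
    """Method 1 (coefficient-map corank) and Method 2 (jet stabilisation)
    give the same dimension for models with a printed coefficient map."""
    for model_name, map_name in (
        ("linear3", "linear3_c"),
        ("linear3_noleak13", "linear3_noleak13_c"),
    ):
        ell1, _ = method1_dimension(coefficient_fixture(map_name), rng)
        table = method2_dimension(fixture(model_name), rng)
        assert table.final_dimension == ell1


def test_dimension_table_csv_layout(linear3_model, rng):
    table = method2_dimension(linear3_model, rng)
    lines = table.to_csv().strip().splitlines()
    assert lines[0] == "r,N_r,corank0,corank_m1,d_r"
    assert lines[1] == "0,13,9,2,7"


def test_restricted_map_composition(linear3_c):
    """Composing with the bundled affine restriction keeps b(1..5) = (1..7)."""
    from identikit.iodim import example19_affine_restriction, restrict_map

    B, const, reduced = example19_affine_restriction()
    cb = restrict_map(linear3_c, B, const, reduced)
    assert cb.m1 == 5 and cb.m2 == 5
    direct = linear3_c.evaluate([1, 2, 3, 4, 5, 6, 7])
    composed = cb.evaluate([1, 2, 3, 4, 5])
    assert direct == composed
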