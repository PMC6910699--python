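"""Identifiability degree: direct solving, monodromy + trace test, jet-side."""

import copy

import numpy as np
import pytest

from identikit import (
    coefficient_fixture,
    jet_degree,
    load_model,
    method3_degree,
    method4_degree,
    monodromy_loop,
    trace_test,
)
from identikit.degree import UnidentifiableError
from identikit.homotopy import ParametricHomotopy, track
from identikit.model_core import random_complex
from identikit.poly import CompiledSystem, Poly


def test_method3_identity_map(rng):
    assert method3_degree(coefficient_fixture("identity3_c"), rng) == 1


def test_method3_square_map(rng):
    """c(p) = p^2 has exactly the two square roots in each fiber."""
    c = coefficient_fixture("identity1_c")
    c.coeffs = [(Poly.var("p1") ** 2, Poly.const(1))]
    k = method3_degree(c, rng)
    # oracle: direct root count of q^2 = a for generic a
    assert k == 2 == len(np.roots([1, 0, -(2.7 + 1.3j)]))


def test_method3_refuses_unidentifiable(linear3_c, rng):
    with pytest.raises(UnidentifiableError, match="degree undefined"):
        method3_degree(linear3_c, rng)


def test_method3_restricted_benchmark(noleak13_c, rng):
    assert method3_degree(noleak13_c, rng) == 2


def test_explicit_monodromy_loop_endpoint(noleak13_c):
    """The worked loop around the slice point (-2, -31, 5, -1, -30): starting
    from p = (-1, -2, 5, -1, -3), the loop endpoint is the second fiber point
    (5/6, -2, -6, -1, 37/6)."""
    p = np.array([-1, -2, 5, -1, -3], dtype=complex)
    cp = np.array([complex(v) for v in noleak13_c.evaluate(p)])
    direction = np.array([0, -15, 5, 0, 35], dtype=complex)
    svar = "_s"
    eqs = [
        num - Poly.const(v) - Poly.var(svar) * complex(d)
        for (num, _), v, d in zip(noleak13_c.coeffs, cp, direction)
    ]
    system = CompiledSystem(eqs, noleak13_c.params + [svar])

    def path(t):
        phase = np.exp(2j * np.pi * (1 - t))
        return np.array([1 - phase]), np.array([2j * np.pi * phase])

    res = track(ParametricHomotopy(system, 5, path), p)
    assert res.ok
    expected = np.array([5 / 6, -2, -6, -1, 37 / 6])
    assert np.max(np.abs(res.endpoint - expected)) < 1e-6


def test_method4_benchmark_certified(noleak13_c, rng):
    k, witness = method4_degree(noleak13_c, rng)
    assert k == 2
    assert witness.certified
    assert len(witness.points) == 2 and witness.deg_X == 1
    assert len(witness.points) == witness.k * witness.deg_X


def test_method4_identity(rng):
    k, witness = method4_degree(coefficient_fixture("identity4_c"), rng)
    assert k == 1 and witness.certified


def test_constant_loop_finds_nothing(noleak13_c, rng):
    _, witness = method4_degree(noleak13_c, rng, run_trace=False)
    before = len(witness.points)
    new = monodromy_loop(witness, np.zeros(5, dtype=complex))
    assert new == []
    assert len(witness.points) == before


def test_complete_witness_stable_under_loops(noleak13_c, rng):
    """Once both fiber points are known, further random loops add nothing."""
    _, witness = method4_degree(noleak13_c, rng, run_trace=False)
    assert len(witness.points) == 2
    for _ in range(10):
        new = monodromy_loop(witness, random_complex(rng, 5))
        assert new == []


def test_methods_three_and_four_agree(noleak13_c, rng):
    assert method3_degree(noleak13_c, rng) == method4_degree(noleak13_c, rng)[0]


def test_trace_test_single_point_line(rng):
    """A witness of a straight line (one point) passes: the centroid of one
    point moves affine-linearly with the slice."""
    _, witness = method4_degree(coefficient_fixture("identity2_c"), rng, run_trace=False)
    assert len(witness.points) == 1
    verdict, bidegree = trace_test(witness, rng)
    assert verdict is True
    assert bidegree == (1, 1)


def test_trace_test_detects_missing_point(noleak13_c, rng):
    _, witness = method4_degree(noleak13_c, rng, run_trace=False)
    assert len(witness.points) == 2
    verdict, bidegree = trace_test(witness, rng)
    assert verdict is True and bidegree == (5, 2)
    broken = copy.deepcopy(witness)
    broken.points = broken.points[:1]
    verdict, bidegree = trace_test(broken, rng)
    assert verdict is False


def test_output_line_bidegree_certifies_enumeration():
    """The jet solution curve of the HIV-type model over the benchmark
    output line has bidegree (60, 12) in (p5, output); the trace over the
    factor coordinates is affine-linear for the complete 72-point set and
    breaks when a point is removed."""
    from identikit import fixture
    from identikit.degree import multihomogeneous_trace_test, output_line_bidegree
    from identikit.homotopy import PathSettings

    rng = np.random.default_rng(0)
    report = output_line_bidegree(
        fixture("hiv"),
        7,
        [0.5, -0.03, -0.15, -0.2, -0.2, -0.17, -0.16, -0.15],
        [1.0, 4.0, 3.0, -2.0, -1.0, -3.0, 3.0, 4.0],
        3 * Poly.var("p5") - 4,
        ([3.0, 4.0, 5.0, 1.0, 1.0, -4.0, 4.0, -1.0], -0.42),
        rng,
    )
    assert report["bidegree"] == (60, 12)
    assert report["trace_pass"] is True
    param_factor, h_y = report["factors"]
    dropped = (report["output_side_points"] + report["param_side_points"])[1:]
    verdict, _ = multihomogeneous_trace_test(
        report["curve_equations"],
        report["curve_variables"],
        param_factor,
        h_y,
        dropped,
        PathSettings(divergence_bound=1e13),
        trace_coords=report["trace_coords"],
    )
    assert verdict is False


def _one_state_model(rhs):
    return load_model(
        {
            "states": ["x"],
            "params": ["p"],
            "outputs": ["y"],
            "odes": {"x": rhs},
            "output_exprs": {"y": "x"},
        }
    )


def test_jet_degree_linear_decay(rng):
    """x' = -p x, y = x: p = -y1/y0 is globally determined, k = 1."""
    res = jet_degree(_one_state_model("-p*x"), 2, rng)
    assert res.k == 1
    assert res.census == [1]


def test_jet_degree_sign_ambiguity(rng):
    """x' = -p^2 x, y = x: the two square roots of -y1/y0 share the output,
    so k = 2 (oracle: direct root solving of p^2 = -y1/y0)."""
    res = jet_degree(_one_state_model("-p^2*x"), 2, rng)
    assert res.k == 2
    seed_group = next(g for g in res.clusters if 0 in g)
    vals = [res.solutions[i][0] for i in seed_group]
    assert len(vals) == 2
    assert vals[0] + vals[1] == pytest.approx(0, abs=1e-6 * (1 + abs(vals[0])))
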