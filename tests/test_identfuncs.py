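"""Fiber sampling, interpolation of identifiable functions, integer recovery,
global classification, independence counting."""

import numpy as np
import pytest

from identikit import (
    all_components,
    classify_global,
    component_partition,
    identifiable_subspace,
    independence_count,
    integer_recovery,
    monomial_basis,
    sample_fiber,
    sample_fiber_jets,
)
from identikit.identfuncs import (
    affine_image_slice,
    constraint_rows,
    format_poly,
    integer_recovery_from_rows,
    staged_search,
)
from identikit.iodim import example19_affine_restriction
from identikit.model_core import fixture, random_complex
from identikit.poly import Poly

P = np.array([1, 2, 3, 4, 5, 6, 7], dtype=complex)


@pytest.fixture(scope="module")
def linear3_fiber_points():
    from identikit import coefficient_fixture

    rng = np.random.default_rng(11)
    c = coefficient_fixture("linear3_c")
    B, const, _ = example19_affine_restriction()
    return c, all_components(c, B, const, [1, 2, 3, 4, 5], rng)


def test_monomial_basis_counts():
    assert len(monomial_basis([f"k{i}" for i in range(7)], 1)) == 7
    assert len(monomial_basis(["p1", "p2"], 2)) == 5
    # C(12, 2) - 1 = 65 nonconstant monomials of degree <= 2 in 10 variables
    assert len(monomial_basis([f"a{i}" for i in range(10)], 2)) == 65
    with pytest.raises(ValueError):
        monomial_basis(["p"], 0)


def test_monomial_basis_subset():
    b = monomial_basis(["p1", "p2", "p3"], 2, subset=["p1", "p2"])
    assert all(t.variables() <= {"p1", "p2"} for t in b.terms)


def test_sample_fiber_defining_property(linear3_c, rng):
    """Every sampled point stays on the fiber: c(q) = c(p) to 1e-8, and for
    this map every single parameter moves (each alone is unidentifiable)."""
    p = random_complex(rng, 7)
    s = sample_fiber(linear3_c, p, 3, rng, dimension=2)
    base_vals = np.array([complex(v) for v in linear3_c.evaluate(p)])
    for q in s.component_points:
        vals = np.array([complex(v) for v in linear3_c.evaluate(q)])
        assert np.max(np.abs(vals - base_vals)) < 1e-8 * (1 + np.max(np.abs(base_vals)))
        assert np.min(np.abs(q - p)) > 1e-3  # every coordinate changed


def test_sample_fiber_requires_positive_dimension(noleak13_c, rng):
    with pytest.raises(ValueError, match="finite"):
        sample_fiber(noleak13_c, random_complex(rng, 5), 1, rng, dimension=0)


def test_all_components_eight_points(linear3_fiber_points):
    """The affine restriction of the 3-compartment map yields the base point
    plus seven published fiber points over p = (1,...,7)."""
    _, pts = linear3_fiber_points
    assert len(pts) == 8
    np.testing.assert_allclose(pts[0], P, atol=1e-8)
    published = np.array(
        [
            [9.2814, -10.3208, 10.7201, -10.52, -2.7201, -2.2814, 33.8409],
            [108.0762, -66.9431, 13.0118, -0.23744, -0.0118, -101.0762, 75.1805],
            [2.4938, 0.3612, 4.3645, 5.326, 8.6355, 4.5062, 2.3128],
            [52.0709, -31.4763, 8.1035, -0.5325, -0.1035, -45.0709, 45.0087],
            [8.6814, -13.22, 14.5081, -14.2737, -1.5081, -1.6814, 35.4937],
            [-9.615, 5.8203, 5.6325, 1.4445, 7.3675, 16.615, 0.7352],
            [-13.625, 9.5193, 3.6057, 1.1636, 4.3943, 20.625, 2.317],
        ]
    )
    for row in published:
        err = min(np.max(np.abs(q - row)) for q in pts)
        assert err < 1e-3


def test_all_components_identifiable_map(rng):
    from identikit import coefficient_fixture

    c = coefficient_fixture("identity3_c")
    B = np.eye(3).tolist()
    pts = all_components(c, B, [0, 0, 0], [1.0, 2.0, 3.0], rng)
    assert len(pts) == 1


def test_identifiable_subspace_dimension_three(linear3_c, rng):
    """Five sample pairs cut the 7-dimensional linear test space down to a
    3-dimensional identifiable subspace; the first four pairs are each
    informative and the fifth is redundant."""
    basis = monomial_basis(linear3_c.params, 1)
    samples = [
        sample_fiber(linear3_c, random_complex(rng, 7), 1, rng, dimension=2)
        for _ in range(5)
    ]
    iset = identifiable_subspace(basis, samples, linear3_c.params)
    assert iset.dimension == 3
    assert iset.nullspace_dim_history[:5] == [6, 5, 4, 3, 3]
    assert sorted(iset.pretty()) == [
        "k01 + k21",
        "k02 + k12 + k32",
        "k03 + k13",
    ]


def test_identifiable_subspace_requires_pairs(linear3_c):
    basis = monomial_basis(linear3_c.params, 1)
    with pytest.raises(ValueError):
        identifiable_subspace(basis, [], linear3_c.params)


def test_integer_recovery_exact_row():
    """A constraint row that is already integer is recovered exactly."""
    rows = np.array([[1.0, -1.0, 0.0], [0.0, 0.0, 0.0]])
    out = integer_recovery_from_rows(rows)
    assert out is not None and len(out) == 2
    for vec in out:
        assert np.abs(np.array([1.0, -1.0, 0.0]) @ vec) < 1e-12


def test_integer_recovery_linear3(linear3_c, rng):
    basis = monomial_basis(linear3_c.params, 1)
    samples = [
        sample_fiber(linear3_c, random_complex(rng, 7), 1, rng, dimension=2)
        for _ in range(5)
    ]
    vecs = integer_recovery(samples, basis, linear3_c.params)
    got = set()
    for vec in vecs:
        combo = sum((v * t for v, t in zip(vec, basis.terms)), Poly())
        got.add(format_poly(combo))
    assert got == {"k01 + k21", "k03 + k13", "k02 + k12 + k32"}


def test_classify_global_published_fiber(linear3_fiber_points):
    """k01 + k21 takes the value 7 on all eight fiber points; the other two
    linear combinations are only locally identifiable, but their sum is
    global."""
    c, pts = linear3_fiber_points
    v = {n: Poly.var(n) for n in c.params}
    funcs = [
        v["k01"] + v["k21"],
        v["k03"] + v["k13"],
        v["k02"] + v["k12"] + v["k32"],
    ]
    labels, combos = classify_global(funcs, pts, c.params)
    assert labels == ["globally identifiable", "identifiable", "identifiable"]
    vals = [complex((funcs[0].eval(dict(zip(c.params, q))))) for q in pts]
    assert np.max(np.abs(np.array(vals) - 7)) < 1e-6
    assert "k02 + k03 + k12 + k13 + k32" in {format_poly(g) for g in combos}


def test_classify_global_reference_cluster(hiv_reference_table):
    """On the 4-point output cluster of the jet-side benchmark: p2, p3 and
    p4 + p5 are globally identifiable while p4 and p5 are not."""
    cluster = hiv_reference_table[:4, :5]
    params = [f"p{i + 1}" for i in range(5)]
    v = {n: Poly.var(n) for n in params}
    funcs = [v["p2"], v["p3"], v["p4"] + v["p5"], v["p4"], v["p5"]]
    labels, _ = classify_global(funcs, list(cluster), params, tol=1e-3)
    assert labels[:3] == ["globally identifiable"] * 3
    assert labels[3] == "identifiable" and labels[4] == "identifiable"


def test_independence_count_examples(rng):
    p1 = Poly.var("p1")
    assert independence_count([p1, p1**2], ["p1", "p2"], rng) == 1
    # the three recovered linear combinations have independent gradients
    v = {n: Poly.var(n) for n in ["k01", "k02", "k03", "k12", "k13", "k21", "k32"]}
    funcs = [v["k01"] + v["k21"], v["k03"] + v["k13"], v["k02"] + v["k12"] + v["k32"]]
    assert independence_count(funcs, list(v), rng) == 3
    explicit = np.array(
        [
            [1, 0, 0, 0, 0, 1, 0],
            [0, 0, 1, 0, 1, 0, 0],
            [0, 1, 0, 1, 0, 0, 1],
        ]
    )
    assert np.linalg.matrix_rank(explicit) == 3


def test_staged_search_recovers_published_functions(fourcomp_c):
    """Staged degree-by-degree search on the 4-compartment map recovers the
    six published generators."""
    rng = np.random.default_rng(3)
    res = staged_search(fourcomp_c, rng)
    names = [format_poly(f) for f in res.functions]
    assert names == [
        "a11",
        "a22",
        "a33 + a44",
        "a12*a21",
        "a33*a44 - a34*a43",
        "a23*a34*a42",
    ]
    assert res.independence == 6 == res.rank_target


def test_staged_search_functions_constant_on_fresh_samples(fourcomp_c):
    """Recovered identifiable functions stay constant on freshly sampled
    fiber points (the membership criterion checked directly)."""
    rng = np.random.default_rng(4)
    res = staged_search(fourcomp_c, rng, pairs_per_stage=12, base_points=2)
    p = random_complex(rng, 10)
    fresh = sample_fiber(fourcomp_c, p, 5, rng, dimension=4)
    env_p = dict(zip(fourcomp_c.params, p))
    for f in res.functions:
        ref = complex(f.to_numeric().eval(env_p))
        for q in fresh.component_points:
            val = complex(f.to_numeric().eval(dict(zip(fourcomp_c.params, q))))
            assert abs(val - ref) < 1e-6 * (1 + abs(ref))


def test_independence_never_exceeds_rank(fourcomp_c):
    rng = np.random.default_rng(5)
    res = staged_search(fourcomp_c, rng, pairs_per_stage=12, base_points=2)
    assert res.independence <= res.rank_target


def test_jet_side_sampling_matches_map_side(linear3_c):
    """Sampling the fiber on the jet system (input/output jets frozen) and
    on the coefficient map visit the same surface: the three identifiable
    combinations take identical values."""
    rng = np.random.default_rng(6)
    m = fixture("linear3")
    s = sample_fiber_jets(m, 7, P, rng, 2, dimension=2)
    combos = np.array([[1, 0, 0, 0, 0, 1, 0], [0, 0, 1, 0, 1, 0, 0], [0, 1, 0, 1, 0, 0, 1]])
    base = combos @ P
    for q in s.component_points:
        np.testing.assert_allclose(combos @ q, base, atol=1e-6)


def test_mapk_mixed_identifiable_parameters():
    """The 32-parameter mixed-output MAPK model has one-dimensional fiber
    components (each a line), and exactly the 16 unscaled rate parameters
    are identifiable: no nonconstant linear combination of the remaining 16
    parameters is constant across fibers."""
    rng = np.random.default_rng(8)
    m = fixture("mapk_mixed")
    pairs = []
    for _ in range(18):
        p0 = random_complex(rng, 32)
        s = sample_fiber_jets(m, 10, p0, rng, 2, dimension=1)
        rows = constraint_rows(monomial_basis(m.params, 1), s.pairs, m.params)
        sv = np.linalg.svd(rows / np.max(np.abs(rows)), compute_uv=False)
        assert int(np.sum(sv > 1e-6 * sv[0])) == 1  # component is a line
        pairs.extend(s.pairs)
    rows = constraint_rows(monomial_basis(m.params, 1), pairs, m.params)
    vecs = integer_recovery_from_rows(rows, tol=1e-6)
    assert vecs is not None and len(vecs) == 16
    singles = set()
    for vec in vecs:
        support = [m.params[i] for i, v in enumerate(vec) if v != 0]
        assert len(support) == 1  # each generator is a single parameter
        singles.add(support[0])
    assert singles == {
        "b00", "b01", "b10", "c0001", "c0010", "c0011", "c0111", "c1011",
        "be01", "be10", "be11", "g0100", "g1000", "g1100", "g1101", "g1110",
    }


def test_component_partition_single_group(linear3_fiber_points):
    """Points connected by slice-loop monodromy merge; the eight fiber
    points of the restricted 3-compartment map lie on a common slice."""
    c, pts = linear3_fiber_points
    rng = np.random.default_rng(7)
    B, const, _ = example19_affine_restriction()
    sl = affine_image_slice(B, const)
    assert max(sl.residual(q) for q in pts) < 1e-6
    part = component_partition(
        c, pts[0], pts, rng, dimension=2, slice_matrix=sl.coefficient_matrix
    )
    flat = sorted(i for g in part for i in g)
    assert flat == list(range(8))
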