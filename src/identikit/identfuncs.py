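"""Identifiable functions of parameters via fiber sampling and interpolation.

For an unidentifiable model the coefficient map c has positive-dimensional
generic fibers; a function f of the parameters is *identifiable* when it is
constant on irreducible components of generic fibers, and *globally*
identifiable when it takes the same value on all components.  Sampling
points q on the component V_p through a generic p (by moving random linear
slices, Eq-style slice homotopies) turns the search for identifiable
functions inside a finite-dimensional space span{f_1, ..., f_j} into linear
algebra: every sample pair imposes the row constraint

    [f_1(q) - f_1(p), ..., f_j(q) - f_j(p)] . a = 0,

and the null space of the stacked rows is the identifiable subspace.
Integer-coefficient generators are recovered by rationalising a reduced
null-space basis and verifying against fresh samples; a staged search over
monomials of rising degree, keeping only generators that are algebraically
independent of those already found, reproduces the practitioner's workflow
of building a transcendence basis of low-degree identifiable functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Sequence

import numpy as np

from .homotopy import (
    LinearSlice,
    PathSettings,
    random_slice_through,
    slice_move_homotopy,
    track,
)
from .iodim import CoefficientMap, method1_dimension, restrict_map
from .model_core import random_complex
from .numerics import numeric_corank
from .poly import CompiledSystem, Poly

RECOVERY_HEIGHT_BOUND = 10**6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FiberSample:
    """Sampled points of the fiber of c through a base point p."""

    source: str
    base_point: np.ndarray
    component_points: list[np.ndarray] = field(default_factory=list)
    all_components: dict[int, list[np.ndarray]] | None = None

    @property
    def pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.base_point, q) for q in self.component_points]


@dataclass
class FunctionBasis:
    """A finite-dimensional test space of functions span{f_1, ..., f_j}."""

    terms: list[Poly]
    degree_bound: int
    generation_rule: str = "monomials"

    def __len__(self) -> int:
        return len(self.terms)

    def evaluate(self, point: Sequence[complex], params: Sequence[str]) -> np.ndarray:
        env = dict(zip(params, np.asarray(point, dtype=complex)))
        return np.array([complex(t.to_numeric().eval(env)) for t in self.terms])


@dataclass
class IdentifiableSet:
    """Recovered identifiable functions over a basis, with labels."""

    params: list[str]
    basis: FunctionBasis
    coefficients: list[np.ndarray] = field(default_factory=list)  # one vector per function
    labels: list[str] = field(default_factory=list)  # identifiable | globally identifiable
    independence_count: int | None = None
    nullspace_dim_history: list[int] = field(default_factory=list)
    global_combinations: list[Poly] = field(default_factory=list)

    @property
    def functions(self) -> list[Poly]:
        out = []
        for a in self.coefficients:
            acc = Poly()
            for coeff, term in zip(a, self.basis.terms):
                if coeff != 0:
                    acc = acc + coeff * term
            out.append(acc)
        return out

    @property
    def dimension(self) -> int:
        return len(self.coefficients)

    def pretty(self) -> list[str]:
        return [format_poly(f) for f in self.functions]

    def to_json_dict(self) -> dict:
        return {
            "functions": self.pretty(),
            "labels": list(self.labels),
            "independence_count": self.independence_count,
            "dimension": self.dimension,
            "globally_identifiable_combinations": [
                format_poly(g) for g in self.global_combinations
            ],
        }


def format_poly(p: Poly) -> str:
    if p.is_zero():
        return "0"
    bits = []
    for mono, c in sorted(p.terms.items(), key=lambda kv: (sum(e for _, e in kv[0]), kv[0])):
        mono_s = "*".join(f"{v}^{e}" if e > 1 else v for v, e in mono)
        c = _tidy_coeff(c)
        if mono_s == "":
            term = f"{c}"
        elif c == 1:
            term = mono_s
        elif c == -1:
            term = f"-{mono_s}"
        else:
            term = f"{c}*{mono_s}"
        bits.append(term)
    out = bits[0]
    for term in bits[1:]:
        out += f" - {term[1:]}" if term.startswith("-") else f" + {term}"
    return out


def _tidy_coeff(c):
    if isinstance(c, complex):
        if abs(c.imag) < 1e-12:
            c = c.real
        else:
            return c
    if isinstance(c, float) and abs(c - round(c)) < 1e-9:
        return int(round(c))
    if isinstance(c, Fraction) and c.denominator == 1:
        return int(c)
    return c


# ---------------------------------------------------------------------------
# fiber sampling
# ---------------------------------------------------------------------------


def _randomized_fiber_equations(
    c: CoefficientMap, value: np.ndarray, d: int, rng: np.random.Generator
) -> list[Poly]:
    """Square-up: generically combine the m2 fiber equations into m1 - d rows."""
    eqs = c.fiber_equations(value)
    need = c.m1 - d
    if len(eqs) == need:
        return eqs
    if len(eqs) < need:
        raise ValueError("fiber equations cannot cut the expected codimension")
    R = random_complex(rng, need * len(eqs)).reshape(need, len(eqs))
    return [sum((coeff * eq for coeff, eq in zip(row, eqs)), Poly()) for row in R]


def sample_fiber(
    c: CoefficientMap,
    p: Sequence[complex],
    n: int,
    rng: np.random.Generator,
    *,
    dimension: int | None = None,
    settings: PathSettings | None = None,
    max_retries: int = 4,
) -> FiberSample:
    """Sample n generic points of the component V_p of the fiber through p.

    A random slice of codimension d (the fiber dimension) through p is moved
    to fresh random slices by homotopy continuation; every endpoint stays on
    V_p by continuity.
    """
    p = np.asarray(p, dtype=complex)
    d = dimension if dimension is not None else method1_dimension(c, rng)[0]
    if d < 1:
        raise ValueError("fiber is finite (d = 0); use all_components instead")
    value = np.array([complex(v) for v in c.evaluate(p)])
    eqs = _randomized_fiber_equations(c, value, d, rng)
    full = CompiledSystem(c.fiber_equations(value), c.params)
    sample = FiberSample(source=c.name, base_point=p)
    scale = 1.0 + float(np.linalg.norm(p))
    while len(sample.component_points) < n:
        got = None
        for _ in range(max_retries):
            slice_from = random_slice_through(p, d, rng)
            slice_to = LinearSlice(
                slice_from.coefficient_matrix,
                slice_from.constants + scale * random_complex(rng, d),
            )
            h = slice_move_homotopy(eqs, c.params, slice_from, slice_to)
            res = track(h, p, settings)
            if not res.ok:
                continue
            q = res.endpoint
            resid = np.max(np.abs(full.values(q))) / max(1.0, np.linalg.norm(q))
            if resid < 1e-8:
                got = q
                break
        if got is None:
            raise ArithmeticError("fiber sampling failed repeatedly; component may be singular")
        sample.component_points.append(got)
    return sample


def move_on_fiber(
    c: CoefficientMap,
    p: Sequence[complex],
    slice_from: LinearSlice,
    slice_to: LinearSlice,
    rng: np.random.Generator,
    *,
    dimension: int | None = None,
    settings: PathSettings | None = None,
) -> np.ndarray:
    """Track p along the fiber of c from one explicit slice to another."""
    p = np.asarray(p, dtype=complex)
    d = dimension if dimension is not None else method1_dimension(c, rng)[0]
    value = np.array([complex(v) for v in c.evaluate(p)])
    eqs = _randomized_fiber_equations(c, value, d, rng)
    h = slice_move_homotopy(eqs, c.params, slice_from, slice_to)
    res = track(h, p, settings)
    if not res.ok:
        raise ArithmeticError(f"slice move failed ({res.status})")
    return res.endpoint


def _normalize_equation(eq: Poly, env: dict[str, complex]) -> Poly:
    """Scale an equation so its largest term magnitude at env is about one."""
    num = eq.to_numeric()
    scale = 0.0
    for mono, coeff in num.terms.items():
        mag = abs(complex(coeff))
        for v, e in mono:
            mag *= abs(env[v]) ** e
        scale = max(scale, mag)
    if scale <= 0:
        return num
    return (1.0 / scale) * num


def sample_fiber_jets(
    model,
    r: int,
    base_params: Sequence[complex],
    rng: np.random.Generator,
    n: int,
    *,
    dimension: int | None = None,
    slice_pair: tuple[LinearSlice, LinearSlice] | None = None,
    settings: PathSettings | None = None,
) -> FiberSample:
    """Sample the parameter fiber directly on the jet system F_r.

    A generic point on F_r = 0 is seeded at the given parameters, the input
    and output jets are frozen at their seeded values, and random linear
    slices in the parameter coordinates are moved by homotopy while the
    state jets ride along.  Returns the parameter parts of the endpoints;
    ``slice_pair`` substitutes explicit source/target slices (given on the
    parameter coordinates) for the random ones.

    High-order jets legitimately reach large magnitudes (they scale like
    eigenvalue^order), so the default divergence bound is raised here.
    """
    from dataclasses import replace as _replace

    from .model_core import seed_point as _seed_point, truncate as _truncate

    if settings is None:
        settings = PathSettings(divergence_bound=1e13)
    elif settings.divergence_bound < 1e13:
        settings = _replace(settings, divergence_bound=1e13)

    jetsys = _truncate(model, r)
    seed = _seed_point(jetsys, rng, params=base_params)
    z_names = jetsys.free_variables
    n_z = len(z_names)
    fixed = {name: seed.assignment[name] for name in jetsys.held_fixed}
    eqs = [eq.subs(fixed) for eq in jetsys.equations]
    z0 = seed.vector(z_names)
    full = CompiledSystem(eqs, z_names)
    if dimension is None:
        jac = full.jacobian(z0)
        dimension = numeric_corank(jac, 0).corank
    d = dimension
    if d < 1:
        raise ValueError("jet fiber is finite (d = 0) at this order")
    # precondition: jets span many orders of magnitude, so track in scaled
    # coordinates w = z / D with D the seed magnitudes, and equilibrate the
    # equations so the square-up below stays well conditioned
    D = np.maximum(np.abs(z0), 1.0)
    scale_sub = {v: float(Dv) * Poly.var(v) for v, Dv in zip(z_names, D)}
    eqs_w = [eq.subs(scale_sub) for eq in eqs]
    w0 = z0 / D
    env0 = dict(zip(z_names, w0))
    eqs_w = [_normalize_equation(eq, env0) for eq in eqs_w]
    if len(eqs_w) != n_z - d:
        # keep the system sparse: pick a well-conditioned subset of rows
        # (QR with pivoting on the transposed Jacobian) instead of dense
        # generic combinations; endpoints are filtered on the full system
        import scipy.linalg

        jac_w = CompiledSystem(eqs_w, z_names).jacobian(w0)
        _, _, piv = scipy.linalg.qr(jac_w.T, pivoting=True)
        keep = sorted(piv[: n_z - d])
        eqs_w = [eqs_w[i] for i in keep]

    m1 = len(model.params)

    def pad_and_scale(slice_p: LinearSlice) -> LinearSlice:
        A = np.hstack(
            [
                slice_p.coefficient_matrix,
                np.zeros((slice_p.codimension, n_z - m1), dtype=complex),
            ]
        )
        return LinearSlice(A * D[None, :], slice_p.constants)

    p0 = np.asarray(base_params, dtype=complex)
    sample = FiberSample(source=f"{model.name}:F_{r}", base_point=p0)
    scale = 1.0 + float(np.linalg.norm(p0))
    attempts = 0
    while len(sample.component_points) < n:
        if slice_pair is not None:
            slice_from, slice_to = (
                pad_and_scale(slice_pair[0]),
                pad_and_scale(slice_pair[1]),
            )
        else:
            Ap = random_complex(rng, d * m1).reshape(d, m1)
            slice_from = pad_and_scale(LinearSlice(Ap, Ap @ p0))
            slice_to = LinearSlice(
                slice_from.coefficient_matrix,
                slice_from.constants + scale * random_complex(rng, d),
            )
        h = slice_move_homotopy(eqs_w, z_names, slice_from, slice_to)
        res = track(h, w0, settings)
        ok = False
        if res.ok:
            endpoint = res.endpoint * D
            resid = np.max(np.abs(full.values(endpoint))) / max(
                1.0, float(np.linalg.norm(endpoint))
            )
            if resid < 1e-6:
                sample.component_points.append(endpoint[:m1])
                ok = True
        if slice_pair is not None:
            if not ok:
                raise ArithmeticError(f"explicit slice move failed ({res.status})")
            break
        if not ok:
            attempts += 1
            if attempts > 4 * n:
                raise ArithmeticError("jet-side fiber sampling failed repeatedly")
    return sample


# ---------------------------------------------------------------------------
# all fiber components via an affine restriction
# ---------------------------------------------------------------------------


def all_components(
    c: CoefficientMap,
    b_matrix: Sequence[Sequence[complex]],
    b_const: Sequence[complex],
    p_hat: Sequence[complex],
    rng: np.random.Generator,
    *,
    settings: PathSettings | None = None,
    max_useless_loops: int = 10,
    total_degree_limit: int = 200,
) -> list[np.ndarray]:
    """Points on every irreducible component of the fiber over p = b(p_hat).

    The parameters are restricted to the affine subspace b(C^{m1-d}); the
    restricted map must be identifiable, so c(b(q_hat)) = c(b(p_hat)) has
    finitely many solutions, at least one on each component of the full
    fiber.  Small systems are solved by total-degree homotopy, larger ones
    by monodromy over the restricted base space.
    """
    reduced = [f"_b{i + 1}" for i in range(len(p_hat))]
    cb = restrict_map(c, b_matrix, b_const, reduced)
    ell, _ = method1_dimension(cb, rng)
    if ell > 0:
        raise ValueError(
            "restricted map is still rank-deficient; choose a new random restriction"
        )
    p_hat = np.asarray(p_hat, dtype=complex)
    bezout = 1
    for num, _ in cb.coeffs[: cb.m1]:
        bezout *= max(num.total_degree(), 1)
    if cb.m2 == cb.m1 and bezout <= total_degree_limit:
        from .degree import solve_fiber

        value = [complex(v) for v in cb.evaluate(p_hat)]
        hat_solutions = solve_fiber(cb, value, rng, settings)
    else:
        from .degree import monodromy_fiber_points

        hat_solutions, _ = monodromy_fiber_points(
            cb,
            p_hat,
            rng,
            max_useless_loops=max_useless_loops,
            settings=settings,
            run_trace=False,
        )
    B = np.asarray(b_matrix, dtype=complex)
    c0 = np.asarray(b_const, dtype=complex)
    points = [B @ q + c0 for q in hat_solutions]
    # base point first, stable order afterwards
    base = B @ p_hat + c0
    points.sort(key=lambda q: float(np.linalg.norm(q - base)))
    return points


def affine_image_slice(
    b_matrix: Sequence[Sequence[complex]], b_const: Sequence[complex]
) -> LinearSlice:
    """The image of the affine map b as a linear slice {N q = N b_const}."""
    B = np.asarray(b_matrix, dtype=complex)
    c0 = np.asarray(b_const, dtype=complex)
    _, _, vh = np.linalg.svd(B.T, full_matrices=True)
    rank = np.linalg.matrix_rank(B)
    N = vh[rank:].conj()
    return LinearSlice(N, N @ c0)


def component_partition(
    c: CoefficientMap,
    base_point: Sequence[complex],
    witness_points: Sequence[np.ndarray],
    rng: np.random.Generator,
    *,
    dimension: int | None = None,
    slice_matrix: np.ndarray | None = None,
    settings: PathSettings | None = None,
    max_useless_loops: int = 8,
) -> list[list[int]]:
    """Partition fiber witness points into irreducible-component orbits.

    The witness points all lie on the fiber over c(base_point) cut by a
    common codimension-d slice.  Random monodromy loops of that slice
    connect points on the same irreducible component; the returned partition
    is the transitive closure of the observed connections (an upper bound on
    the true number of components, tight once the loops mix).
    """
    p = np.asarray(base_point, dtype=complex)
    pts = [np.asarray(w, dtype=complex) for w in witness_points]
    d = dimension if dimension is not None else method1_dimension(c, rng)[0]
    value = np.array([complex(v) for v in c.evaluate(p)])
    eqs = _randomized_fiber_equations(c, value, d, rng)
    full = CompiledSystem(c.fiber_equations(value), c.params)
    if slice_matrix is None:
        A = random_complex(rng, d * c.m1).reshape(d, c.m1)
    else:
        A = np.asarray(slice_matrix, dtype=complex)
    base_slice = LinearSlice(A, A @ pts[0])
    for w in pts:
        if base_slice.residual(w) > 1e-6 * (1 + np.linalg.norm(w)):
            raise ValueError("witness points must lie on a common slice")

    parent = list(range(len(pts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, k: int) -> bool:
        ri, rk = find(i), find(k)
        if ri == rk:
            return False
        parent[max(ri, rk)] = min(ri, rk)
        return True

    from .homotopy import loop_homotopy

    scale = 1.0 + float(np.linalg.norm(base_slice.constants))
    useless = 0
    while useless < max_useless_loops and len({find(i) for i in range(len(pts))}) > 1:
        useless += 1
        direction = scale * random_complex(rng, d)
        h = loop_homotopy(eqs, c.params, base_slice, direction)
        for i, w in enumerate(pts):
            res = track(h, w, settings)
            if not res.ok:
                continue
            z = res.endpoint
            if float(np.max(np.abs(full.values(z)))) > 1e-6 * max(1.0, float(np.linalg.norm(z))):
                continue
            for k, other in enumerate(pts):
                if np.linalg.norm(z - other) < 1e-6 * (1 + np.linalg.norm(other)):
                    if union(i, k):
                        useless = 0
                    break
    groups: dict[int, list[int]] = {}
    for i in range(len(pts)):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


# ---------------------------------------------------------------------------
# interpolation of identifiable functions
# ---------------------------------------------------------------------------


def monomial_basis(
    params: Sequence[str],
    max_degree: int,
    *,
    subset: Sequence[str] | None = None,
    degrees: Sequence[int] | None = None,
) -> FunctionBasis:
    """All nonconstant monomials of total degree <= max_degree.

    ``subset`` restricts the variables used; ``degrees`` restricts to the
    listed total degrees (e.g. a single stage of a staged search).
    """
    if max_degree < 1:
        raise ValueError("max_degree must be at least 1")
    names = list(subset) if subset is not None else list(params)
    wanted = set(degrees) if degrees is not None else set(range(1, max_degree + 1))
    terms: list[Poly] = []
    for deg in sorted(wanted):
        for combo in combinations_with_replacement_sorted(names, deg):
            mono: dict[str, int] = {}
            for v in combo:
                mono[v] = mono.get(v, 0) + 1
            terms.append(Poly({tuple(sorted(mono.items())): 1}))
    return FunctionBasis(terms=terms, degree_bound=max_degree)


def combinations_with_replacement_sorted(names: Sequence[str], r: int):
    from itertools import combinations_with_replacement

    return combinations_with_replacement(names, r)


def constraint_rows(
    basis: FunctionBasis, pairs: Sequence[tuple[np.ndarray, np.ndarray]], params: Sequence[str]
) -> np.ndarray:
    rows = []
    for p, q in pairs:
        row = basis.evaluate(q, params) - basis.evaluate(p, params)
        rows.append(row)
    return np.array(rows, dtype=complex)


def _nullspace(rows: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Orthonormal nullspace basis (columns) of a stacked constraint matrix.

    Rows that are negligible relative to the largest entry of the matrix are
    numerically zero constraints (sample pairs on which every basis function
    agrees) and are dropped before per-row normalisation, which would
    otherwise amplify their noise into spurious constraints.
    """
    if rows.size == 0:
        raise ValueError("no constraint rows")
    gmax = float(np.max(np.abs(rows)))
    if gmax == 0:
        return np.eye(rows.shape[1], dtype=complex)
    scales = np.max(np.abs(rows), axis=1)
    keep = scales > 1e-9 * gmax
    rows = rows[keep] / scales[keep, None]
    if rows.shape[0] == 0:
        return np.eye(rows.shape[1], dtype=complex)
    _, sv, vh = np.linalg.svd(rows, full_matrices=True)
    cut = tol * (sv[0] if len(sv) and sv[0] > 0 else 1.0)
    rank = int(np.sum(sv > cut))
    return vh[rank:].conj().T


def identifiable_subspace(
    basis: FunctionBasis,
    samples: Sequence[FiberSample],
    params: Sequence[str],
    tol: float = 1e-8,
) -> IdentifiableSet:
    """Null-space of the sample constraints: the identifiable subspace of F.

    Pairs are imposed one at a time; the null-space dimension decreases
    monotonically and the computation stops once it is stable across two
    consecutive additions.  The recorded dimension history exposes which
    pairs were informative and which redundant.
    """
    pairs = [pair for s in samples for pair in s.pairs]
    if not pairs:
        raise ValueError("at least one sample pair is required")
    rows: list[np.ndarray] = []
    history: list[int] = []
    stable = 0
    for pair in pairs:
        rows.append(constraint_rows(basis, [pair], params)[0])
        ns = _nullspace(np.array(rows), tol)
        history.append(ns.shape[1])
        if len(history) > 1 and history[-1] == history[-2]:
            stable += 1
            if stable >= 2:
                break
        else:
            stable = 0
    ns = _nullspace(np.array(rows), tol)
    ints = integer_recovery_from_rows(np.array(rows), tol=tol)
    if ints is not None and len(ints) == ns.shape[1]:
        coeffs = [np.array(v, dtype=complex) for v in ints]
    else:
        coeffs = [ns[:, i] for i in range(ns.shape[1])]
    out = IdentifiableSet(
        params=list(params),
        basis=basis,
        coefficients=coeffs,
        labels=["identifiable"] * len(coeffs),
        nullspace_dim_history=history,
    )
    return out


# ---------------------------------------------------------------------------
# integer recovery
# ---------------------------------------------------------------------------


def _rationalize(x: complex, max_den: int = RECOVERY_HEIGHT_BOUND) -> Fraction | None:
    if abs(x.imag) > 1e-6 * (1 + abs(x.real)):
        return None
    f = Fraction(float(x.real)).limit_denominator(max_den)
    if abs(float(f) - x.real) > 1e-6 * (1 + abs(x.real)):
        return None
    return f


def integer_recovery_from_rows(
    rows: np.ndarray, tol: float = 1e-8
) -> list[list[int]] | None:
    """Primitive integer vectors spanning the null space of the constraint rows.

    The orthonormal null-space basis is reduced to row-echelon form over its
    own span (pivoting on the first well-conditioned columns), each entry is
    rationalised with a bounded denominator, and candidates are verified
    against the rows.  Returns None when the span admits no such basis below
    the height bound.
    """
    ns = _nullspace(rows, tol)
    dim = ns.shape[1]
    if dim == 0:
        return []
    V = ns.T.copy()  # dim x n_terms
    n = V.shape[1]
    pivots: list[int] = []
    r = 0
    for col in range(n):
        if r >= dim:
            break
        piv = max(range(r, dim), key=lambda i: abs(V[i, col]))
        if abs(V[piv, col]) < 1e-8:
            continue
        V[[r, piv]] = V[[piv, r]]
        V[r] = V[r] / V[r, col]
        for i in range(dim):
            if i != r:
                V[i] = V[i] - V[i, col] * V[r]
        pivots.append(col)
        r += 1
    out: list[list[int]] = []
    gmax = float(np.max(np.abs(rows))) or 1.0
    scale_rows = np.max(np.abs(rows), axis=1)
    sig = scale_rows > 1e-9 * gmax  # negligible rows are trivially satisfied
    normalized_rows = rows[sig] / scale_rows[sig, None]
    if normalized_rows.shape[0] == 0:
        normalized_rows = np.zeros((1, rows.shape[1]), dtype=complex)
    for i in range(r):
        fracs = []
        ok = True
        for x in V[i]:
            if abs(x) < 1e-9:
                fracs.append(Fraction(0))
                continue
            f = _rationalize(complex(x))
            if f is None:
                ok = False
                break
            fracs.append(f)
        if not ok:
            return None
        from math import gcd, lcm

        denom = lcm(*[f.denominator for f in fracs]) if fracs else 1
        ints = [int(f * denom) for f in fracs]
        g = 0
        for v in ints:
            g = gcd(g, abs(v))
        if g > 1:
            ints = [v // g for v in ints]
        if max(abs(v) for v in ints) > RECOVERY_HEIGHT_BOUND:
            return None
        vec = np.array(ints, dtype=complex)
        if np.max(np.abs(normalized_rows @ vec)) > 1e-6 * max(1.0, np.linalg.norm(vec)):
            return None
        out.append(ints)
    return out


def integer_recovery(
    samples: Sequence[FiberSample], basis: FunctionBasis, params: Sequence[str]
) -> list[list[int]]:
    """Integer coefficient vectors spanning the identifiable subspace of F."""
    pairs = [pair for s in samples for pair in s.pairs]
    if not pairs:
        raise ValueError("at least one sample pair is required")
    rows = constraint_rows(basis, pairs, params)
    out = integer_recovery_from_rows(rows)
    if out is None:
        raise ArithmeticError(
            "no integer relation below the height bound "
            f"{RECOVERY_HEIGHT_BOUND}; the identifiable subspace may be irrational"
        )
    return out


# ---------------------------------------------------------------------------
# global classification and independence
# ---------------------------------------------------------------------------


def classify_global(
    functions: Sequence[Poly],
    component_points: Sequence[np.ndarray],
    params: Sequence[str],
    tol: float = 1e-6,
    *,
    complete_coverage: bool = True,
) -> tuple[list[str], list[Poly]]:
    """Label functions globally identifiable iff constant across all components.

    Also searches the span of the given functions for combinations that
    become globally identifiable even when individual functions are not
    (sums over conjugate components), via a second null-space over the
    component-value matrix.  With ``complete_coverage`` False the labels are
    reported as provisional.
    """
    pts = [np.asarray(q, dtype=complex) for q in component_points]
    if len(pts) < 2:
        return ["globally identifiable" for _ in functions], list(functions)
    envs = [dict(zip(params, q)) for q in pts]
    values = np.array(
        [[complex(f.to_numeric().eval(env)) for env in envs] for f in functions]
    )
    labels = []
    suffix = "" if complete_coverage else " (provisional)"
    for row in values:
        spread = np.max(np.abs(row - row[0]))
        scale = max(1.0, float(np.max(np.abs(row))))
        if spread < tol * scale:
            labels.append("globally identifiable" + suffix)
        else:
            labels.append("identifiable" + suffix)
    # combinations constant across components: nullspace of value differences
    diff_rows = (values[:, 1:] - values[:, :1]).T  # (n_pts-1) x n_funcs
    combos: list[Poly] = []
    if functions:
        ints = integer_recovery_from_rows(diff_rows)
        if ints:
            for vec in ints:
                acc = Poly()
                for coeff, f in zip(vec, functions):
                    if coeff != 0:
                        acc = acc + coeff * f
                combos.append(acc)
    return labels, combos


def independence_count(
    functions: Sequence[Poly], params: Sequence[str], rng: np.random.Generator
) -> int:
    """Number of algebraically independent functions: generic Jacobian rank."""
    if not functions:
        return 0
    point = random_complex(rng, len(params))
    system = CompiledSystem(list(functions), list(params))
    jac = system.jacobian(point)
    return numeric_corank(jac, 0).rank


# ---------------------------------------------------------------------------
# staged sparse search (low-degree transcendence basis)
# ---------------------------------------------------------------------------


@dataclass
class StagedSearchResult:
    functions: list[Poly]
    stages: list[tuple[int, list[str]]]  # (degree, pretty functions found)
    rank_target: int
    independence: int


def staged_search(
    c: CoefficientMap,
    rng: np.random.Generator,
    *,
    max_degree: int = 3,
    max_support: int = 3,
    pairs_per_stage: int = 24,
    base_points: int = 3,
    settings: PathSettings | None = None,
    subset_budget: int = 40_000,
) -> StagedSearchResult:
    """Build low-degree identifiable functions degree by degree.

    At each degree d the candidate monomials of total degree d are scanned
    for sparse integer combinations (support size 1, 2, ..., max_support)
    that are constant on sampled fiber components, keeping only candidates
    algebraically independent of the functions already found, until
    rank c = m1 - l independent identifiable functions are known.
    """
    ell, rank_report = method1_dimension(c, rng)
    rank_target = rank_report.rank
    if ell == 0:
        raise ValueError("map is identifiable; every function of the parameters qualifies")
    # shared sample pairs (raw parameter points), reused by every stage
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    per_base = max(1, pairs_per_stage // base_points)
    for _ in range(base_points):
        p = random_complex(rng, c.m1)
        sample = sample_fiber(c, p, per_base, rng, dimension=ell, settings=settings)
        pairs.extend(sample.pairs)

    found: list[Poly] = []
    stages: list[tuple[int, list[str]]] = []
    check_point = random_complex(rng, c.m1)

    def independent_with(candidate: Poly) -> bool:
        funcs = found + [candidate]
        system = CompiledSystem(funcs, list(c.params))
        jac = system.jacobian(check_point)
        return numeric_corank(jac, 0).rank == len(funcs)

    for degree_stage in range(1, max_degree + 1):
        if len(found) >= rank_target:
            break
        basis = monomial_basis(c.params, degree_stage, degrees=[degree_stage])
        M = constraint_rows(basis, pairs, c.params)
        scales = np.max(np.abs(M), axis=1, keepdims=True)
        scales[scales == 0] = 1.0
        Mn = M / scales
        stage_found: list[str] = []
        n_terms = len(basis.terms)
        col_norm = np.linalg.norm(Mn, axis=0)
        col_scale = max(1.0, float(np.max(col_norm)))
        # support-1 candidates: single monomials constant on the fiber
        for idx in range(n_terms):
            if len(found) >= rank_target:
                break
            if col_norm[idx] < 1e-6 * col_scale:
                candidate = basis.terms[idx]
                if independent_with(candidate):
                    found.append(candidate)
                    stage_found.append(format_poly(candidate))
        for support in range(2, max_support + 1):
            if len(found) >= rank_target:
                break
            combos = combinations(range(n_terms), support)
            budget = subset_budget
            for cols in combos:
                if len(found) >= rank_target:
                    break
                budget -= 1
                if budget < 0:
                    break
                sub = Mn[:, list(cols)]
                # skip if any chosen column is itself (near) constant
                if any(col_norm[i] < 1e-6 * col_scale for i in cols):
                    continue
                sv = np.linalg.svd(sub, compute_uv=False)
                if sv[-1] > 1e-6 * max(sv[0], 1.0):
                    continue
                ints = integer_recovery_from_rows(sub)
                if not ints:
                    continue
                for vec in ints:
                    if all(v != 0 for v in vec) is False and support > 1:
                        continue
                    candidate = Poly()
                    for coeff, i in zip(vec, cols):
                        candidate = candidate + coeff * basis.terms[i]
                    if independent_with(candidate):
                        found.append(candidate)
                        stage_found.append(format_poly(candidate))
        stages.append((degree_stage, stage_found))
    indep = independence_count(found, c.params, rng)
    return StagedSearchResult(
        functions=found, stages=stages, rank_target=rank_target, independence=indep
    )
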