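"""Dimension of unidentifiability from coefficient maps and from jet systems.

The coefficients of a model's input-output equations form a rational map
c : C^m1 -> C^m2 on the parameters.  The dimension of a generic fiber of c
(the *dimension of unidentifiability*, l) equals the corank of the Jacobian
of c at a generic complex point; l = 0 means the model is identifiable.

Two routes are provided:

* ``method1_dimension`` evaluates the Jacobian corank of an explicitly known
  coefficient map at random complex points.
* ``method2_dimension`` works without input-output equations: for rising
  truncation order r it seeds a generic point on the jet system F_r, holds
  input and output jets fixed, and computes d_r = corank_0 - corank_m1 of
  the Jacobian (the dimension of the parameter projection of the fiber).
  The nonincreasing integer sequence d_r stabilises at l.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .model_core import OdeModel, random_complex, seed_point, truncate
from .numerics import DEFAULT_RANK_TOL, RankReport, jacobian_at, numeric_corank
from .poly import Poly


def elementary_symmetric(k: int, values: Sequence) -> object:
    """k-th elementary symmetric polynomial of the given values; E_0 = 1.

    Works on numbers and on :class:`Poly` values alike.
    """
    n = len(values)
    if k < 0 or k > n:
        raise ValueError(f"k={k} out of range for {n} values")
    # dynamic programming over e_0..e_k
    e: list[object] = [1] + [0] * k
    for v in values:
        for i in range(min(k, len(e) - 1), 0, -1):
            e[i] = e[i] + e[i - 1] * v
    return e[k]


# ---------------------------------------------------------------------------
# coefficient maps
# ---------------------------------------------------------------------------


@dataclass
class CoefficientMap:
    """A rational map p -> (c_1(p), ..., c_m2(p)) of input-output coefficients."""

    name: str
    params: list[str]
    coeffs: list[tuple[Poly, Poly]]  # (numerator, denominator)

    def __post_init__(self) -> None:
        declared = set(self.params)
        for num, den in self.coeffs:
            extra = (num.variables() | den.variables()) - declared
            if extra:
                raise ValueError(f"coefficient uses undeclared parameter(s) {sorted(extra)}")

    @property
    def m1(self) -> int:
        return len(self.params)

    @property
    def m2(self) -> int:
        return len(self.coeffs)

    @property
    def is_polynomial(self) -> bool:
        return all(den.total_degree() == 0 for _, den in self.coeffs)

    def evaluate(self, point: Sequence) -> list:
        """Evaluate the map at a point; exact inputs give exact outputs."""
        env = dict(zip(self.params, point))
        out = []
        for num, den in self.coeffs:
            n = num.eval(env)
            d = den.eval(env)
            if isinstance(n, (int, Fraction)) and isinstance(d, (int, Fraction)):
                val = Fraction(n) / Fraction(d)
                out.append(int(val) if val.denominator == 1 else val)
            else:
                out.append(n / d)
        return out

    def jacobian(self, point: Sequence[complex]) -> np.ndarray:
        env = dict(zip(self.params, np.asarray(point, dtype=complex)))
        jac = np.zeros((self.m2, self.m1), dtype=complex)
        for i, (num, den) in enumerate(self.coeffs):
            nv = complex(num.to_numeric().eval(env)) if not num.is_zero() else 0.0
            dv = complex(den.to_numeric().eval(env))
            if abs(dv) < 1e-14:
                raise ArithmeticError(f"denominator of coefficient {i} vanishes at the point")
            for j, p in enumerate(self.params):
                dn = num.diff(p)
                dd = den.diff(p)
                dnv = complex(dn.to_numeric().eval(env)) if not dn.is_zero() else 0.0
                ddv = complex(dd.to_numeric().eval(env)) if not dd.is_zero() else 0.0
                jac[i, j] = (dnv * dv - nv * ddv) / (dv * dv)
        return jac

    def graph_equations(self, image_vars: Sequence[str]) -> list[Poly]:
        """Denominator-cleared graph equations y_i * den_i - num_i."""
        eqs = []
        for (num, den), y in zip(self.coeffs, image_vars):
            eqs.append(Poly.var(y) * den - num)
        return eqs

    def fiber_equations(self, value: Sequence[complex]) -> list[Poly]:
        """Denominator-cleared equations c(q) = value."""
        return [den * complex(v) - num for (num, den), v in zip(self.coeffs, value)]


def restrict_map(c: CoefficientMap, b_matrix, b_const, reduced_params: Sequence[str]) -> CoefficientMap:
    """Compose c with an affine map b(p_hat) = B p_hat + const on the parameters."""
    sub = {}
    for i, p in enumerate(c.params):
        expr = Poly.const(b_const[i])
        for j, q in enumerate(reduced_params):
            if b_matrix[i][j] != 0:
                expr = expr + b_matrix[i][j] * Poly.var(q)
        sub[p] = expr
    coeffs = [(num.subs(sub), den.subs(sub)) for num, den in c.coeffs]
    return CoefficientMap(name=f"{c.name}|b", params=list(reduced_params), coeffs=coeffs)


def _one(p: Poly) -> tuple[Poly, Poly]:
    return (p, Poly.const(1))


def coefficient_fixture(name: str) -> CoefficientMap:
    """Bundled coefficient maps of input-output equations for the benchmarks."""
    if name == "linear3_c":
        k01, k02, k03, k12, k13, k21, k32 = (
            Poly.var(v) for v in ("k01", "k02", "k03", "k12", "k13", "k21", "k32")
        )
        a1 = -(k01 + k21)
        a2 = -(k02 + k12 + k32)
        a3 = -(k03 + k13)
        coeffs = [
            elementary_symmetric(1, [a1, a2, a3]),
            elementary_symmetric(2, [a1, a2, a3]) - elementary_symmetric(2, [k12, k21]),
            elementary_symmetric(3, [a1, a2, a3])
            + elementary_symmetric(3, [k13, k32, k21])
            + elementary_symmetric(3, [k12, k21, k03 + k13]),
            elementary_symmetric(1, [a2, a3]),
            elementary_symmetric(2, [a2, a3]),
        ]
        return CoefficientMap(
            name="linear3_c",
            params=["k01", "k02", "k03", "k12", "k13", "k21", "k32"],
            coeffs=[_one(c) for c in coeffs],
        )
    if name == "linear3_noleak13_c":
        k02, k12, k13, k21, k32 = (
            Poly.var(v) for v in ("k02", "k12", "k13", "k21", "k32")
        )
        coeffs = [
            k02 + k12 + k13 + k21 + k32,
            k02 * k13 + k02 * k21 + k12 * k13 + k13 * k21 + k13 * k32 + k21 * k32,
            k02 * k13 * k21,
            k02 + k12 + k13 + k32,
            k02 * k13 + k12 * k13 + k13 * k32,
        ]
        return CoefficientMap(
            name="linear3_noleak13_c",
            params=["k02", "k12", "k13", "k21", "k32"],
            coeffs=[_one(c) for c in coeffs],
        )
    if name == "fourcomp_c":
        names = ["a11", "a12", "a21", "a22", "a23", "a33", "a34", "a42", "a43", "a44"]
        v = {n: Poly.var(n) for n in names}
        zero = Poly()
        A = [
            [v["a11"], v["a12"], zero, zero],
            [v["a21"], v["a22"], v["a23"], zero],
            [zero, zero, v["a33"], v["a34"]],
            [zero, v["a42"], v["a43"], v["a44"]],
        ]
        A1 = [row[1:] for row in A[1:]]  # submodel seen from the output compartment
        coeffs = [
            _principal_minor_sum(A, 4),
            -_principal_minor_sum(A, 3),
            _principal_minor_sum(A, 2),
            -_principal_minor_sum(A, 1),
            _principal_minor_sum(A1, 3),
            -_principal_minor_sum(A1, 2),
            _principal_minor_sum(A1, 1),
        ]
        return CoefficientMap(name="fourcomp_c", params=names, coeffs=[_one(c) for c in coeffs])
    if name.startswith("identity"):
        n = int(name.removeprefix("identity").removesuffix("_c"))
        params = [f"p{i + 1}" for i in range(n)]
        return CoefficientMap(
            name=name, params=params, coeffs=[_one(Poly.var(p)) for p in params]
        )
    raise ValueError(
        f"unknown coefficient map {name!r}; available: linear3_c, "
        "linear3_noleak13_c, fourcomp_c, identityN_c"
    )


def _det(M: list[list[Poly]]) -> Poly:
    n = len(M)
    if n == 1:
        return M[0][0]
    out = Poly()
    for j in range(n):
        if M[0][j].is_zero():
            continue
        minor = [row[:j] + row[j + 1 :] for row in M[1:]]
        term = M[0][j] * _det(minor)
        out = out + term if j % 2 == 0 else out - term
    return out


def _principal_minor_sum(M: list[list[Poly]], k: int) -> Poly:
    from itertools import combinations

    n = len(M)
    out = Poly()
    for idx in combinations(range(n), k):
        out = out + _det([[M[i][j] for j in idx] for i in idx])
    return out


def example19_affine_restriction() -> tuple[list[list[int]], list[int], list[str]]:
    """The affine restriction b : C^5 -> C^7 used with the 3-compartment map."""
    B = [
        [1, 0, 0, 0, 0],
        [0, 1, 0, 0, 0],
        [0, 0, 1, 0, 0],
        [0, 0, 0, 1, 0],
        [0, 0, 0, 0, 1],
        [1, 3, -1, -3, 2],
        [2, 3, 5, 1, -3],
    ]
    const = [0, 0, 0, 0, 0, 4, -5]
    reduced = [f"b{i + 1}" for i in range(5)]
    return B, const, reduced


# ---------------------------------------------------------------------------
# Method 1
# ---------------------------------------------------------------------------


def method1_dimension(
    c: CoefficientMap,
    rng: np.random.Generator,
    *,
    tol: float = DEFAULT_RANK_TOL,
) -> tuple[int, RankReport]:
    """Dimension of unidentifiability as the Jacobian corank of c.

    The corank is computed at two independent random complex points; a
    disagreement indicates a borderline rank tolerance and raises.
    """
    reports = []
    for _ in range(2):
        point = random_complex(rng, c.m1)
        jac = c.jacobian(point)
        reports.append(numeric_corank(jac, 0, tol))
    if reports[0].corank != reports[1].corank:
        raise ArithmeticError(
            "corank differs between two random points "
            f"({reports[0].corank} vs {reports[1].corank}); review the rank tolerance"
        )
    return reports[0].corank, reports[0]


# ---------------------------------------------------------------------------
# Method 2
# ---------------------------------------------------------------------------


@dataclass
class DimensionTable:
    """Per-order summary rows (r, N_r, corank_0, corank_m1, d_r) of Method 2."""

    model_name: str
    m1: int
    rows: list[tuple[int, int, int, int, int]] = field(default_factory=list)
    stabilized: bool = False
    stop_r: int | None = None

    @property
    def final_dimension(self) -> int | None:
        if not self.stabilized:
            return None
        for r, _, _, _, d in self.rows:
            if r == self.stop_r:
                return d
        return None

    @property
    def d_sequence(self) -> list[int]:
        return [row[4] for row in self.rows]

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("r,N_r,corank0,corank_m1,d_r\n")
        for row in self.rows:
            buf.write(",".join(str(v) for v in row) + "\n")
        return buf.getvalue()


def method2_dimension(
    model: OdeModel,
    rng: np.random.Generator,
    max_r: int = 25,
    *,
    tol: float = DEFAULT_RANK_TOL,
    extra_rows: int = 1,
    force_r: int | None = None,
) -> DimensionTable:
    """Dimension of unidentifiability from jet systems (no input-output equations).

    For r = 0, 1, 2, ... build F_r, seed a generic point z_r, hold input and
    output jets fixed, and set d_r = corank_0 JF_r(z_r) - corank_m1 JF_r(z_r).
    Stops when d_r = 0 or when both coranks repeat between consecutive orders;
    ``extra_rows`` additional confirmation rows are computed and reported.
    ``force_r`` forces computation of rows up to the given order regardless.
    """
    if max_r < 1:
        raise ValueError("max_r must be at least 1")
    table = DimensionTable(model_name=model.name, m1=model.m1)
    prev: tuple[int, int] | None = None
    prev_d = None
    stop_r: int | None = None
    r = 0
    while True:
        jetsys = truncate(model, r)
        compiled = jetsys.compiled()
        # d_r is provably nonincreasing and nonnegative; a violation flags a
        # numerically unlucky sample point, so retry with a fresh one
        for attempt in range(3):
            point = seed_point(jetsys, rng)
            jac = jacobian_at(compiled, point.vector(), held_fixed=jetsys.held_fixed)
            rep0 = numeric_corank(jac, 0, tol)
            rep_m1 = numeric_corank(jac, model.m1, tol)
            d_r = rep0.corank - rep_m1.corank
            if 0 <= d_r and (prev_d is None or d_r <= prev_d):
                break
        table.rows.append((r, jetsys.n_free, rep0.corank, rep_m1.corank, d_r))
        prev_d = d_r
        if stop_r is None:
            hit = d_r == 0 or (prev is not None and prev == (rep0.corank, rep_m1.corank))
            if hit:
                stop_r = r
        prev = (rep0.corank, rep_m1.corank)
        done_forced = force_r is None or r >= force_r
        if stop_r is not None and r >= stop_r + extra_rows and done_forced:
            table.stabilized = True
            table.stop_r = stop_r
            break
        if r >= max_r:
            break
        r += 1
    return table
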