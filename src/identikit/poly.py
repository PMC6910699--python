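"""Sparse multivariate polynomials and fast compiled evaluation.

Polynomials are the common currency of the toolkit: jet (truncated Taylor)
systems, input-output coefficient maps, homotopies and linear slices are all
held as sparse polynomial systems over named variables.  Coefficients may be
exact (``int``/``Fraction``) or numeric (``float``/``complex``); arithmetic
never converts exact coefficients to floats on its own, so fixture maps can
be evaluated in exact rational arithmetic when needed.

For path tracking and rank computations, :class:`CompiledSystem` flattens a
polynomial system into index arrays so that values and Jacobians are
computed with a handful of vectorised numpy operations per call.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

# A monomial is a sorted tuple of (variable name, positive exponent) pairs.
Monomial = tuple[tuple[str, int], ...]

_ZERO_TOL = 0.0  # exact coefficient arithmetic drops true zeros only


def _is_exact(c) -> bool:
    return isinstance(c, (int, Fraction))


class Poly:
    """Sparse multivariate polynomial over named variables."""

    __slots__ = ("terms",)

    def __init__(self, terms: Mapping[Monomial, object] | None = None):
        self.terms: dict[Monomial, object] = {}
        if terms:
            for mono, c in terms.items():
                if c != 0:
                    self.terms[mono] = c

    # -- constructors ---------------------------------------------------
    @staticmethod
    def const(c) -> "Poly":
        return Poly({(): c}) if c != 0 else Poly()

    @staticmethod
    def var(name: str) -> "Poly":
        return Poly({((name, 1),): 1})

    @staticmethod
    def linear(coeffs: Mapping[str, object], constant=0) -> "Poly":
        terms: dict[Monomial, object] = {}
        for name, c in coeffs.items():
            if c != 0:
                terms[((name, 1),)] = c
        if constant != 0:
            terms[()] = constant
        return Poly(terms)

    # -- basic queries ---------------------------------------------------
    def is_zero(self) -> bool:
        return not self.terms

    def variables(self) -> set[str]:
        out: set[str] = set()
        for mono in self.terms:
            for name, _ in mono:
                out.add(name)
        return out

    def total_degree(self) -> int:
        if not self.terms:
            return 0
        return max(sum(e for _, e in mono) for mono in self.terms)

    def constant_part(self):
        return self.terms.get((), 0)

    # -- arithmetic -------------------------------------------------------
    def _iadd_term(self, mono: Monomial, c) -> None:
        cur = self.terms.get(mono)
        if cur is None:
            if c != 0:
                self.terms[mono] = c
        else:
            s = cur + c
            if s == 0:
                del self.terms[mono]
            else:
                self.terms[mono] = s

    def __add__(self, other) -> "Poly":
        other = _as_poly(other)
        out = Poly(dict(self.terms))
        for mono, c in other.terms.items():
            out._iadd_term(mono, c)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Poly":
        return Poly({m: -c for m, c in self.terms.items()})

    def __sub__(self, other) -> "Poly":
        return self + (-_as_poly(other))

    def __rsub__(self, other) -> "Poly":
        return _as_poly(other) + (-self)

    def __mul__(self, other) -> "Poly":
        other = _as_poly(other)
        out = Poly()
        for m1, c1 in self.terms.items():
            for m2, c2 in other.terms.items():
                out._iadd_term(_mono_mul(m1, m2), c1 * c2)
        return out

    __rmul__ = __mul__

    def __pow__(self, n: int) -> "Poly":
        if n < 0:
            raise ValueError("negative power of a polynomial")
        out = Poly.const(1)
        base = self
        while n:
            if n & 1:
                out = out * base
            base = base * base if n > 1 else base
            n >>= 1
        return out

    def diff(self, name: str) -> "Poly":
        out = Poly()
        for mono, c in self.terms.items():
            for i, (v, e) in enumerate(mono):
                if v == name:
                    if e == 1:
                        new = mono[:i] + mono[i + 1 :]
                    else:
                        new = mono[:i] + ((v, e - 1),) + mono[i + 1 :]
                    out._iadd_term(new, c * e)
                    break
        return out

    def eval(self, env: Mapping[str, object]):
        total = 0
        for mono, c in self.terms.items():
            val = c
            for v, e in mono:
                val = val * env[v] ** e
            total = total + val
        return total

    def subs(self, env: Mapping[str, object]) -> "Poly":
        """Substitute variables by scalars or polynomials."""
        out = Poly()
        for mono, c in self.terms.items():
            part = Poly.const(c)
            for v, e in mono:
                rep = env.get(v)
                if rep is None:
                    part = part * Poly({((v, e),): 1})
                else:
                    rep = _as_poly(rep)
                    part = part * rep**e
            out = out + part
        return out

    def to_numeric(self) -> "Poly":
        return Poly({m: complex(c) for m, c in self.terms.items()})

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if not self.terms:
            return "0"
        bits = []
        for mono, c in sorted(self.terms.items()):
            mono_s = "*".join(f"{v}^{e}" if e > 1 else v for v, e in mono)
            bits.append(f"({c})*{mono_s}" if mono_s else f"({c})")
        return " + ".join(bits)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Poly):
            other = _as_poly(other)
        return (self - other).is_zero()

    def __hash__(self):
        return hash(frozenset(self.terms.items()))


def _as_poly(x) -> Poly:
    if isinstance(x, Poly):
        return x
    return Poly.const(x)


def _mono_mul(m1: Monomial, m2: Monomial) -> Monomial:
    if not m1:
        return m2
    if not m2:
        return m1
    merged = dict(m1)
    for v, e in m2:
        merged[v] = merged.get(v, 0) + e
    return tuple(sorted(merged.items()))


# ---------------------------------------------------------------------------
# Truncated Taylor series with derivative-normalised coefficients
# ---------------------------------------------------------------------------


class TaylorSeries:
    """Truncated series x(t) = sum_j coeff[j] t^j / j! with Poly coefficients.

    Coefficients are normalised as derivatives at t=0, so the product rule is
    the Leibniz convolution with binomial weights.
    """

    __slots__ = ("coeffs",)

    def __init__(self, coeffs: Sequence[Poly]):
        self.coeffs = list(coeffs)

    @property
    def order(self) -> int:
        return len(self.coeffs) - 1

    @staticmethod
    def constant(value, order: int) -> "TaylorSeries":
        return TaylorSeries([_as_poly(value)] + [Poly()] * order)

    @staticmethod
    def from_jets(names: Sequence[str]) -> "TaylorSeries":
        return TaylorSeries([Poly.var(n) for n in names])

    def __add__(self, other: "TaylorSeries") -> "TaylorSeries":
        assert len(self.coeffs) == len(other.coeffs)
        return TaylorSeries([a + b for a, b in zip(self.coeffs, other.coeffs)])

    def __mul__(self, other: "TaylorSeries") -> "TaylorSeries":
        order = min(self.order, other.order)
        out = []
        for j in range(order + 1):
            acc = Poly()
            for m in range(j + 1):
                a = self.coeffs[m]
                b = other.coeffs[j - m]
                if a.is_zero() or b.is_zero():
                    continue
                acc = acc + math.comb(j, m) * (a * b)
            out.append(acc)
        return TaylorSeries(out)

    def scale(self, c) -> "TaylorSeries":
        return TaylorSeries([c * a for a in self.coeffs])

    def derivative(self) -> "TaylorSeries":
        # d/dt shifts derivative-normalised coefficients down by one
        return TaylorSeries(self.coeffs[1:])


def poly_series(poly: Poly, env: Mapping[str, TaylorSeries], order: int) -> TaylorSeries:
    """Taylor expansion of ``poly`` with each variable replaced by a series."""
    out = TaylorSeries.constant(0, order)
    for mono, c in poly.terms.items():
        part = TaylorSeries.constant(c, order)
        for v, e in mono:
            s = env[v]
            for _ in range(e):
                part = part * s
        out = out + part
    return out


# ---------------------------------------------------------------------------
# Compiled evaluation
# ---------------------------------------------------------------------------


class CompiledSystem:
    """Vectorised evaluator for a polynomial system and its Jacobian.

    The system is flattened once: every distinct non-constant monomial that
    appears in an equation or in a partial derivative is stored as a segment
    of (variable index, exponent) pairs.  Evaluation computes all monomial
    values with one vectorised power + segmented product, then applies sparse
    coefficient matrices.
    """

    def __init__(self, polys: Sequence[Poly], variables: Sequence[str]):
        self.polys = list(polys)
        self.variables = list(variables)
        self.n_eq = len(self.polys)
        self.n_var = len(self.variables)
        vidx = {v: i for i, v in enumerate(self.variables)}
        for k, p in enumerate(self.polys):
            extra = p.variables() - set(vidx)
            if extra:
                raise ValueError(f"equation {k} uses undeclared variables {sorted(extra)}")

        derivs: list[list[tuple[int, Poly]]] = []
        for p in self.polys:
            row = []
            for v in p.variables():
                d = p.diff(v)
                if not d.is_zero():
                    row.append((vidx[v], d))
            derivs.append(row)

        mono_index: dict[Monomial, int] = {}

        def midx(mono: Monomial) -> int:
            i = mono_index.get(mono)
            if i is None:
                i = len(mono_index)
                mono_index[mono] = i
            return i

        # equation matrix
        rows, cols, vals = [], [], []
        const = np.zeros(self.n_eq, dtype=complex)
        for i, p in enumerate(self.polys):
            for mono, c in p.terms.items():
                if mono == ():
                    const[i] += complex(c)
                else:
                    rows.append(i)
                    cols.append(midx(mono))
                    vals.append(complex(c))
        # jacobian matrix, row index = eq * n_var + var
        jrows, jcols, jvals = [], [], []
        jconst = np.zeros((self.n_eq, self.n_var), dtype=complex)
        for i, row in enumerate(derivs):
            for j, d in row:
                for mono, c in d.terms.items():
                    if mono == ():
                        jconst[i, j] += complex(c)
                    else:
                        jrows.append(i * self.n_var + j)
                        jcols.append(midx(mono))
                        jvals.append(complex(c))

        self.n_mono = len(mono_index)
        flat_var: list[int] = []
        flat_exp: list[int] = []
        ptr = [0]
        for mono in mono_index:  # dict preserves insertion order
            for v, e in mono:
                flat_var.append(vidx[v])
                flat_exp.append(e)
            ptr.append(len(flat_var))
        self._flat_var = np.asarray(flat_var, dtype=np.intp)
        self._flat_exp = np.asarray(flat_exp, dtype=np.int64)
        self._ptr = np.asarray(ptr[:-1], dtype=np.intp)
        self._simple_exp = bool(np.all(self._flat_exp == 1)) if len(flat_exp) else True

        shape_a = (self.n_eq, self.n_mono)
        self._A = sp.csr_matrix((vals, (rows, cols)), shape=shape_a, dtype=complex)
        self._const = const
        shape_j = (self.n_eq * self.n_var, self.n_mono)
        self._J = sp.csr_matrix((jvals, (jrows, jcols)), shape=shape_j, dtype=complex)
        self._jconst = jconst

    # -- evaluation -------------------------------------------------------
    def _mono_values(self, z: np.ndarray) -> np.ndarray:
        if self.n_mono == 0:
            return np.zeros(0, dtype=complex)
        base = z[self._flat_var]
        if not self._simple_exp:
            base = base**self._flat_exp
        return np.multiply.reduceat(base, self._ptr)

    def values(self, z: np.ndarray) -> np.ndarray:
        m = self._mono_values(np.asarray(z, dtype=complex))
        return self._A @ m + self._const

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        m = self._mono_values(np.asarray(z, dtype=complex))
        return (self._J @ m).reshape(self.n_eq, self.n_var) + self._jconst

    def values_and_jacobian(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = self._mono_values(np.asarray(z, dtype=complex))
        vals = self._A @ m + self._const
        jac = (self._J @ m).reshape(self.n_eq, self.n_var) + self._jconst
        return vals, jac


def sympy_to_poly(expr, allowed: Iterable[str]) -> Poly:
    """Convert a sympy expression (polynomial in its symbols) to a Poly.

    Rational coefficients are kept exact as :class:`fractions.Fraction`.
    """
    import sympy

    allowed = set(allowed)
    syms = sorted(expr.free_symbols, key=lambda s: s.name)
    undeclared = [s.name for s in syms if s.name not in allowed]
    if undeclared:
        raise ValueError(f"undeclared symbol(s): {', '.join(undeclared)}")
    expr = sympy.expand(expr)
    if not syms:
        return Poly.const(_sympy_coeff(expr))
    p = sympy.Poly(expr, *syms)
    out = Poly()
    names = [s.name for s in syms]
    for exps, coeff in p.terms():
        mono = tuple(sorted((n, e) for n, e in zip(names, exps) if e))
        out._iadd_term(mono, _sympy_coeff(coeff))
    return out


def _sympy_coeff(c):
    import sympy

    if isinstance(c, sympy.Integer):
        return int(c)
    if isinstance(c, sympy.Rational):
        return Fraction(int(c.p), int(c.q))
    cc = complex(c)
    return cc.real if cc.imag == 0 else cc
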