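"""Rational ODE models and their truncated Taylor-jet systems.

A model

    x'(t) = f(x(t), p, u(t)),    y(t) = g(x(t), p)

with rational right-hand sides is represented by :class:`OdeModel`.  The
central construction is :func:`truncate`: writing the states, inputs and
outputs as Taylor series x(t) = sum_j x_j t^j / j! and matching coefficients
of 1, t, ..., t^r yields a polynomial system F_r in the parameters and the
jet variables.  The jet coordinate ``x_j`` of a symbol is the j-th derivative
at t = 0 and is named ``"x.j"``.

Rational right-hand sides are cleared to polynomial form per equation before
expansion (valid at generic points; cleared denominators are retained and
checked for vanishing when seeding points).  Generic points on F_r = 0 are
produced by :func:`seed_point` via forward recursion: parameters, initial
states and input jets are drawn at random, and higher state jets plus output
jets follow uniquely, block by block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .poly import CompiledSystem, Poly, TaylorSeries, poly_series, sympy_to_poly

_DATA_DIR = Path(__file__).parent / "data"

FIXTURE_ALIASES = {"mapk": "mapk_6out"}
FIXTURE_NAMES = (
    "linear3",
    "linear3_noleak13",
    "threecomp",
    "hiv",
    "fourcomp",
    "mapk_6out",
    "mapk_2out",
    "mapk_4out",
    "mapk_mixed",
)


def jet_name(base: str, order: int) -> str:
    return f"{base}.{order}"


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class OdeModel:
    """A rational ODE model with declared symbol order preserved."""

    name: str
    states: list[str]
    params: list[str]
    inputs: list[str]
    outputs: list[str]
    rhs: list[tuple[Poly, Poly]]  # (numerator, denominator) per state
    output_exprs: list[tuple[Poly, Poly]]  # per output
    initial_constraints: list[Poly] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rhs) != len(self.states):
            raise ValueError("one right-hand side required per state")
        if len(self.output_exprs) != len(self.outputs):
            raise ValueError("one output expression required per output")
        declared = set(self.states) | set(self.params) | set(self.inputs)
        for num, den in self.rhs:
            extra = (num.variables() | den.variables()) - declared
            if extra:
                raise ValueError(f"undeclared symbol(s): {sorted(extra)}")
        out_declared = set(self.states) | set(self.params)
        for num, den in self.output_exprs:
            extra = (num.variables() | den.variables()) - out_declared
            if extra:
                raise ValueError(f"undeclared symbol(s) in output: {sorted(extra)}")
        for c in self.initial_constraints:
            extra = c.variables() - set(self.states)
            if extra:
                raise ValueError(f"initial constraints must be in states, got {sorted(extra)}")
            if c.total_degree() > 1:
                raise ValueError("initial constraints must be linear")
        # denominators must not vanish identically at a generic point
        rng = np.random.default_rng(20231213)
        pt = {s: complex(*rng.uniform(0.3, 1.0, 2)) for s in declared}
        for _, den in list(self.rhs) + list(self.output_exprs):
            if abs(complex(den.to_numeric().eval(pt))) < 1e-12:
                raise ValueError("denominator vanishes at a sampled generic point")

    @property
    def m1(self) -> int:
        return len(self.params)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _parse_rational(text: str, allowed: Sequence[str]) -> tuple[Poly, Poly]:
    import sympy
    from sympy.parsing.sympy_parser import parse_expr, standard_transformations

    local = {name: sympy.Symbol(name) for name in allowed}
    try:
        expr = parse_expr(
            text.replace("^", "**"), local_dict=local, transformations=standard_transformations
        )
    except Exception as exc:  # noqa: BLE001 - surface the parse failure
        raise ValueError(f"cannot parse expression {text!r}: {exc}") from exc
    syms = expr.free_symbols
    undeclared = sorted(s.name for s in syms if s.name not in local)
    if undeclared:
        raise ValueError(f"undeclared symbol(s): {', '.join(undeclared)}")
    if not expr.is_rational_function(*syms):
        raise ValueError(f"expression {text!r} is not a rational function")
    num, den = sympy.fraction(sympy.cancel(sympy.together(expr)))
    return sympy_to_poly(num, allowed), sympy_to_poly(den, allowed)


def _parse_constraint(text: str, states: Sequence[str]) -> Poly:
    cleaned = text.replace("(0)", "")
    if "=" in cleaned:
        lhs, rhs = cleaned.split("=", 1)
    else:
        lhs, rhs = cleaned, "0"
    lnum, lden = _parse_rational(lhs, states)
    rnum, rden = _parse_rational(rhs, states)
    if lden.total_degree() > 0 or rden.total_degree() > 0:
        raise ValueError("initial constraints must be polynomial")
    poly = lnum * rden.constant_part() - rnum * lden.constant_part()
    return poly


def load_model(spec: Mapping | str | Path) -> OdeModel:
    """Build a validated :class:`OdeModel` from a config mapping or file.

    The config is flat JSON/TOML with keys ``name``, ``states``, ``params``,
    ``inputs``, ``outputs``, ``odes`` (state -> expression), ``output_exprs``
    (output -> expression) and optional ``constraints``.  ``^`` and ``**``
    are both accepted for powers.
    """
    if isinstance(spec, (str, Path)):
        path = Path(spec)
        if path.suffix == ".toml":
            import tomllib

            spec = tomllib.loads(path.read_text())
        else:
            spec = json.loads(path.read_text())

    states = list(spec["states"])
    params = list(spec["params"])
    inputs = list(spec.get("inputs", []))
    outputs = list(spec["outputs"])
    allowed = states + params + inputs
    odes = spec["odes"]
    missing = [s for s in states if s not in odes]
    if missing:
        raise ValueError(f"missing ODE right-hand side for state(s) {missing}")
    rhs = [_parse_rational(odes[s], allowed) for s in states]
    out_allowed = states + params
    output_exprs = [_parse_rational(spec["output_exprs"][y], out_allowed) for y in outputs]
    constraints = [_parse_constraint(c, states) for c in spec.get("constraints", [])]
    return OdeModel(
        name=spec.get("name", "model"),
        states=states,
        params=params,
        inputs=inputs,
        outputs=outputs,
        rhs=rhs,
        output_exprs=output_exprs,
        initial_constraints=constraints,
    )


def fixture(name: str, constraints: Sequence[str] | None = None) -> OdeModel:
    """Load one of the bundled benchmark models by name."""
    name = FIXTURE_ALIASES.get(name, name)
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    spec = json.loads((_DATA_DIR / f"{name}.json").read_text())
    if constraints:
        spec = dict(spec)
        spec["constraints"] = list(spec.get("constraints", [])) + list(constraints)
    return load_model(spec)


# ---------------------------------------------------------------------------
# jet systems
# ---------------------------------------------------------------------------


@dataclass
class JetSystem:
    """The truncated polynomial system F_r with blocks G_0, ..., G_r.

    Block ``G_j`` holds one polynomial per state (coefficient of t^j of the
    denominator-cleared ``rhs - x'``, contributing ``-x.(j+1)``) and one per
    output (``y.j`` matched against the jet of g).  Initial constraints, when
    present, are additional linear equations on the order-0 state jets and
    are kept separate from the blocks so that F_r is a prefix of F_{r+1}.
    """

    model: OdeModel
    order: int
    blocks: list[list[Poly]]
    constraint_equations: list[Poly]

    @property
    def param_names(self) -> list[str]:
        return list(self.model.params)

    @property
    def state_jet_names(self) -> list[str]:
        return [
            jet_name(s, j) for j in range(self.order + 2) for s in self.model.states
        ]

    @property
    def input_jet_names(self) -> list[str]:
        return [jet_name(u, j) for j in range(self.order + 1) for u in self.model.inputs]

    @property
    def output_jet_names(self) -> list[str]:
        return [jet_name(y, j) for j in range(self.order + 1) for y in self.model.outputs]

    @property
    def variables(self) -> list[str]:
        return (
            self.param_names
            + self.state_jet_names
            + self.input_jet_names
            + self.output_jet_names
        )

    @property
    def held_fixed(self) -> list[str]:
        return self.input_jet_names + self.output_jet_names

    @property
    def free_variables(self) -> list[str]:
        return self.param_names + self.state_jet_names

    @property
    def n_free(self) -> int:
        """N_r: parameter plus state-jet variable count with u, y held fixed."""
        return len(self.free_variables)

    @property
    def equations(self) -> list[Poly]:
        eqs = [eq for block in self.blocks for eq in block]
        eqs.extend(self.constraint_equations)
        return eqs

    def compiled(self) -> CompiledSystem:
        return CompiledSystem(self.equations, self.variables)


@dataclass
class JetPoint:
    """A numeric point on F_r = 0, deterministic given the generator."""

    system: JetSystem
    assignment: dict[str, complex]
    residual: float

    def vector(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = self.system.variables if names is None else names
        return np.array([self.assignment[n] for n in names], dtype=complex)


def truncate(model: OdeModel, r: int) -> JetSystem:
    """Build the order-r jet system F_r by truncated power-series arithmetic."""
    if r < 0:
        raise ValueError("truncation order must be nonnegative")
    env: dict[str, TaylorSeries] = {}
    for s in model.states:
        env[s] = TaylorSeries.from_jets([jet_name(s, j) for j in range(r + 2)])
    for u in model.inputs:
        env[u] = TaylorSeries.from_jets([jet_name(u, j) for j in range(r + 1)])
    for p in model.params:
        env[p] = TaylorSeries.constant(Poly.var(p), r + 1)

    blocks: list[list[Poly]] = [[] for _ in range(r + 1)]
    for s, (num, den) in zip(model.states, model.rhs):
        num_s = poly_series(num, env, r)
        den_s = poly_series(den, env, r + 1)
        xdot = env[s].derivative()  # coefficients x.(j+1)
        lhs = TaylorSeries(den_s.coeffs[: r + 1]) * xdot
        for j in range(r + 1):
            blocks[j].append(num_s.coeffs[j] - lhs.coeffs[j])
    for y, (num, den) in zip(model.outputs, model.output_exprs):
        yser = TaylorSeries.from_jets([jet_name(y, j) for j in range(r + 1)])
        num_s = poly_series(num, env, r)
        den_s = poly_series(den, env, r)
        lhs = den_s * yser
        for j in range(r + 1):
            blocks[j].append(lhs.coeffs[j] - num_s.coeffs[j])

    constraint_eqs = [
        c.subs({s: Poly.var(jet_name(s, 0)) for s in model.states})
        for c in model.initial_constraints
    ]
    return JetSystem(model=model, order=r, blocks=blocks, constraint_equations=constraint_eqs)


def random_complex(rng: np.random.Generator, n: int) -> np.ndarray:
    """Generic complex samples: a+bi with a, b uniform on [-1, 1], |z| >= 0.1."""
    out = np.empty(n, dtype=complex)
    for i in range(n):
        while True:
            a, b = rng.uniform(-1.0, 1.0, 2)
            z = complex(a, b)
            if abs(z) >= 0.1:
                out[i] = z
                break
    return out


def _solve_linear_in(eq: Poly, var: str, env: dict[str, complex]) -> complex:
    """Solve eq = 0 for ``var``, with eq linear in ``var`` and env complete otherwise."""
    coeff = complex(eq.diff(var).to_numeric().eval(env))
    if abs(coeff) < 1e-12:
        raise ArithmeticError(f"vanishing pivot while solving for {var}")
    env0 = dict(env)
    env0[var] = 0.0
    rest = complex(eq.to_numeric().eval(env0))
    return -rest / coeff


def seed_point(
    jetsys: JetSystem,
    rng: np.random.Generator,
    *,
    params: Sequence[complex] | None = None,
    max_retries: int = 20,
) -> JetPoint:
    """Generic point on F_r = 0 by random sampling plus forward recursion.

    Parameters, order-0 states (projected onto the initial constraints) and
    input jets are drawn at random; every higher state jet and every output
    jet is then the unique solution of its block equation.
    """
    model = jetsys.model
    r = jetsys.order
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            env: dict[str, complex] = {}
            pvals = (
                np.asarray(params, dtype=complex)
                if params is not None
                else random_complex(rng, len(model.params))
            )
            for p, v in zip(model.params, pvals):
                env[p] = complex(v)
            x0 = random_complex(rng, len(model.states))
            if jetsys.constraint_equations:
                x0 = _project_onto_constraints(model, x0)
            for s, v in zip(model.states, x0):
                env[jet_name(s, 0)] = complex(v)
            for u in model.inputs:
                for j, v in enumerate(random_complex(rng, r + 1)):
                    env[jet_name(u, j)] = complex(v)
            n_states = len(model.states)
            for j in range(r + 1):
                block = jetsys.blocks[j]
                for i, s in enumerate(model.states):
                    var = jet_name(s, j + 1)
                    env[var] = _solve_linear_in(block[i], var, env)
                for i, y in enumerate(model.outputs):
                    var = jet_name(y, j)
                    env[var] = _solve_linear_in(block[n_states + i], var, env)
            residual = _relative_residual(jetsys, env)
            if residual > 1e-10:
                raise ArithmeticError(f"seed residual {residual:.2e} too large")
            return JetPoint(system=jetsys, assignment=env, residual=residual)
        except ArithmeticError as exc:
            last_err = exc
            continue
    raise ArithmeticError(f"could not seed a generic jet point: {last_err}")


def _project_onto_constraints(model: OdeModel, x0: np.ndarray) -> np.ndarray:
    rows = []
    rhs = []
    for c in model.initial_constraints:
        row = np.array(
            [complex(c.diff(s).constant_part()) for s in model.states], dtype=complex
        )
        rows.append(row)
        rhs.append(-complex(c.constant_part()))
    A = np.array(rows)
    b = np.array(rhs)
    correction = A.conj().T @ np.linalg.solve(A @ A.conj().T, A @ x0 - b)
    out = x0 - correction
    # enforce exact zeros for pure coordinate constraints such as x3(0) = 0
    for c, bi in zip(model.initial_constraints, b):
        nz = [s for s in model.states if not c.diff(s).is_zero()]
        if len(nz) == 1 and bi == 0:
            out[model.states.index(nz[0])] = 0.0
    return out


def _relative_residual(jetsys: JetSystem, env: Mapping[str, complex]) -> float:
    worst = 0.0
    for eq in jetsys.equations:
        num = eq.to_numeric()
        val = abs(complex(num.eval(env)))
        scale = max(
            (abs(complex(c)) * _mono_mag(m, env) for m, c in num.terms.items()),
            default=1.0,
        )
        worst = max(worst, val / max(scale, 1.0))
    return worst


def _mono_mag(mono, env) -> float:
    out = 1.0
    for v, e in mono:
        out *= abs(env[v]) ** e
    return out
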