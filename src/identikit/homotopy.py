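"""Predictor-corrector path tracking, total-degree solving, linear slices.

The tracker follows solution curves of a homotopy H(z, t) = 0 from t = 1 to
t = 0 with an RK4 predictor on the Davidenko ODE dz/dt = -H_z^{-1} H_t and a
Newton corrector, halving the step on corrector failure and growing it after
runs of successes.  Endpoints are polished by Newton at t = 0.

Start systems are total-degree (Bezout) products x_i^{d_i} = b_i combined
with the gamma trick: the convex combination is twisted by a random
unit-modulus constant so that, with probability one, no path crosses the
discriminant for t in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .model_core import random_complex
from .numerics import DEFAULT_CLUSTER_TOL, cluster_points
from .poly import CompiledSystem, Poly

Converged = "converged"
Diverged = "diverged"
Singular = "singular"
StepLimit = "step-limit"


@dataclass
class PathSettings:
    initial_step: float = 0.05
    min_step: float = 1e-8
    newton_tol: float = 1e-9
    max_newton: int = 3
    endpoint_tol: float = 1e-10
    max_steps: int = 10_000
    divergence_bound: float = 1e8
    step_growth_after: int = 5

    def __post_init__(self) -> None:
        if not self.min_step < self.initial_step:
            raise ValueError("min step must be below initial step")
        if self.newton_tol <= 0 or self.endpoint_tol <= 0:
            raise ValueError("tolerances must be positive")

    def tightened(self, factor: float = 100.0) -> "PathSettings":
        return replace(
            self,
            newton_tol=self.newton_tol / factor,
            endpoint_tol=self.endpoint_tol,
            initial_step=self.initial_step / 4,
            min_step=self.min_step / factor,
        )


@dataclass
class TrackResult:
    endpoint: np.ndarray
    status: str
    residual: float
    steps_taken: int

    @property
    def ok(self) -> bool:
        return self.status == Converged


# ---------------------------------------------------------------------------
# homotopies
# ---------------------------------------------------------------------------


class ParametricHomotopy:
    """H(z, t) = F(z, theta(t)) for a compiled system over (z, theta).

    ``path`` maps t in [0, 1] to (theta values, d theta / d t).
    """

    def __init__(
        self,
        system: CompiledSystem,
        n_z: int,
        path: Callable[[float], tuple[np.ndarray, np.ndarray]],
    ):
        self.system = system
        self.n_z = n_z
        self.path = path

    def _full(self, z: np.ndarray, t: float) -> np.ndarray:
        theta, _ = self.path(t)
        return np.concatenate([z, theta])

    def values(self, z: np.ndarray, t: float) -> np.ndarray:
        return self.system.values(self._full(z, t))

    def jac_and_dt(self, z: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        theta, dtheta = self.path(t)
        full = np.concatenate([z, theta])
        vals, jac = self.system.values_and_jacobian(full)
        jz = jac[:, : self.n_z]
        ht = jac[:, self.n_z :] @ dtheta
        return vals, jz, ht


class ConvexCombinationHomotopy:
    """H(z, t) = gamma * t * G(z) + (1 - t) * F(z) (target F at t = 0)."""

    def __init__(self, target: CompiledSystem, start: CompiledSystem, gamma: complex):
        self.target = target
        self.start = start
        self.gamma = gamma

    def values(self, z: np.ndarray, t: float) -> np.ndarray:
        return self.gamma * t * self.start.values(z) + (1 - t) * self.target.values(z)

    def jac_and_dt(self, z: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        fv, fj = self.target.values_and_jacobian(z)
        gv, gj = self.start.values_and_jacobian(z)
        vals = self.gamma * t * gv + (1 - t) * fv
        jz = self.gamma * t * gj + (1 - t) * fj
        ht = self.gamma * gv - fv
        return vals, jz, ht


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def _newton(h, z: np.ndarray, t: float, tol: float, iters: int) -> tuple[np.ndarray, bool]:
    for _ in range(iters):
        vals, jz, _ = h.jac_and_dt(z, t)
        try:
            dz = np.linalg.solve(jz, vals)
        except np.linalg.LinAlgError:
            return z, False
        z = z - dz
        if np.linalg.norm(dz) < tol * (1 + np.linalg.norm(z)):
            return z, True
    return z, False


def _residual(h, z: np.ndarray, t: float) -> float:
    vals = h.values(z, t)
    return float(np.max(np.abs(vals)) / max(1.0, np.linalg.norm(z)))


def track(h, start: np.ndarray, settings: PathSettings | None = None) -> TrackResult:
    """Track H(z, t) = 0 from (start, t=1) to t = 0."""
    s = settings or PathSettings()
    z = np.asarray(start, dtype=complex).copy()
    t = 1.0
    step = s.initial_step
    steps = 0
    ok_run = 0

    def tangent(zz: np.ndarray, tt: float) -> np.ndarray | None:
        _, jz, ht = h.jac_and_dt(zz, tt)
        try:
            return -np.linalg.solve(jz, ht)
        except np.linalg.LinAlgError:
            return None

    while t > 1e-14:
        if steps >= s.max_steps:
            return TrackResult(z, StepLimit, _residual(h, z, t), steps)
        step = min(step, t)
        # RK4 predictor on the Davidenko ODE, moving t downward
        dt = -step
        k1 = tangent(z, t)
        pred = None
        if k1 is not None:
            k2 = tangent(z + 0.5 * dt * k1, t + 0.5 * dt)
            if k2 is not None:
                k3 = tangent(z + 0.5 * dt * k2, t + 0.5 * dt)
                if k3 is not None:
                    k4 = tangent(z + dt * k3, t + dt)
                    if k4 is not None:
                        pred = z + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        accepted = False
        if pred is not None and np.all(np.isfinite(pred)):
            corrected, ok = _newton(h, pred, t - step, s.newton_tol, s.max_newton)
            if ok and np.all(np.isfinite(corrected)):
                z = corrected
                t -= step
                accepted = True
        steps += 1
        if accepted:
            ok_run += 1
            if ok_run >= s.step_growth_after:
                step = min(step * 2, s.initial_step * 4)
                ok_run = 0
        else:
            step *= 0.5
            ok_run = 0
            if step < s.min_step:
                return TrackResult(z, Singular, _residual(h, z, t), steps)
        if np.linalg.norm(z) > s.divergence_bound:
            return TrackResult(z, Diverged, _residual(h, z, t), steps)

    # endpoint polish at t = 0
    z, ok = _newton(h, z, 0.0, s.endpoint_tol / 10, 12)
    res = _residual(h, z, 0.0)
    if ok and res <= s.endpoint_tol and np.all(np.isfinite(z)):
        return TrackResult(z, Converged, res, steps)
    if np.linalg.norm(z) > s.divergence_bound:
        return TrackResult(z, Diverged, res, steps)
    return TrackResult(z, Singular, res, steps)


# ---------------------------------------------------------------------------
# total-degree solving
# ---------------------------------------------------------------------------


def total_degree_solve(
    equations: Sequence[Poly],
    variables: Sequence[str],
    rng: np.random.Generator,
    settings: PathSettings | None = None,
    *,
    cluster_tol: float = DEFAULT_CLUSTER_TOL,
    report: dict | None = None,
) -> list[np.ndarray]:
    """All isolated nonsingular solutions of a square polynomial system.

    Tracks the full Bezout count of paths from the start system
    x_i^{d_i} = b_i.  Endpoints that fail to converge (diverging to infinity
    or hitting singularities) are discarded; duplicate endpoints from
    distinct paths are re-tracked at tighter tolerance before deduplication.
    """
    if len(equations) != len(variables):
        raise ValueError("total-degree solving needs a square system")
    s = settings or PathSettings()
    n = len(variables)
    degrees = [max(eq.total_degree(), 1) for eq in equations]
    target = CompiledSystem(list(equations), list(variables))
    b = random_complex(rng, n)
    start_eqs = [Poly.var(v) ** d - Poly.const(bi) for v, d, bi in zip(variables, degrees, b)]
    start_sys = CompiledSystem(start_eqs, list(variables))
    gamma = np.exp(2j * np.pi * rng.uniform())
    h = ConvexCombinationHomotopy(target, start_sys, gamma)

    roots = [
        [bi ** (1.0 / d) * np.exp(2j * np.pi * k / d) for k in range(d)]
        for bi, d in zip(b, degrees)
    ]
    import itertools

    starts = [np.array(combo, dtype=complex) for combo in itertools.product(*roots)]
    results = [track(h, st, s) for st in starts]
    good = [(i, r) for i, r in enumerate(results) if r.ok]
    # flag paths that landed on top of each other and re-run them tighter
    if good:
        groups = cluster_points([r.endpoint for _, r in good], cluster_tol)
        flagged = [g for g in groups if len(g) > 1]
        if flagged:
            tight = s.tightened()
            for g in flagged:
                for gi in g:
                    idx = good[gi][0]
                    results[idx] = track(h, starts[idx], tight)
            good = [(i, r) for i, r in enumerate(results) if r.ok]
    endpoints = [r.endpoint for _, r in good]
    statuses = [r.status for r in results]
    if report is not None:
        report["paths"] = len(starts)
        report["status_counts"] = {st: statuses.count(st) for st in set(statuses)}
    if not endpoints:
        return []
    groups = cluster_points(endpoints, cluster_tol)
    return [endpoints[g[0]] for g in groups]


# ---------------------------------------------------------------------------
# linear slices
# ---------------------------------------------------------------------------


@dataclass
class LinearSlice:
    """Affine-linear slice A z = b of the ambient space."""

    coefficient_matrix: np.ndarray
    constants: np.ndarray

    def __post_init__(self) -> None:
        self.coefficient_matrix = np.asarray(self.coefficient_matrix, dtype=complex)
        self.constants = np.asarray(self.constants, dtype=complex)
        if self.coefficient_matrix.ndim != 2:
            raise ValueError("coefficient matrix must be 2-d")
        if np.linalg.matrix_rank(self.coefficient_matrix) < self.codimension:
            raise ValueError("slice rows must be linearly independent")

    @property
    def codimension(self) -> int:
        return self.coefficient_matrix.shape[0]

    @property
    def ambient(self) -> int:
        return self.coefficient_matrix.shape[1]

    def residual(self, point: np.ndarray) -> float:
        point = np.asarray(point, dtype=complex)
        return float(np.max(np.abs(self.coefficient_matrix @ point - self.constants)))

    def equations(self, variables: Sequence[str]) -> list[Poly]:
        out = []
        for row, c in zip(self.coefficient_matrix, self.constants):
            out.append(Poly.linear(dict(zip(variables, row)), -c))
        return out


def random_slice_through(
    point: Sequence[complex], codimension: int, rng: np.random.Generator
) -> LinearSlice:
    point = np.asarray(point, dtype=complex)
    if codimension > point.shape[0]:
        raise ValueError("codimension exceeds ambient dimension")
    A = random_complex(rng, codimension * point.shape[0]).reshape(codimension, -1)
    return LinearSlice(A, A @ point)


def slice_move_homotopy(
    constraints: Sequence[Poly],
    variables: Sequence[str],
    slice_from: LinearSlice,
    slice_to: LinearSlice,
) -> ParametricHomotopy:
    """Homotopy {constraints = 0, t * slice_from + (1-t) * slice_to = 0}."""
    n = len(variables)
    tvar = "_t"
    while tvar in variables:
        tvar = "_" + tvar
    tpoly = Poly.var(tvar)
    eqs = list(constraints)
    from_rows = slice_from.equations(variables)
    to_rows = slice_to.equations(variables)
    if len(from_rows) != len(to_rows):
        raise ValueError("slices must have equal codimension")
    for fr, to in zip(from_rows, to_rows):
        eqs.append(tpoly * fr + (1 - tpoly) * to)
    system = CompiledSystem(eqs, list(variables) + [tvar])

    def path(t: float) -> tuple[np.ndarray, np.ndarray]:
        return np.array([t], dtype=complex), np.array([1.0], dtype=complex)

    return ParametricHomotopy(system, n, path)


def move_slice(
    constraints: Sequence[Poly],
    variables: Sequence[str],
    point: Sequence[complex],
    slice_from: LinearSlice,
    slice_to: LinearSlice,
    settings: PathSettings | None = None,
) -> TrackResult:
    """Track a point on {constraints} ∩ slice_from to {constraints} ∩ slice_to."""
    h = slice_move_homotopy(constraints, variables, slice_from, slice_to)
    start = np.asarray(point, dtype=complex)
    if slice_from.residual(start) > 1e-6:
        raise ValueError("start point does not satisfy the source slice")
    return track(h, start, settings)


def loop_homotopy(
    constraints: Sequence[Poly],
    variables: Sequence[str],
    base_slice: LinearSlice,
    direction: np.ndarray,
) -> ParametricHomotopy:
    """Monodromy loop: the slice constants traverse s(t) = 1 - e^{2 pi i (1-t)}.

    The loop starts and ends at ``base_slice`` (s(1) = s(0) = 0) and sweeps
    the constants along ``base_slice.constants + s(t) * direction``.
    """
    n = len(variables)
    svar = "_s"
    eqs = list(constraints)
    spoly = Poly.var(svar)
    for row, c, d in zip(
        base_slice.coefficient_matrix, base_slice.constants, np.asarray(direction)
    ):
        eqs.append(Poly.linear(dict(zip(variables, row)), -c) - spoly * complex(d))
    system = CompiledSystem(eqs, list(variables) + [svar])

    def path(t: float) -> tuple[np.ndarray, np.ndarray]:
        phase = np.exp(2j * np.pi * (1 - t))
        s = 1 - phase
        ds = 2j * np.pi * phase  # d s / d t
        return np.array([s], dtype=complex), np.array([ds], dtype=complex)

    return ParametricHomotopy(system, n, path)
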