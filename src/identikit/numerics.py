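"""Numeric rank and corank decisions, Jacobian evaluation, point clustering.

Dimension computations throughout the toolkit reduce to coranks of Jacobian
matrices at generic complex points.  Ranks are decided from singular values
with an explicit relative threshold; an ambiguity guard recomputes the SVD
in higher precision when any singular value falls close to the cut, so that
integer corank decisions rest on a clean spectral gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .poly import CompiledSystem

DEFAULT_RANK_TOL = 1e-8
DEFAULT_CLUSTER_TOL = 1e-6
_AMBIGUITY_FACTOR = 100.0


@dataclass
class RankReport:
    """Rank/corank of the last (N - column_offset) columns of a matrix."""

    rank: int
    corank: int
    singular_values: list[float]
    tolerance_used: float
    column_offset: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "rank": self.rank,
                "corank": self.corank,
                "singular_values": self.singular_values,
                "tolerance_used": self.tolerance_used,
                "column_offset": self.column_offset,
            }
        )


def jacobian_at(
    system: CompiledSystem,
    point: Sequence[complex],
    *,
    held_fixed: Sequence[str] = (),
) -> np.ndarray:
    """Jacobian of a compiled system at a point, excluding held-fixed columns."""
    z = np.asarray(point, dtype=complex)
    if z.shape[0] != system.n_var:
        raise ValueError(f"point has {z.shape[0]} coordinates, system expects {system.n_var}")
    jac = system.jacobian(z)
    if held_fixed:
        fixed = set(held_fixed)
        keep = [i for i, v in enumerate(system.variables) if v not in fixed]
        jac = jac[:, keep]
    if not np.all(np.isfinite(jac)):
        bad = int(np.argwhere(~np.isfinite(jac).all(axis=1))[0][0])
        raise ArithmeticError(f"Jacobian not finite at equation index {bad}")
    return jac


def numeric_corank(
    matrix: np.ndarray,
    j: int = 0,
    tol: float = DEFAULT_RANK_TOL,
) -> RankReport:
    """Corank of the last (N - j) columns, decided at relative threshold ``tol``.

    Rank is invariant under scaling rows and columns by nonzero constants, so
    the block is equilibrated (rows then columns normalised to unit maximum)
    before the SVD; jet-system Jacobians otherwise span a factorially wide
    dynamic range.  A singular value counts toward the rank when it exceeds
    ``tol * sigma_max``.  If any singular value lies within a factor 100 of
    the cut on a small matrix, the SVD is repeated at 40-digit precision
    before the decision is made.
    """
    matrix = np.asarray(matrix, dtype=complex)
    if j > matrix.shape[1]:
        raise ValueError("column offset exceeds column count")
    block = matrix[:, j:]
    ncols = block.shape[1]
    if ncols == 0 or block.shape[0] == 0:
        return RankReport(
            rank=0, corank=ncols, singular_values=[], tolerance_used=tol, column_offset=j
        )
    block = _equilibrate(block)
    sv = np.linalg.svd(block, compute_uv=False)
    if sv[0] == 0:
        return RankReport(
            rank=0,
            corank=ncols,
            singular_values=[0.0] * len(sv),
            tolerance_used=tol,
            column_offset=j,
        )
    cut = tol * sv[0]
    rank = int(np.sum(sv > cut))
    ambiguous = bool(np.any((sv > cut / _AMBIGUITY_FACTOR) & (sv < cut * _AMBIGUITY_FACTOR)))
    if ambiguous:
        # A singular value near the fixed cut makes the threshold decision
        # unreliable.  Numerically zero singular values sit many orders
        # below the genuine ones, so look for a decisive spectral gap; the
        # smallest genuine singular values of large jet systems drift toward
        # the cut while true zeros stay at the numerical floor.
        gap_rank = _gap_rank(sv)
        if gap_rank is not None:
            rank = gap_rank
        elif max(block.shape) <= 80:
            sv = _svd_highprec(block)
            cut = tol * sv[0] if sv[0] > 0 else tol
            rank = int(np.sum(sv > cut))
    return RankReport(
        rank=rank,
        corank=ncols - rank,
        singular_values=[float(s) for s in sv],
        tolerance_used=tol,
        column_offset=j,
    )


_GAP_FACTOR = 1e6
_GAP_CEILING = 1e-4


def _gap_rank(sv: np.ndarray) -> int | None:
    """Rank from the sharpest spectral gap, or None when no decisive gap exists.

    Only gaps whose lower edge lies below ``1e-4 * sigma_max`` qualify (a wide
    gap between two large singular values says nothing about rank), and the
    ratio across the gap must exceed 1e6.  Trailing zeros count as an
    infinite gap.
    """
    smax = sv[0]
    best_i, best_ratio = None, _GAP_FACTOR
    for i in range(len(sv) - 1):
        lo = sv[i + 1]
        if lo > _GAP_CEILING * smax:
            continue
        if sv[i] == 0:
            continue
        ratio = np.inf if lo == 0 else sv[i] / lo
        if ratio > best_ratio:
            best_i, best_ratio = i, ratio
    if best_i is None:
        # no decisive gap: a tail that is still clearly above the numerical
        # floor contains no true zeros, hence full rank
        if sv[-1] > 1e-10 * smax:
            return len(sv)
        return None
    return best_i + 1


def _equilibrate(block: np.ndarray) -> np.ndarray:
    out = block.copy()
    for axis in (1, 0):
        mags = np.max(np.abs(out), axis=axis, keepdims=True)
        mags[mags == 0] = 1.0
        out = out / mags
    return out


def _svd_highprec(block: np.ndarray, dps: int = 40) -> np.ndarray:
    import mpmath

    with mpmath.workdps(dps):
        m = mpmath.matrix([[mpmath.mpc(v) for v in row] for row in block.tolist()])
        sv = mpmath.svd_c(m, compute_uv=False)
        return np.array([float(s) for s in sv], dtype=float)


def corank_profile(
    system: CompiledSystem,
    point: Sequence[complex],
    offsets: Sequence[int],
    *,
    held_fixed: Sequence[str] = (),
    tol: float = DEFAULT_RANK_TOL,
) -> list[RankReport]:
    jac = jacobian_at(system, point, held_fixed=held_fixed)
    return [numeric_corank(jac, j, tol) for j in offsets]


def cluster_points(
    points: Sequence[np.ndarray],
    tol: float = DEFAULT_CLUSTER_TOL,
) -> list[list[int]]:
    """Group points by transitive closure of relative distance < tol.

    Group order is stable: groups are sorted by their first member index.
    """
    pts = [np.atleast_1d(np.asarray(p, dtype=complex)) for p in points]
    n = len(pts)
    if n == 0:
        return []
    dim = pts[0].shape[0]
    for p in pts:
        if p.shape[0] != dim:
            raise ValueError("points must share a dimension")
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for k in range(i + 1, n):
            scale = max(np.linalg.norm(pts[i]), np.linalg.norm(pts[k]), 1.0)
            if np.linalg.norm(pts[i] - pts[k]) < tol * scale:
                ri, rk = find(i), find(k)
                if ri != rk:
                    parent[max(ri, rk)] = min(ri, rk)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def dedupe_points(
    points: Sequence[np.ndarray], tol: float = DEFAULT_CLUSTER_TOL
) -> list[np.ndarray]:
    """One representative (the first) per cluster."""
    pts = list(points)
    return [pts[g[0]] for g in cluster_points(pts, tol)]
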