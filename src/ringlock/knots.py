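"""Knotted/unknotted classification of closed polygonal curves.

Pipeline: KMT chain simplification (vertex elision with unobstructed
triangles, knot-type preserving), projection along a generic random
direction into a crossing diagram, and the Alexander polynomial evaluated
at ``t = -1`` and ``t = -2``.

The Alexander polynomial is computed *exactly*: the (n-1)x(n-1) minor of the
crossing/arc matrix has entries linear in ``t``, so its determinant is found
by integer fraction-free (Bareiss) evaluation at integer points followed by
exact interpolation.  The unit ``+-t^k`` is stripped before evaluation, which
makes ``|Delta(-2)|`` well defined (a direct numeric evaluation at ``-2``
would leave a power-of-two ambiguity).  The unknot yields ``(1, 1)``; any
pair other than ``(1, 1)`` certifies a knot.  Alexander-trivial knots (none
arise from the low-complexity closures produced here) would be missed — a
documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .melt_io import RinglockError

__all__ = [
    "ProjectionDegeneracyError",
    "KnotComputationError",
    "PlanarDiagram",
    "KnotInvariant",
    "kmt_simplify",
    "project_diagram",
    "alexander_magnitudes",
    "is_knotted",
]

_TOL = 1e-9
DEFAULT_RETRIES = 20


class ProjectionDegeneracyError(RinglockError):
    """Projection direction not generic; caller should retry with a new one."""


class KnotComputationError(RinglockError):
    """All projection retries were degenerate (surfaces as indeterminate)."""


@dataclass(frozen=True)
class Crossing:
    over_edge: int
    under_edge: int
    over_param: float
    under_param: float
    sign: int


@dataclass(frozen=True)
class PlanarDiagram:
    """Crossing diagram of a closed curve projected along ``direction``."""

    crossings: tuple[Crossing, ...]
    n_edges: int
    direction: np.ndarray

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)


@dataclass(frozen=True)
class KnotInvariant:
    """``(|Delta(-1)|, |Delta(-2)|)`` plus the simplified crossing count."""

    det_minus1: int
    det_minus2: int
    n_crossings: int

    @property
    def is_trivial(self) -> bool:
        return self.det_minus1 == 1 and self.det_minus2 == 1


# ---------------------------------------------------------------------------
# KMT simplification
# ---------------------------------------------------------------------------


def _segments_cross_triangle(
    tri: np.ndarray, p0: np.ndarray, p1: np.ndarray, skip_vertex: np.ndarray
) -> np.ndarray:
    """Which segments ``p0[k]->p1[k]`` obstruct the elision triangle.

    Near-singular contacts (within ``_TOL``) count as obstructions so the
    vertex is conservatively kept.  Intersections that coincide with a
    triangle corner equal to ``skip_vertex[k]`` (a shared polygon vertex of
    an adjacent edge) are ignored.
    """
    a, b, c = tri
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn < 1e-14:  # degenerate triangle: nothing can obstruct it
        return np.zeros(len(p0), dtype=bool)
    n = n / nn
    d0 = (p0 - a) @ n
    d1 = (p1 - a) @ n
    blocked = np.zeros(len(p0), dtype=bool)

    coplanar = (np.abs(d0) < _TOL) & (np.abs(d1) < _TOL)
    near = ((np.abs(d0) < _TOL) | (np.abs(d1) < _TOL)) & ~coplanar
    opposite = ((d0 > _TOL) & (d1 < -_TOL)) | ((d0 < -_TOL) & (d1 > _TOL))
    cand = near | opposite
    if cand.any():
        idx = np.flatnonzero(cand)
        dd = d0[idx] - d1[idx]
        dd = np.where(np.abs(dd) < 1e-14, np.nan, dd)
        t = d0[idx] / dd
        x = p0[idx] + t[:, None] * (p1[idx] - p0[idx])
        bad_t = ~np.isfinite(t) | (t < -_TOL) | (t > 1 + _TOL)
        inside = _points_in_triangle(tri, x, margin=-_TOL)
        sk = skip_vertex[idx]
        has_skip = np.isfinite(sk[:, 0])
        at_skip = has_skip & (
            np.linalg.norm(x - np.where(has_skip[:, None], sk, 0.0), axis=1)
            <= 10 * _TOL
        )
        hit = ~bad_t & inside & ~at_skip
        # a vanishing depth difference among "near" candidates is a grazing
        # contact: keep the vertex conservatively
        hit |= ~np.isfinite(t) & near[idx]
        blocked[idx] = hit

    if coplanar.any():
        # in-plane 2-D clipping, scalar arithmetic (hot path for arcs)
        e1 = b - a
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        A2 = (0.0, 0.0)
        B2 = (float((b - a) @ e1), float((b - a) @ e2))
        C2 = (float((c - a) @ e1), float((c - a) @ e2))
        area2 = B2[0] * C2[1] - B2[1] * C2[0]
        if area2 < 0:
            B2, C2 = C2, B2
        edges2 = ((A2, B2), (B2, C2), (C2, A2))
        for k in np.flatnonzero(coplanar):
            q0x = float((p0[k] - a) @ e1)
            q0y = float((p0[k] - a) @ e2)
            q1x = float((p1[k] - a) @ e1)
            q1y = float((p1[k] - a) @ e2)
            lo, hi = 0.0, 1.0
            ok = True
            for (qa, qb) in edges2:
                ex, ey = qb[0] - qa[0], qb[1] - qa[1]
                f0 = ex * (q0y - qa[1]) - ey * (q0x - qa[0])
                f1 = ex * (q1y - qa[1]) - ey * (q1x - qa[0])
                df = f1 - f0
                if abs(df) < 1e-15:
                    if f0 < 0:
                        ok = False
                        break
                    continue
                t_hit = -f0 / df
                if df > 0:
                    if t_hit > lo:
                        lo = t_hit
                else:
                    if t_hit < hi:
                        hi = t_hit
                if lo >= hi:
                    ok = False
                    break
            if ok:
                seg_len = float(
                    np.sqrt((q1x - q0x) ** 2 + (q1y - q0y) ** 2)
                )
                if (hi - lo) * seg_len > 10 * _TOL:
                    blocked[k] = True
    return blocked


def _points_in_triangle(tri: np.ndarray, x: np.ndarray, margin: float = 0.0):
    """Vectorized barycentric inside test for points in the triangle plane."""
    a, b, c = tri
    v0, v1 = c - a, b - a
    v2 = x - a
    d00 = float(v0 @ v0)
    d01 = float(v0 @ v1)
    d11 = float(v1 @ v1)
    d02 = v2 @ v0
    d12 = v2 @ v1
    denom = d00 * d11 - d01 * d01
    if abs(denom) < 1e-18:
        return np.ones(len(x), dtype=bool)  # near-degenerate: conservative
    u = (d11 * d02 - d01 * d12) / denom
    v = (d00 * d12 - d01 * d02) / denom
    return (u >= margin) & (v >= margin) & (u + v <= 1 - margin)


def _point_in_triangle(tri: np.ndarray, x: np.ndarray, margin: float = 0.0) -> bool:
    return bool(_points_in_triangle(tri, x[None, :], margin)[0])


def kmt_simplify(closed_curve: np.ndarray, max_passes: int = 10_000) -> np.ndarray:
    """Iterative knot-preserving vertex elision on a closed polygon.

    A vertex is removed only when its elision triangle intersects no other
    segment of the curve; sweeps run in index order until a fixpoint.  Never
    reduces below 3 vertices.
    """
    pts = [np.asarray(p, dtype=float) for p in np.asarray(closed_curve, dtype=float)]
    if len(pts) < 3:
        raise ValueError("a closed curve needs at least 3 vertices")
    for _ in range(max_passes):
        removed_any = False
        i = 0
        while i < len(pts) and len(pts) > 3:
            n = len(pts)
            ip, inx = (i - 1) % n, (i + 1) % n
            tri = np.array([pts[ip], pts[i], pts[inx]])
            # candidate obstructing edges: all but (ip,i) and (i,inx)
            edge_ids = [e for e in range(n) if e not in (ip, i)]
            p0 = np.array([pts[e] for e in edge_ids])
            p1 = np.array([pts[(e + 1) % n] for e in edge_ids])
            skip = np.full((len(edge_ids), 3), np.nan)
            for k, e in enumerate(edge_ids):
                if (e + 1) % n == ip:  # edge ending at triangle corner ip
                    skip[k] = pts[ip]
                elif e == inx:  # edge starting at triangle corner inx
                    skip[k] = pts[inx]
            if not _segments_cross_triangle(tri, p0, p1, skip).any():
                del pts[i]
                removed_any = True
                # do not advance: the polygon shifted left at i
            else:
                i += 1
        if not removed_any:
            break
    return np.array(pts)


# ---------------------------------------------------------------------------
# projection to a crossing diagram
# ---------------------------------------------------------------------------


def _orthonormal_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise ValueError("projection direction must be nonzero")
    d = d / nd
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v, d


def project_diagram(closed_curve: np.ndarray, direction: np.ndarray) -> PlanarDiagram:
    """Crossing diagram of the curve viewed along ``direction``.

    Raises :class:`ProjectionDegeneracyError` on any non-generic incidence
    (near-parallel overlapping edges, crossings at edge endpoints, depth
    ties, coincident crossings); callers retry with a fresh direction.
    """
    P = np.asarray(closed_curve, dtype=float)
    n = len(P)
    u, v, d = _orthonormal_basis(direction)
    xy = np.column_stack([P @ u, P @ v])
    depth = P @ d

    crossings: list[Crossing] = []
    per_edge_params: dict[int, list[float]] = {}
    for i in range(n):
        p = xy[i]
        r = xy[(i + 1) % n] - p
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the wrap
            q = xy[j]
            s = xy[(j + 1) % n] - q
            denom = r[0] * s[1] - r[1] * s[0]
            scale = np.linalg.norm(r) * np.linalg.norm(s)
            if scale < 1e-15:
                raise ProjectionDegeneracyError("zero-length projected edge")
            if abs(denom) < _TOL * scale:
                # parallel; degenerate only if the supporting lines coincide
                qp = q - p
                if abs(qp[0] * r[1] - qp[1] * r[0]) < _TOL * max(scale, 1.0):
                    raise ProjectionDegeneracyError("collinear projected edges")
                continue
            qp = q - p
            t = (qp[0] * s[1] - qp[1] * s[0]) / denom
            w = (qp[0] * r[1] - qp[1] * r[0]) / denom
            if -_TOL < t < _TOL or 1 - _TOL < t < 1 + _TOL:
                if -2 * _TOL < w < 1 + 2 * _TOL and -2 * _TOL < t < 1 + 2 * _TOL:
                    raise ProjectionDegeneracyError("crossing at an edge endpoint")
                continue
            if -_TOL < w < _TOL or 1 - _TOL < w < 1 + _TOL:
                if -2 * _TOL < t < 1 + 2 * _TOL:
                    raise ProjectionDegeneracyError("crossing at an edge endpoint")
                continue
            if not (0 < t < 1 and 0 < w < 1):
                continue
            zi = depth[i] + t * (depth[(i + 1) % n] - depth[i])
            zj = depth[j] + w * (depth[(j + 1) % n] - depth[j])
            if abs(zi - zj) < _TOL:
                raise ProjectionDegeneracyError("depth tie at a crossing")
            if zi > zj:
                over_e, under_e, over_p, under_p = i, j, t, w
                d_over, d_under = r, s
            else:
                over_e, under_e, over_p, under_p = j, i, w, t
                d_over, d_under = s, r
            sgn = 1 if d_over[0] * d_under[1] - d_over[1] * d_under[0] > 0 else -1
            crossings.append(Crossing(over_e, under_e, over_p, under_p, sgn))
            for e, par in ((i, t), (j, w)):
                per_edge_params.setdefault(e, []).append(par)

    for params in per_edge_params.values():
        ps = sorted(params)
        if any(b - a < _TOL for a, b in zip(ps, ps[1:])):
            raise ProjectionDegeneracyError("coincident crossings on one edge")

    return PlanarDiagram(
        crossings=tuple(crossings), n_edges=n, direction=np.array(d)
    )


# ---------------------------------------------------------------------------
# Alexander polynomial
# ---------------------------------------------------------------------------


def _int_det_bareiss(M: list[list[int]]) -> int:
    """Exact determinant of an integer matrix (fraction-free Bareiss)."""
    n = len(M)
    if n == 0:
        return 1
    M = [row[:] for row in M]
    sign = 1
    prev = 1
    for k in range(n - 1):
        if M[k][k] == 0:
            swap = next((r for r in range(k + 1, n) if M[r][k] != 0), None)
            if swap is None:
                return 0
            M[k], M[swap] = M[swap], M[k]
            sign = -sign
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                M[i][j] = (M[i][j] * M[k][k] - M[i][k] * M[k][j]) // prev
            M[i][k] = 0
        prev = M[k][k]
    return sign * M[n - 1][n - 1]


def _interpolate_integer_poly(xs: list[int], ys: list[int]) -> list[int]:
    """Exact polynomial through ``(xs, ys)``; coefficients low-to-high."""
    m = len(xs)
    coeffs = [Fraction(0)] * m
    # Newton divided differences
    table = [Fraction(y) for y in ys]
    newton = []
    for level in range(m):
        newton.append(table[0])
        table = [
            (table[i + 1] - table[i]) / (xs[i + 1 + level] - xs[i])
            for i in range(len(table) - 1)
        ]
    # expand Newton form
    poly = [Fraction(0)] * m
    basis = [Fraction(1)] + [Fraction(0)] * (m - 1)
    for level in range(m):
        for i in range(m):
            poly[i] += newton[level] * basis[i]
        if level < m - 1:
            new_basis = [Fraction(0)] * m
            for i in range(m - 1):
                new_basis[i + 1] += basis[i]
                new_basis[i] -= basis[i] * xs[level]
            basis = new_basis
    out = []
    for c in poly:
        if c.denominator != 1:
            raise KnotComputationError("non-integer Alexander coefficients")
        out.append(int(c))
    return out


def _alexander_polynomial(diagram: PlanarDiagram) -> list[int]:
    """Normalized Alexander polynomial coefficients (low-to-high, c0 != 0)."""
    nc = diagram.n_crossings
    if nc == 0:
        return [1]

    events = []  # (edge, param, crossing index, is_over)
    for ci, c in enumerate(diagram.crossings):
        events.append((c.over_edge, c.over_param, ci, True))
        events.append((c.under_edge, c.under_param, ci, False))
    events.sort(key=lambda e: (e[0], e[1]))

    under_before = 0
    over_arc = {}
    under_arcs = {}
    for edge, par, ci, is_over in events:
        if is_over:
            over_arc[ci] = under_before % nc
        else:
            under_arcs[ci] = (under_before % nc, (under_before + 1) % nc)
            under_before += 1

    # rows: crossings; cols: arcs; entries a + b*t
    M0 = [[0] * nc for _ in range(nc)]
    M1 = [[0] * nc for _ in range(nc)]
    for ci, c in enumerate(diagram.crossings):
        k = over_arc[ci]
        i_in, i_out = under_arcs[ci]
        if c.sign > 0:
            # x_out = x_over x_in x_over^-1  ->  t*x_in + (1-t)*x_over - x_out
            M1[ci][i_in] += 1
            M0[ci][k] += 1
            M1[ci][k] -= 1
            M0[ci][i_out] -= 1
        else:
            # x_out = x_over^-1 x_in x_over  ->  x_in + (t-1)*x_over - t*x_out
            M0[ci][i_in] += 1
            M1[ci][k] += 1
            M0[ci][k] -= 1
            M1[ci][i_out] -= 1

    m = nc - 1  # delete last row and column
    if m == 0:
        return [1]
    xs = list(range(2, 2 + m + 1))
    ys = []
    for x in xs:
        Mx = [
            [M0[i][j] + x * M1[i][j] for j in range(m)] for i in range(m)
        ]
        ys.append(_int_det_bareiss(Mx))
    coeffs = _interpolate_integer_poly(xs, ys)
    while coeffs and coeffs[-1] == 0:
        coeffs.pop()
    if not coeffs:
        raise KnotComputationError("vanishing Alexander determinant")
    first = next(i for i, c in enumerate(coeffs) if c != 0)
    return coeffs[first:]


def _eval_int_poly(coeffs: list[int], x: int) -> int:
    acc = 0
    for c in reversed(coeffs):
        acc = acc * x + c
    return acc


def alexander_magnitudes(diagram: PlanarDiagram) -> KnotInvariant:
    """``(|Delta(-1)|, |Delta(-2)|)`` from the crossing diagram, exactly."""
    coeffs = _alexander_polynomial(diagram)
    d1 = abs(_eval_int_poly(coeffs, -1))
    d2 = abs(_eval_int_poly(coeffs, -2))
    if d1 % 2 == 0:
        # |Delta(-1)| is odd for every knot; an even value flags a broken
        # diagram (non-generic projection slipped through) -> retry upstream
        raise ProjectionDegeneracyError("even knot determinant: bad diagram")
    return KnotInvariant(det_minus1=d1, det_minus2=d2, n_crossings=diagram.n_crossings)


# ---------------------------------------------------------------------------
# top-level classification
# ---------------------------------------------------------------------------


def is_knotted(
    closed_curve: np.ndarray,
    n_retries: int = DEFAULT_RETRIES,
    rng: np.random.Generator | int | None = None,
) -> tuple[bool, KnotInvariant]:
    """Knotted/unknotted verdict for a closed polygonal curve.

    KMT-simplifies, then projects along seeded random directions (retrying on
    degeneracy up to ``n_retries``) and evaluates the Alexander magnitudes.
    """
    rng = np.random.default_rng(rng)
    simplified = kmt_simplify(closed_curve)
    last_err: Exception | None = None
    for _ in range(max(1, n_retries)):
        direction = rng.standard_normal(3)
        try:
            diagram = project_diagram(simplified, direction)
            inv = alexander_magnitudes(diagram)
        except ProjectionDegeneracyError as err:
            last_err = err
            continue
        return (not inv.is_trivial), inv
    raise KnotComputationError(
        f"all {n_retries} projection directions degenerate: {last_err}"
    )
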