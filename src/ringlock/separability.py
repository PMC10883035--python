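"""Linear separability of bead clouds.

Two uses: (i) the cheap pair prefilter — two rings whose bead sets can be
split by a plane are evidently disentangled; (ii) the exposed-monomer
detector — a three-monomer window of one ring is *exposed* when it is
linearly separable from all remaining monomers of the pair, and the
separating normal then serves as the outward direction of the window's
termini.

Separability is decided by a linear program (HiGHS): maximize the margin of
``w . x = c`` subject to a box constraint on the normal, with a tiny L1
tie-break so symmetric inputs get the clean axis-aligned plane.  The reported
margin is the geometric (Euclidean) margin of the plane found.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .melt_io import MeltFrame, RingTopology, minimum_image, unwrap_ring

__all__ = [
    "MIN_MARGIN",
    "SeparabilityResult",
    "ExposedSegment",
    "separating_plane",
    "candidate_pairs",
    "pair_coordinates",
    "exposed_segments",
]

#: Numerical guard on the binary separability decision, in sigma.
MIN_MARGIN = 1e-9

_L1_TIEBREAK = 1e-5  # above the HiGHS dual tolerance, so ties resolve cleanly


@dataclass(frozen=True)
class SeparabilityResult:
    """Separating plane ``w . x = c`` with normal oriented from B toward A."""

    separable: bool
    normal: np.ndarray  # unit 3-vector
    offset: float
    margin: float  # Euclidean margin, >= 0


@dataclass(frozen=True)
class ExposedSegment:
    """An exposed three-monomer window of one ring of a pair.

    ``ring_id`` is pair-local (0 = first ring, 1 = second).  Both termini
    carry the window's separating normal as their outward direction.
    """

    ring_id: int
    center_bead: int
    termini: tuple[int, int]
    outward_dirs: np.ndarray  # (2, 3), unit rows
    distance_to_pair_com: float
    margin: float


def separating_plane(
    points_a: np.ndarray, points_b: np.ndarray, min_margin: float = MIN_MARGIN
) -> SeparabilityResult:
    """Best-margin separating plane between two finite point sets.

    Solves ``max delta`` s.t. ``w.a - c >= delta``, ``c - w.b >= delta``,
    ``|w_i| <= 1``; the pair is separable iff the geometric margin of the
    optimal plane is at least ``min_margin``.
    """
    A = np.atleast_2d(np.asarray(points_a, dtype=float))
    B = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both point sets must be nonempty")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("points must be finite")

    # variables: w(3), c, delta, s(3);  minimize -delta + eps * sum(s)
    shift = 0.5 * (A.mean(axis=0) + B.mean(axis=0))  # conditioning only
    Ash, Bsh = A - shift, B - shift
    na, nb = len(Ash), len(Bsh)
    n_var = 8
    cost = np.zeros(n_var)
    cost[4] = -1.0
    cost[5:8] = _L1_TIEBREAK

    G = np.zeros((na + nb + 6, n_var))
    h = np.zeros(na + nb + 6)
    G[:na, 0:3] = -Ash
    G[:na, 3] = 1.0
    G[:na, 4] = 1.0
    G[na : na + nb, 0:3] = Bsh
    G[na : na + nb, 3] = -1.0
    G[na : na + nb, 4] = 1.0
    rows = na + nb
    for i in range(3):  # s_i >= |w_i|
        G[rows + 2 * i, i] = 1.0
        G[rows + 2 * i, 5 + i] = -1.0
        G[rows + 2 * i + 1, i] = -1.0
        G[rows + 2 * i + 1, 5 + i] = -1.0

    bounds = [(-1, 1)] * 3 + [(None, None), (None, None)] + [(0, None)] * 3
    res = linprog(cost, A_ub=G, b_ub=h, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS handles these LPs
        return SeparabilityResult(False, np.array([0.0, 0.0, 1.0]), 0.0, 0.0)

    w = res.x[0:3]
    c = res.x[3] + float(w @ shift)
    norm = float(np.linalg.norm(w))
    if norm < 1e-12:
        return SeparabilityResult(False, np.array([0.0, 0.0, 1.0]), 0.0, 0.0)
    w_unit = w / norm
    c_unit = c / norm
    margin = float(
        min((A @ w_unit).min() - c_unit, c_unit - (B @ w_unit).max())
    )
    if margin < min_margin:
        return SeparabilityResult(False, w_unit, c_unit, max(margin, 0.0))
    return SeparabilityResult(True, w_unit, c_unit, margin)


def pair_coordinates(
    frame: MeltFrame, topology: RingTopology, ring_i: int, ring_j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped coordinates of a ring pair under consistent imaging.

    Ring ``j`` is rigidly shifted by the lattice vector that brings its
    center of mass to the periodic image nearest ring ``i``'s center.
    """
    xi = unwrap_ring(frame, topology, ring_i)
    xj = unwrap_ring(frame, topology, ring_j)
    ci, cj = xi.mean(axis=0), xj.mean(axis=0)
    delta = minimum_image(cj - ci, frame.box_side)
    return xi, xj + (ci + delta - cj)


def candidate_pairs(
    frame: MeltFrame,
    topology: RingTopology,
    min_margin: float = MIN_MARGIN,
    prefilter: bool = True,
) -> list[tuple[int, int]]:
    """All distinct ring pairs that are *not* linearly separable.

    The optional bounding-sphere prefilter only skips pairs whose sphere gap
    proves separability outright; with it on or off the result is identical.
    Cut-open (linear) molecules are not tested.
    """
    ring_ids = [r for r in range(topology.n_rings) if topology.is_ring[r]]
    unwrapped = {r: unwrap_ring(frame, topology, r) for r in ring_ids}
    centers = {r: unwrapped[r].mean(axis=0) for r in ring_ids}
    radii = {
        r: float(np.linalg.norm(unwrapped[r] - centers[r], axis=1).max())
        for r in ring_ids
    }
    out = []
    for a_idx, i in enumerate(ring_ids):
        for j in ring_ids[a_idx + 1 :]:
            d = float(
                np.linalg.norm(minimum_image(centers[j] - centers[i], frame.box_side))
            )
            if prefilter and d > radii[i] + radii[j] + 1e-6:
                continue  # sphere gap > 0: provably separable
            xi, xj = pair_coordinates(frame, topology, i, j)
            if not separating_plane(xi, xj, min_margin).separable:
                out.append((i, j))
    return out


def _window(n: int, i: int) -> np.ndarray:
    return np.array([(i - 1) % n, i, (i + 1) % n])


def exposed_segments(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    min_margin: float = MIN_MARGIN,
    per_terminus: bool = False,
) -> list[ExposedSegment]:
    """Exposed three-monomer windows of both rings of a consistently imaged pair.

    For every monomer ``i`` the window ``{i-1, i, i+1}`` is tested against all
    remaining monomers of *both* rings.  Windows are cyclic and may overlap.
    With ``per_terminus`` each terminus additionally gets its own single-bead
    separating normal where one exists (falling back to the window normal).
    """
    rings = [np.asarray(coords_a, float), np.asarray(coords_b, float)]
    com = np.vstack(rings).mean(axis=0)
    out: list[ExposedSegment] = []
    for rid, X in enumerate(rings):
        other = rings[1 - rid]
        n = len(X)
        for i in range(n):
            win = _window(n, i)
            rest_mask = np.ones(n, dtype=bool)
            rest_mask[win] = False
            B = np.vstack([X[rest_mask], other])
            res = separating_plane(X[win], B, min_margin)
            if not res.separable:
                continue
            dirs = np.vstack([res.normal, res.normal])
            if per_terminus:
                for k, t in enumerate((win[0], win[2])):
                    solo_mask = np.ones(n, dtype=bool)
                    solo_mask[win] = False
                    r2 = separating_plane(
                        X[t][None, :], np.vstack([X[solo_mask], other]), min_margin
                    )
                    if r2.separable:
                        dirs[k] = r2.normal
            centroid = X[win].mean(axis=0)
            out.append(
                ExposedSegment(
                    ring_id=rid,
                    center_bead=i,
                    termini=(int(win[0]), int(win[2])),
                    outward_dirs=dirs,
                    distance_to_pair_com=float(np.linalg.norm(centroid - com)),
                    margin=res.margin,
                )
            )
    return out
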