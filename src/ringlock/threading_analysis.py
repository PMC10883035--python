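"""Ring-ring threading via spanning-surface piercing, and NtD/NtN labels.

A ring *threads* another when it passes through the surface spanning the
other ring's curve.  True minimal surfaces are replaced here by a
fan-triangulated, area-relaxed surrogate: a layered cone mesh over the ring
polygon whose interior vertices are smoothed with accept-if-area-decreases
sweeps (boundary fixed), so the total area is monotonically non-increasing.
Piercing counts on strongly non-convex rings may differ from true minimal
surfaces — a documented limitation.

For pairs of unlinked rings every transversal piercing count is even (one
in, one out); an odd count implies linkage and is flagged as a warning
rather than silently accepted.  Threading requires count >= 2.

Nondeadlocked rings are classified NtD (threaded by at least one deadlocked
ring), NtN (threaded, but only by nondeadlocked rings) or unthreaded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .melt_io import MeltFrame, RingTopology, RinglockError, unwrap_ring
from .separability import pair_coordinates

__all__ = [
    "SurfaceFailure",
    "SpanningSurface",
    "ThreadingRecord",
    "spanning_surface",
    "count_piercings",
    "threading_graph",
    "classify_nondeadlocked",
]

_TOL = 1e-9
DEFAULT_RELAX_SWEEPS = 200


class SurfaceFailure(RinglockError):
    """The ring polygon could not be spanned (self-intersecting boundary)."""


@dataclass
class SpanningSurface:
    """Triangulated spanning surface of one ring.

    ``vertices`` stacks the fixed boundary (first ``n_boundary`` rows) and
    the relaxed interior; ``triangles`` indexes into it.
    """

    vertices: np.ndarray
    triangles: np.ndarray  # (m, 3) int
    n_boundary: int
    n_relax: int

    @property
    def total_area(self) -> float:
        return float(_triangle_areas(self.vertices, self.triangles).sum())


@dataclass(frozen=True)
class ThreadingRecord:
    """Ring ``threading`` pierces the surface of ring ``threaded``."""

    threaded: int
    threading: int
    count: int


def _triangle_areas(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a, b, c = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _cone_mesh(ring: np.ndarray, n_layers: int):
    """Layered cone between the ring polygon and its centroid."""
    n = len(ring)
    centroid = ring.mean(axis=0)
    verts = [ring]
    for layer in range(1, n_layers):
        t = layer / n_layers
        verts.append(ring * (1 - t) + centroid * t)
    verts.append(centroid[None, :])
    vertices = np.vstack(verts)
    apex = len(vertices) - 1

    def vid(layer: int, i: int) -> int:
        return layer * n + (i % n)

    tris = []
    for layer in range(n_layers - 1):
        for i in range(n):
            tris.append((vid(layer, i), vid(layer, i + 1), vid(layer + 1, i)))
            tris.append((vid(layer, i + 1), vid(layer + 1, i + 1), vid(layer + 1, i)))
    top = n_layers - 1
    for i in range(n):
        tris.append((vid(top, i), vid(top, i + 1), apex))
    return vertices, np.array(tris, dtype=np.intp)


def spanning_surface(
    ring_coords: np.ndarray,
    n_relax: int = DEFAULT_RELAX_SWEEPS,
    n_layers: int = 4,
) -> SpanningSurface:
    """Area-relaxed layered-cone surface spanning a closed ring.

    Each sweep proposes moving every interior vertex to the mean of its
    mesh neighbours (Jacobi update) and accepts the sweep — possibly damped
    — only if the total area does not increase, so relaxation is monotone
    and the boundary never moves.
    """
    ring = np.asarray(ring_coords, dtype=float)
    n = len(ring)
    if n < 3:
        raise SurfaceFailure("ring needs at least 3 beads")
    vertices, tris = _cone_mesh(ring, n_layers)
    n_boundary = n

    # neighbour map for interior vertices
    nbrs: dict[int, set[int]] = {}
    for t in tris:
        for u in t:
            if u >= n_boundary:
                nbrs.setdefault(int(u), set()).update(int(v) for v in t if v != u)
    interior = np.array(sorted(nbrs), dtype=np.intp)
    nbr_lists = [np.array(sorted(nbrs[int(u)]), dtype=np.intp) for u in interior]

    area = _triangle_areas(vertices, tris).sum()
    for _ in range(n_relax):
        proposal = vertices.copy()
        for u, nb in zip(interior, nbr_lists):
            proposal[u] = vertices[nb].mean(axis=0)
        accepted = False
        for damp in (1.0, 0.5, 0.25):
            candidate = vertices + damp * (proposal - vertices)
            new_area = _triangle_areas(candidate, tris).sum()
            if new_area <= area + 1e-12:
                vertices, area = candidate, new_area
                accepted = True
                break
        if not accepted:
            break  # converged: any further averaging would grow the area
    return SpanningSurface(
        vertices=vertices, triangles=tris, n_boundary=n_boundary, n_relax=n_relax
    )


def count_piercings(
    surface: SpanningSurface,
    other_ring_coords: np.ndarray,
    max_perturb_retries: int = 3,
) -> int:
    """Transversal intersections of the other ring's bonds with the surface.

    Grazing contacts (parameters within ``1e-9`` of a boundary) are resolved
    by re-counting with a tiny deterministic offset of the other ring,
    nudging the configuration toward transversality.
    """
    other = np.asarray(other_ring_coords, dtype=float)
    shift = np.array([1.31e-7, 0.79e-7, 0.53e-7])  # fixed, incommensurate
    for attempt in range(max_perturb_retries + 1):
        count = _count_transversal(surface, other + attempt * shift)
        if count >= 0:
            return count
    # fall back to the last perturbed count even if still marginal
    return max(0, _count_transversal(surface, other + max_perturb_retries * shift))


def _count_transversal(surface: SpanningSurface, other: np.ndarray) -> int:
    """Batched segment-triangle count; -1 signals a near-degenerate contact."""
    p0 = other
    p1 = np.roll(other, -1, axis=0)
    tris = surface.triangles
    va = surface.vertices[tris[:, 0]]
    vb = surface.vertices[tris[:, 1]]
    vc = surface.vertices[tris[:, 2]]
    e1 = vb - va
    e2 = vc - va
    d = (p1 - p0)[:, None, :]  # (s, 1, 3)
    h = np.cross(d, e2[None, :, :])  # (s, m, 3)
    det = np.einsum("mj,smj->sm", e1, h)
    scale = np.linalg.norm(e1, axis=1)[None, :] * np.linalg.norm(e2, axis=1)[None, :]
    parallel = np.abs(det) < 1e-12 * np.maximum(scale, 1.0)
    det_safe = np.where(parallel, 1.0, det)
    s_vec = p0[:, None, :] - va[None, :, :]
    u = np.einsum("smj,smj->sm", s_vec, h) / det_safe
    q = np.cross(s_vec, e1[None, :, :])
    v = np.einsum("smj,smj->sm", d, q) / det_safe
    t = np.einsum("mj,smj->sm", e2, q) / det_safe
    inside = (
        ~parallel
        & (u > _TOL)
        & (v > _TOL)
        & (u + v < 1.0 - _TOL)
        & (t > _TOL)
        & (t < 1.0 - _TOL)
    )
    grazing = (
        ~parallel
        & (u > -_TOL)
        & (v > -_TOL)
        & (u + v < 1.0 + _TOL)
        & (t > -_TOL)
        & (t < 1.0 + _TOL)
        & ~inside
    )
    if grazing.any():
        return -1
    # shared internal mesh edges would double-count only if a segment passed
    # exactly through an edge - those cases are grazing and already retried
    return int(inside.sum())


def threading_graph(
    frame: MeltFrame,
    topology: RingTopology,
    n_relax: int = DEFAULT_RELAX_SWEEPS,
) -> tuple[list[ThreadingRecord], list[ThreadingRecord]]:
    """Directed threading records for all ordered ring pairs of a frame.

    Returns ``(records, warnings)``: records hold pairs with piercing count
    >= 2 (a threading); warnings hold odd counts, which for an uncatenated
    melt flag either a true link (impossible under crossing-forbidding
    dynamics) or a surface artifact.  Per-pair surface failures are skipped.
    """
    ring_ids = [r for r in range(topology.n_rings) if topology.is_ring[r]]
    unwrapped = {r: unwrap_ring(frame, topology, r) for r in ring_ids}
    centers = {r: unwrapped[r].mean(axis=0) for r in ring_ids}
    radii = {
        r: float(np.linalg.norm(unwrapped[r] - centers[r], axis=1).max())
        for r in ring_ids
    }
    surfaces: dict[int, SpanningSurface] = {}
    records: list[ThreadingRecord] = []
    warnings: list[ThreadingRecord] = []
    for i in ring_ids:
        for j in ring_ids:
            if i == j:
                continue
            from .melt_io import minimum_image

            d = float(
                np.linalg.norm(minimum_image(centers[j] - centers[i], frame.box_side))
            )
            if d > radii[i] + radii[j]:
                continue  # surface lies in ring i's hull: no contact possible
            xi, xj = pair_coordinates(frame, topology, i, j)
            try:
                if i not in surfaces:
                    surfaces[i] = spanning_surface(unwrapped[i], n_relax)
                # rebuild surface in pair imaging (ring i unchanged, xi==unwrapped[i])
                count = count_piercings(surfaces[i], xj)
            except SurfaceFailure:
                continue
            if count % 2 == 1:
                warnings.append(ThreadingRecord(threaded=i, threading=j, count=count))
            if count >= 2:
                records.append(ThreadingRecord(threaded=i, threading=j, count=count))
    return records, warnings


def classify_nondeadlocked(
    threading_records: list[ThreadingRecord],
    deadlock_edges: list[tuple[int, int]],
    n_rings: int,
) -> dict[int, str]:
    """Label each nondeadlocked ring NtD, NtN or unthreaded.

    Deadlocked rings are those incident to at least one deadlock edge.  A
    nondeadlocked ring is NtD if some deadlocked ring threads it, NtN if it
    is threaded only by nondeadlocked rings, else unthreaded.
    """
    deadlocked = set()
    for a, b in deadlock_edges:
        deadlocked.add(int(a))
        deadlocked.add(int(b))
    labels: dict[int, str] = {}
    threaders: dict[int, set[int]] = {}
    for rec in threading_records:
        threaders.setdefault(rec.threaded, set()).add(rec.threading)
    for ring in range(n_rings):
        if ring in deadlocked:
            continue
        by = threaders.get(ring, set())
        if not by:
            labels[ring] = "unthreaded"
        elif by & deadlocked:
            labels[ring] = "NtD"
        else:
            labels[ring] = "NtN"
    if set(labels) & deadlocked:
        raise RinglockError("a ring appears both deadlocked and labeled")
    return labels
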