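"""The reconnection detector for deadlocked ring pairs.

A pair that is not linearly separable is processed as follows: find the
exposed three-monomer segments of both rings; pick one segment per ring,
furthest from the pair's center of mass, whose four termini rays mutually
diverge; remove the middle monomer(s) of each segment, turning both rings
into open chains; extend each terminus radially along its outward direction
to a sphere enclosing the pair and join the sphere points pairwise with
great-circle arcs.  The two possible wirings each yield a single closed
curve; the pair is deadlocked iff both closures are knotted, free iff both
are unknotted, and indeterminate when the wirings disagree or no valid cut
exists (diagnosed, never silently resolved).

Divergence predicate (the geometric condition that lets the closure arcs be
drawn without creating new entanglement): every radial leg, beyond 1 sigma
from its terminus, must clear every bond of both chains by at least
``eps_arc`` (bonds incident to that terminus's own segment exempt), and legs
of termini from *different* segments must clear each other by ``eps_arc``
(same-segment termini share one outward normal — parallel rays — and cannot
converge).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .knots import KnotComputationError, KnotInvariant, is_knotted
from .melt_io import MeltFrame, RingTopology, RinglockError
from .separability import (
    MIN_MARGIN,
    ExposedSegment,
    exposed_segments,
    pair_coordinates,
    separating_plane,
)

__all__ = [
    "ClosureParams",
    "CutChain",
    "ClosureCurve",
    "DeadlockVerdict",
    "ClosureFailure",
    "select_cut_segments",
    "open_ring",
    "build_closures",
    "classify_pair",
    "scan_frame",
]


class ClosureFailure(RinglockError):
    """Arc clearance could not be satisfied for this cut-segment pair."""


@dataclass(frozen=True)
class ClosureParams:
    """Geometry and policy knobs of the reconnection construction."""

    eps_arc: float = 1.0  # arc-to-chain clearance, sigma (>= 1)
    r_arc_factor: float = 2.0  # sphere radius / max pair extent
    arc_step: float = 0.5  # arc discretization step, sigma
    retries: int = 1  # extra cut-segment pairs tried after a failure
    middle_width: int = 1  # beads removed at each segment center (odd)
    n_proj_retries: int = 20  # knot-engine projection retries
    min_margin: float = MIN_MARGIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eps_arc < 1.0:
            raise ValueError("eps_arc must be >= 1 sigma")
        if self.middle_width < 1 or self.middle_width % 2 == 0:
            raise ValueError("middle_width must be a positive odd integer")


@dataclass(frozen=True)
class CutChain:
    """A ring opened at an exposed segment (middle monomers removed)."""

    ring_id: int
    coords: np.ndarray  # ordered open chain
    termini_outward: np.ndarray  # (2, 3) unit rows: first, last vertex

    @property
    def termini(self) -> tuple[np.ndarray, np.ndarray]:
        return self.coords[0], self.coords[-1]


@dataclass(frozen=True)
class ClosureCurve:
    """One reconnected closed curve (chain beads plus closure-arc vertices)."""

    vertices: np.ndarray
    wiring: str  # "straight" | "crossed"
    pair_ids: tuple[int, int]
    time: float
    n_chain_beads: int


@dataclass(frozen=True)
class DeadlockVerdict:
    pair: tuple[int, int]
    verdict: str  # deadlocked | free | indeterminate
    invariants: tuple[KnotInvariant, KnotInvariant] | None = None
    agreement: bool | None = None
    time: float = 0.0
    reason: str = ""


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _segment_segment_distance(
    p0: np.ndarray, p1: np.ndarray, q0: np.ndarray, q1: np.ndarray
) -> float:
    """Minimum distance between two 3-D segments (clamped closed form)."""
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    if a < 1e-18 and e < 1e-18:
        return float(np.linalg.norm(r))
    if a < 1e-18:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e < 1e-18:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            den = a * e - b * b
            s = np.clip((b * f - c * e) / den, 0.0, 1.0) if den > 1e-18 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm(p0 + s * d1 - (q0 + t * d2)))


def _min_dist_points_to_segments(
    points: np.ndarray, s0: np.ndarray, s1: np.ndarray
) -> float:
    """Min distance from a point set to a set of segments (vectorized)."""
    if len(points) == 0 or len(s0) == 0:
        return np.inf
    d = s1 - s0  # (m, 3)
    dd = np.einsum("ij,ij->i", d, d)
    dd = np.where(dd > 1e-18, dd, 1.0)
    w = points[:, None, :] - s0[None, :, :]  # (n, m, 3)
    t = np.clip(np.einsum("nmj,mj->nm", w, d) / dd[None, :], 0.0, 1.0)
    closest = s0[None, :, :] + t[..., None] * d[None, :, :]
    return float(np.linalg.norm(points[:, None, :] - closest, axis=2).min())


def _ring_bonds(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return coords, np.roll(coords, -1, axis=0)


def _sphere_exit(p: np.ndarray, d: np.ndarray, com: np.ndarray, R: float) -> float:
    """Ray parameter where ``p + t d`` (|d|=1) exits the sphere (com, R)."""
    rel = p - com
    b = rel @ d
    c = rel @ rel - R * R
    disc = b * b - c
    if disc < 0:  # ray from inside always hits; guard anyway
        disc = 0.0
    return float(-b + np.sqrt(disc))


# ---------------------------------------------------------------------------
# cut-segment selection
# ---------------------------------------------------------------------------


def _segment_bond_exemptions(n: int, seg: ExposedSegment, width: int) -> set[int]:
    """Ring-bond indices (bond i joins beads i, i+1) incident to the window."""
    half = (width - 1) // 2
    lo, hi = seg.center_bead - half - 1, seg.center_bead + half + 1
    out = set()
    for b in range(lo - 1, hi + 1):
        out.add(b % n)
    return out


def _termini_rays(
    coords: np.ndarray, seg: ExposedSegment
) -> list[tuple[np.ndarray, np.ndarray]]:
    return [
        (coords[seg.termini[0]], seg.outward_dirs[0]),
        (coords[seg.termini[1]], seg.outward_dirs[1]),
    ]


def divergence_ok(
    seg_a: ExposedSegment,
    seg_b: ExposedSegment,
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    params: ClosureParams,
) -> bool:
    """Do the four termini rays mutually diverge (see module docstring)?"""
    com = np.vstack([coords_a, coords_b]).mean(axis=0)
    extent = float(
        np.linalg.norm(np.vstack([coords_a, coords_b]) - com, axis=1).max()
    )
    R = params.r_arc_factor * extent
    rays = []  # (point, dir, ring, segment, t_end)
    for ring, (coords, seg) in enumerate(((coords_a, seg_a), (coords_b, seg_b))):
        for p, dvec in _termini_rays(coords, seg):
            t_end = _sphere_exit(p, dvec, com, R)
            rays.append((p, dvec, ring, t_end))

    # leg clearance vs both rings' bonds (own-window bonds exempt)
    bonds = []
    for ring, (coords, seg) in enumerate(((coords_a, seg_a), (coords_b, seg_b))):
        s0, s1 = _ring_bonds(coords)
        exempt = _segment_bond_exemptions(len(coords), seg, params.middle_width)
        bonds.append((s0, s1, exempt))
    for p, dvec, ring, t_end in rays:
        if t_end <= 1.0:
            return False
        leg0, leg1 = p + 1.0 * dvec, p + t_end * dvec
        for bring, (s0, s1, exempt) in enumerate(bonds):
            for bi in range(len(s0)):
                if bring == ring and bi in exempt:
                    continue
                if (
                    _segment_segment_distance(leg0, leg1, s0[bi], s1[bi])
                    < params.eps_arc
                ):
                    return False

    # pairwise leg clearance for termini of different segments
    for (p1, d1, r1, t1), (p2, d2, r2, t2) in itertools.combinations(rays, 2):
        if r1 == r2:
            continue  # same segment: parallel rays, cannot converge
        if (
            _segment_segment_distance(
                p1 + 1.0 * d1, p1 + t1 * d1, p2 + 1.0 * d2, p2 + t2 * d2
            )
            < params.eps_arc
        ):
            return False
    return True


def select_cut_segments(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    segments: list[ExposedSegment],
    params: ClosureParams = ClosureParams(),
    skip: int = 0,
) -> tuple[ExposedSegment, ExposedSegment] | None:
    """First divergent segment pair in descending distance-to-pair-COM order.

    Candidate pairs (one exposed segment per ring) are ranked by the summed
    distance of the windows to the pair's center of mass, ties broken by
    lower (ring id, bead index); ``skip`` passes over the first matches so a
    failed closure can be retried with the next-ranked pair.
    """
    segs_a = [s for s in segments if s.ring_id == 0]
    segs_b = [s for s in segments if s.ring_id == 1]
    if not segs_a or not segs_b:
        return None
    ranked = sorted(
        itertools.product(segs_a, segs_b),
        key=lambda p: (
            -(p[0].distance_to_pair_com + p[1].distance_to_pair_com),
            p[0].center_bead,
            p[1].center_bead,
        ),
    )
    found = 0
    for sa, sb in ranked:
        if divergence_ok(sa, sb, coords_a, coords_b, params):
            if found == skip:
                return sa, sb
            found += 1
    return None


# ---------------------------------------------------------------------------
# ring opening and closure construction
# ---------------------------------------------------------------------------


def open_ring(
    ring_coords: np.ndarray, segment: ExposedSegment, width: int = 1
) -> CutChain:
    """Remove the ``width`` middle monomer(s) of the segment; return the chain.

    The chain starts at the bead after the removed run and ends at the bead
    before it, so its termini are the segment's flanking beads; each terminus
    carries the segment's outward direction.
    """
    n = len(ring_coords)
    half = (width - 1) // 2
    start = (segment.center_bead + half + 1) % n
    order = [(start + k) % n for k in range(n - width)]
    coords = ring_coords[order]
    # chain[0] is segment terminus i+1..., chain[-1] is terminus i-1
    dirs = np.vstack([segment.outward_dirs[1], segment.outward_dirs[0]])
    return CutChain(ring_id=segment.ring_id, coords=coords, termini_outward=dirs)


def _slerp(q1: np.ndarray, q2: np.ndarray, com: np.ndarray, R: float, step: float):
    """Great-circle polyline between two points on the sphere (com, R)."""
    u1 = (q1 - com) / R
    u2 = (q2 - com) / R
    cosang = float(np.clip(u1 @ u2, -1.0, 1.0))
    ang = np.arccos(cosang)
    if ang < 1e-12:
        return np.empty((0, 3))
    if ang > np.pi - 1e-9:  # antipodal: route via an arbitrary waypoint
        perp = np.cross(u1, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(u1, [0.0, 1.0, 0.0])
        mid = com + R * perp / np.linalg.norm(perp)
        first = _slerp(q1, mid, com, R, step)
        second = _slerp(mid, q2, com, R, step)
        return np.vstack([first, [mid], second]) if len(first) or len(second) else np.array([mid])
    n_pts = max(1, int(np.ceil(ang * R / step)) - 1)
    ts = np.linspace(0.0, 1.0, n_pts + 2)[1:-1]
    sin_ang = np.sin(ang)
    pts = (
        np.sin((1 - ts))[:, None] * 0.0  # placeholder, replaced below
    )
    pts = (
        (np.sin((1 - ts) * ang)[:, None] * u1 + np.sin(ts * ang)[:, None] * u2)
        / sin_ang
    )
    return com + R * pts


def _leg_vertices(p: np.ndarray, d: np.ndarray, t_end: float, step: float):
    """Vertices along a radial leg, excluding the terminus itself."""
    n_pts = max(2, int(np.ceil(t_end / step)))
    ts = np.linspace(0.0, t_end, n_pts + 1)[1:]
    return p + ts[:, None] * d


def _route_on_sphere(
    q1: np.ndarray,
    q2: np.ndarray,
    com: np.ndarray,
    R: float,
    step: float,
    avoid_pts: list[np.ndarray],
    clearance: float,
) -> np.ndarray:
    """Great-circle polyline from q1 to q2 keeping clear of piercing points.

    ``avoid_pts`` are the points where radial legs bound for a larger sphere
    pierce this one; the track must stay ``clearance`` away from them.  If
    the direct arc is too close, detour via tilted waypoints; give up with
    :class:`ClosureFailure` after a few tries.
    """

    def clear(path: np.ndarray) -> bool:
        if not avoid_pts:
            return True
        pts = np.asarray(avoid_pts)
        full = np.vstack([[q1], path, [q2]]) if len(path) else np.vstack([[q1], [q2]])
        return _min_dist_points_to_segments(pts, full[:-1], full[1:]) >= clearance

    direct = _slerp(q1, q2, com, R, step)
    if clear(direct):
        return direct
    u1 = (q1 - com) / R
    u2 = (q2 - com) / R
    mid = u1 + u2
    if np.linalg.norm(mid) < 1e-9:
        mid = np.cross(u1, [1.0, 0.0, 0.0])
    mid /= np.linalg.norm(mid)
    perp = np.cross(u1 - u2, mid)
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(mid, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    for alpha in (0.6, -0.6, 1.2, -1.2, 1.8, -1.8):
        w = mid + alpha * perp
        w = com + R * w / np.linalg.norm(w)
        path = np.vstack(
            [_slerp(q1, w, com, R, step), [w], _slerp(w, q2, com, R, step)]
        )
        if clear(path):
            return path
    raise ClosureFailure("no clear great-circle route on the closure sphere")


def build_closures(
    chain_a: CutChain,
    chain_b: CutChain,
    params: ClosureParams = ClosureParams(),
    pair_ids: tuple[int, int] = (0, 1),
    time: float = 0.0,
) -> tuple[ClosureCurve, ClosureCurve]:
    """Both reconnection closures: straight (a1-b1, a2-b2) and crossed.

    Termini are extended radially along their outward directions and joined
    by great-circle polylines.  The two arcs of one closure run on spheres
    of *different* radii (inner ``r_arc_factor x max pair extent``, outer
    ``+ 2 eps_arc + 1``) so they cannot cross each other, and the inner
    arc's track detours around the points where the outer legs pierce the
    inner sphere.  Arc clearance from both chains (beyond the 1-sigma
    junction zone, chain-end bonds exempt) is explicitly verified;
    violation raises :class:`ClosureFailure`.
    """
    all_pts = np.vstack([chain_a.coords, chain_b.coords])
    com = all_pts.mean(axis=0)
    extent = float(np.linalg.norm(all_pts - com, axis=1).max())
    R_in = params.r_arc_factor * extent
    R_out = R_in + 2.0 * params.eps_arc + 1.0

    # termini: a1 = chain_a[0], a2 = chain_a[-1], likewise b
    termini = {
        "a1": (chain_a.coords[0], chain_a.termini_outward[0]),
        "a2": (chain_a.coords[-1], chain_a.termini_outward[1]),
        "b1": (chain_b.coords[0], chain_b.termini_outward[0]),
        "b2": (chain_b.coords[-1], chain_b.termini_outward[1]),
    }

    def leg(name: str, R: float) -> tuple[np.ndarray, np.ndarray]:
        p, d = termini[name]
        t_end = _sphere_exit(p, d, com, R)
        if t_end <= 1.0:
            raise ClosureFailure(f"terminus {name}: no outward room to the sphere")
        return _leg_vertices(p, d, t_end, params.arc_step), p + t_end * d

    # clearance of every leg (at its longest) vs both chains
    chains = {"a": chain_a.coords, "b": chain_b.coords}
    for name in termini:
        vertices, _ = leg(name, R_out)
        p = termini[name][0]
        far = vertices[np.linalg.norm(vertices - p, axis=1) >= 1.0 - 1e-12]
        for key, coords in chains.items():
            s0, s1 = coords[:-1], coords[1:]
            if key == name[0]:
                # exempt the two bonds at this chain end (junction zone)
                if name.endswith("1"):
                    s0, s1 = s0[2:], s1[2:]
                else:
                    s0, s1 = s0[:-2], s1[:-2]
            if _min_dist_points_to_segments(far, s0, s1) < params.eps_arc:
                raise ClosureFailure(f"leg {name} violates eps_arc clearance")

    def closure(label: str) -> ClosureCurve:
        # cycle: chain_a a1 -> a2, inner arc a2 -> b_entry, chain b to its
        # other terminus, outer arc b_exit -> a1
        if label == "straight":  # pairs a2-b2 and a1-b1
            b_path, b_entry, b_exit = chain_b.coords[::-1], "b2", "b1"
        else:  # crossed: pairs a2-b1 and a1-b2
            b_path, b_entry, b_exit = chain_b.coords, "b1", "b2"
        leg_a2, q_a2 = leg("a2", R_in)
        leg_en, q_en = leg(b_entry, R_in)
        leg_ex, q_ex = leg(b_exit, R_out)
        leg_a1, q_a1 = leg("a1", R_out)
        pierce = []
        for outer_name in (b_exit, "a1"):
            p, d = termini[outer_name]
            pierce.append(p + _sphere_exit(p, d, com, R_in) * d)
        inner = _route_on_sphere(
            q_a2, q_en, com, R_in, params.arc_step, pierce, params.eps_arc
        )
        outer = _slerp(q_ex, q_a1, com, R_out, params.arc_step)
        verts = np.vstack(
            [
                chain_a.coords,
                leg_a2,
                inner,
                leg_en[::-1],
                b_path,
                leg_ex,
                outer,
                leg_a1[::-1],
            ]
        )
        return ClosureCurve(
            vertices=verts,
            wiring=label,
            pair_ids=pair_ids,
            time=time,
            n_chain_beads=len(chain_a.coords) + len(chain_b.coords),
        )

    return closure("straight"), closure("crossed")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_pair(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    params: ClosureParams = ClosureParams(),
    pair_ids: tuple[int, int] = (0, 1),
    time: float = 0.0,
) -> DeadlockVerdict:
    """Full reconnection pipeline for one consistently imaged ring pair."""
    if separating_plane(coords_a, coords_b, params.min_margin).separable:
        return DeadlockVerdict(
            pair=pair_ids, verdict="free", time=time, reason="linearly separable"
        )
    segments = exposed_segments(coords_a, coords_b, params.min_margin)
    seed_seq = np.random.SeedSequence(params.seed, spawn_key=tuple(pair_ids))
    for attempt in range(params.retries + 1):
        sel = select_cut_segments(coords_a, coords_b, segments, params, skip=attempt)
        if sel is None:
            if attempt == 0:
                return DeadlockVerdict(
                    pair=pair_ids,
                    verdict="indeterminate",
                    time=time,
                    reason="no divergent exposed segment pair",
                )
            break
        seg_a, seg_b = sel
        chain_a = open_ring(coords_a, seg_a, params.middle_width)
        chain_b = open_ring(coords_b, seg_b, params.middle_width)
        try:
            straight, crossed = build_closures(
                chain_a, chain_b, params, pair_ids, time
            )
            rng = np.random.default_rng(seed_seq.spawn(1)[0])
            k1, inv1 = is_knotted(straight.vertices, params.n_proj_retries, rng)
            k2, inv2 = is_knotted(crossed.vertices, params.n_proj_retries, rng)
        except (ClosureFailure, KnotComputationError) as err:
            if attempt < params.retries:
                continue
            return DeadlockVerdict(
                pair=pair_ids, verdict="indeterminate", time=time, reason=str(err)
            )
        if k1 != k2:
            return DeadlockVerdict(
                pair=pair_ids,
                verdict="indeterminate",
                invariants=(inv1, inv2),
                agreement=False,
                time=time,
                reason="wiring disagreement",
            )
        return DeadlockVerdict(
            pair=pair_ids,
            verdict="deadlocked" if k1 else "free",
            invariants=(inv1, inv2),
            agreement=True,
            time=time,
        )
    return DeadlockVerdict(
        pair=pair_ids,
        verdict="indeterminate",
        time=time,
        reason="cut-segment retries exhausted",
    )


def scan_frame(
    frame: MeltFrame,
    topology: RingTopology,
    params: ClosureParams = ClosureParams(),
) -> tuple[list[DeadlockVerdict], list[tuple[int, int]]]:
    """Classify every non-separable ring pair of a frame.

    Returns all verdicts plus the edge list of deadlocked pairs; the
    indeterminate count is available by filtering the verdicts.
    """
    from .separability import candidate_pairs  # local to avoid cycle noise

    verdicts = []
    edges = []
    for i, j in candidate_pairs(frame, topology, params.min_margin):
        xa, xb = pair_coordinates(frame, topology, i, j)
        v = classify_pair(xa, xb, params, pair_ids=(i, j), time=frame.time)
        verdicts.append(v)
        if v.verdict == "deadlocked":
            edges.append((i, j))
    return verdicts, edges
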