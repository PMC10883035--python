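"""Deterministic labeled test geometries.

Reference knotted curves calibrate the knot engine; labeled ring pairs
(separable / threaded-but-free / deadlocked clasp) exercise the full
reconnection detector against ground truth fixed by construction; scripted
aggregation sequences and seeded random graphs feed the cluster analytics.

The deadlocked clasp is two hairpins whose folds helically wrap each
other's strand bundle (mutual girth hitches): the rings stay unknotted and
unlinked, but outward pulling only tightens the wraps.  Far caps carry
high-curvature exposed segments, so reconnection cut points are unambiguous.
Ground-truth labels are certified only within the jitter cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "JITTER_CAP",
    "LabeledPair",
    "make_reference_curve",
    "make_labeled_pair",
    "make_aggregation_sequence",
    "make_random_graph",
]

#: Vertex jitter amplitudes above this (in sigma) could change ground truth.
JITTER_CAP = 0.1

#: Target bead spacing of fixture rings, in sigma (near the FENE+WCA bond rest
#: length so fixtures behave under the pull-apart oracle's force field).
BEAD_SPACING = 0.95


@dataclass(frozen=True)
class LabeledPair:
    """Two ring coordinate arrays with a construction-fixed ground truth."""

    ring_a: np.ndarray
    ring_b: np.ndarray
    label: str  # separable | threaded_free | deadlocked
    kind: str
    seed: int
    jitter: float


# ---------------------------------------------------------------------------
# reference knotted curves
# ---------------------------------------------------------------------------


def _circle(n: int, radius: float = 1.0) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)])


def _trefoil(n: int) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [
            np.sin(t) + 2 * np.sin(2 * t),
            np.cos(t) - 2 * np.cos(2 * t),
            -np.sin(3 * t),
        ]
    )


def _figure_eight(n: int) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [
            (2 + np.cos(2 * t)) * np.cos(3 * t),
            (2 + np.cos(2 * t)) * np.sin(3 * t),
            np.sin(4 * t),
        ]
    )


def _granny(n: int) -> np.ndarray:
    """Connected sum of two trefoils, spliced across a separating plane.

    Each straight splice segment crosses the mid-plane exactly once, so the
    result is 3_1 # 3_1 by construction.
    """
    half = n // 2
    A = _trefoil(half)
    B = _trefoil(n - half) + np.array([10.0, 0.0, 0.0])
    # open A at the edge whose midpoint has maximal x, B at minimal x
    ia = int(np.argmax((A[:, 0] + np.roll(A[:, 0], -1)) / 2))
    ib = int(np.argmin((B[:, 0] + np.roll(B[:, 0], -1)) / 2))
    # chain A: from edge end (ia+1) around to edge start ia; same for B
    chain_a = np.roll(A, -(ia + 1), axis=0)
    chain_b = np.roll(B, -(ib + 1), axis=0)
    # cycle: chain_a, jump a_end -> b_start, chain_b, jump b_end -> a_start
    return np.vstack([chain_a, chain_b])


def make_reference_curve(kind: str, n_vertices: int) -> np.ndarray:
    """Standard parametric embedding of a reference curve, ``n`` vertices.

    Kinds: ``circle`` (n >= 3), ``trefoil``, ``figure_eight``, ``granny``
    (all knots need n >= 30 to stay simple at these parametrizations).
    """
    builders = {
        "circle": (_circle, 3),
        "trefoil": (_trefoil, 30),
        "figure_eight": (_figure_eight, 30),
        "granny": (_granny, 60),
    }
    if kind not in builders:
        raise ValueError(f"unknown curve kind {kind!r}")
    fn, n_min = builders[kind]
    if n_vertices < n_min:
        raise ValueError(f"{kind} needs at least {n_min} vertices to stay simple")
    return fn(n_vertices)


# ---------------------------------------------------------------------------
# polyline helpers
# ---------------------------------------------------------------------------


def _resample_closed(path: np.ndarray, spacing: float = BEAD_SPACING) -> np.ndarray:
    """Resample a closed polyline at uniform arclength spacing."""
    path = np.asarray(path, dtype=float)
    closed = np.vstack([path, path[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(8, int(round(total / spacing)))
    targets = np.linspace(0.0, total, n, endpoint=False)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])


def _arc(center, radius, start_angle, end_angle, plane_u, plane_v, n=40):
    th = np.linspace(start_angle, end_angle, n)
    return (
        np.asarray(center)[None, :]
        + radius * np.cos(th)[:, None] * np.asarray(plane_u)[None, :]
        + radius * np.sin(th)[:, None] * np.asarray(plane_v)[None, :]
    )


_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# labeled pairs
# ---------------------------------------------------------------------------

# clasp geometry (see _pair_deadlocked): strand offsets from the bundle
# axis, hook half-length, strand half-length, full wraps of each fold
_CLASP_RHO = 1.2  # bundle center distance from the pair axis
_CLASP_DELTA = 0.8  # strand half-separation within a bundle
_CLASP_F = 3.0  # x where the folds start wrapping
_CLASP_L = 11.0  # strand half-length
_CLASP_WRAPS = 1  # full turns of each fold around the other bundle


def _pair_separable() -> tuple[np.ndarray, np.ndarray]:
    a = _resample_closed(_circle(200, radius=4.0))
    b = _resample_closed(_circle(200, radius=4.0)) + np.array([11.5, 0.0, 0.0])
    return a, b


def _pair_threaded_free() -> tuple[np.ndarray, np.ndarray]:
    # circle in the xy-plane; a narrow stadium loop dips through its disk
    # and returns: two transversal piercings, removable by +z translation
    a = _resample_closed(_circle(240, radius=5.0))
    g = 2.0
    top, bottom = 8.0, -2.5
    path = np.vstack(
        [
            np.column_stack([np.full(40, -g), np.zeros(40), np.linspace(top, bottom, 40)]),
            _arc([0.0, 0.0, bottom], g, np.pi, 2 * np.pi, _EX, _EZ)[1:],
            np.column_stack([np.full(40, g), np.zeros(40), np.linspace(bottom, top, 40)])[1:],
            _arc([0.0, 0.0, top], g, 0.0, np.pi, _EX, _EZ)[1:-1],
        ]
    )
    return a, _resample_closed(path)


def _hook_ring(
    m: int = _CLASP_WRAPS,
    rho: float = _CLASP_RHO,
    delta: float = _CLASP_DELTA,
    f: float = _CLASP_F,
    L: float = _CLASP_L,
) -> np.ndarray:
    """One ring of the clasp: a hairpin whose fold wraps the other bundle.

    The two strands run along x at ``(y, z) = (rho, +-delta)``; the fold is
    a helix that winds ``m`` full turns around the other ring's bundle axis
    ``(y, z) = (-rho, 0)`` before returning as the second strand (offset
    outward in y so it clears the partner's helix).  The partner ring is
    the point reflection of this one through the origin.
    """
    rw = float(np.hypot(2 * rho, delta))
    phi0 = float(np.arctan2(delta, 2 * rho))
    x_adv = 1.5 * (m + 0.3)
    ts = np.linspace(0.0, 1.0, 80)
    phi = phi0 - ts * (2 * np.pi * m + 2 * phi0)
    helix = np.column_stack(
        [f + ts * x_adv, -rho + rw * np.cos(phi), rw * np.sin(phi)]
    )
    n1 = 40
    s1 = np.column_stack(
        [np.linspace(-L, f, n1), np.full(n1, rho), np.full(n1, delta)]
    )
    y2 = rho + 1.6
    ret_up = np.column_stack(
        [np.full(6, f + x_adv), np.linspace(rho, y2, 6), np.full(6, -delta)]
    )
    s2 = np.column_stack(
        [np.linspace(f + x_adv, -L, n1), np.full(n1, y2), np.full(n1, -delta)]
    )
    cap = np.column_stack(
        [
            np.full(8, -L) - 0.8 * np.sin(np.linspace(0, np.pi, 8)),
            np.linspace(y2, rho, 8),
            np.linspace(-delta, delta, 8),
        ]
    )
    return np.vstack([s1, helix[1:], ret_up[1:], s2[1:], cap[1:-1]])


def _pair_deadlocked() -> tuple[np.ndarray, np.ndarray]:
    """Mutual helical hooks: unlinked rings that cannot be pulled apart.

    Each ring is a long hairpin whose fold winds one full turn around the
    other ring's doubled strand bundle (ring B is ring A reflected through
    the origin, so the hooks are mutual).  The rings are individually
    unknotted and their linking number is zero — the wrap crossings cancel
    in signed pairs — yet pulling the far caps in opposite directions only
    tightens the wraps: unscrewing either fold would have to pump winding
    into the taut central section, which the tension forbids.  A plain
    half-turn hook (two elbows) lacks this lock and slips out sideways;
    the full wrap is the elementary pulled-taut deadlock morphology.
    """
    a = _hook_ring()
    b = -_hook_ring()
    return _resample_closed(a), _resample_closed(b)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    a, b, c, d = q
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
            [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
            [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
        ]
    )


def make_labeled_pair(kind: str, seed: int, jitter: float = 0.05) -> LabeledPair:
    """A ring pair with ground truth fixed by construction.

    A seeded random rigid motion (joint rotation + translation) and Gaussian
    vertex jitter are applied; jitter above :data:`JITTER_CAP` is refused
    because it could change the ground truth.
    """
    if jitter > JITTER_CAP:
        raise ValueError(f"jitter {jitter} > {JITTER_CAP} sigma could change labels")
    builders = {
        "separable": _pair_separable,
        "threaded_free": _pair_threaded_free,
        "deadlocked": _pair_deadlocked,
    }
    if kind not in builders:
        raise ValueError(f"unknown pair kind {kind!r}")
    a, b = builders[kind]()
    rng = np.random.default_rng(seed)
    R = _random_rotation(rng)
    t = rng.uniform(-5.0, 5.0, size=3)
    a = a @ R.T + t
    b = b @ R.T + t
    if jitter > 0:
        a = a + rng.normal(0.0, jitter, size=a.shape)
        b = b + rng.normal(0.0, jitter, size=b.shape)
    return LabeledPair(
        ring_a=a, ring_b=b, label=kind, kind=kind, seed=seed, jitter=jitter
    )


# ---------------------------------------------------------------------------
# synthetic deadlock-graph inputs
# ---------------------------------------------------------------------------


def make_aggregation_sequence(
    n_rings: int,
    merge_schedule: list[tuple[float, list[tuple[int, int]]]],
    seed: int = 0,
) -> list[tuple[float, np.ndarray]]:
    """Time-ordered cumulative edge lists following a scripted merge schedule.

    Each schedule entry ``(time, [(a, b), ...])`` merges the clusters
    currently containing rings ``a`` and ``b`` (which must be disjoint) by
    adding the edge ``(a, b)``.  Returns ``[(time, edges), ...]``.
    """
    rng = np.random.default_rng(seed)
    del rng  # the schedule is deterministic; seed kept for interface parity
    parent = list(range(n_rings))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int]] = []
    out: list[tuple[float, np.ndarray]] = []
    last_t = -np.inf
    for time, pairs in merge_schedule:
        if time <= last_t:
            raise ValueError("schedule times must be strictly increasing")
        last_t = time
        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra == rb:
                raise ValueError(
                    f"schedule at t={time} merges rings {a},{b} already in one cluster"
                )
            parent[ra] = rb
            edges.append((a, b))
        out.append((time, np.array(edges, dtype=np.intp).reshape(-1, 2)))
    return out


def make_random_graph(n_nodes: int, edge_prob: float, seed: int) -> np.ndarray:
    """Seeded Erdos-Renyi-style edge list on ``n_nodes`` nodes."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    keep = rng.random(len(iu[0])) < edge_prob
    return np.column_stack([iu[0][keep], iu[1][keep]]).astype(np.intp)
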