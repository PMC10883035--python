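"""The reconnection pipeline: cuts, closures, classification, frame scans."""

from __future__ import annotations

import numpy as np
import pytest

from ringlock.fixtures import make_labeled_pair
from ringlock.melt_io import MeltFrame, RingTopology
from ringlock.reconnection import (
    ClosureParams,
    build_closures,
    classify_pair,
    open_ring,
    scan_frame,
    select_cut_segments,
)
from ringlock.separability import exposed_segments

from conftest import circle_ring

PARAMS = ClosureParams(seed=13)


def _chains_for(kind, seed):
    pair = make_labeled_pair(kind, seed)
    segs = exposed_segments(pair.ring_a, pair.ring_b)
    sel = select_cut_segments(pair.ring_a, pair.ring_b, segs, PARAMS)
    assert sel is not None
    ca = open_ring(pair.ring_a, sel[0])
    cb = open_ring(pair.ring_b, sel[1])
    return pair, ca, cb


class TestOpenRing:
    def test_removes_exactly_center_bead(self):
        a = circle_ring(40, 6.0)
        b = circle_ring(40, 6.0, center=(30, 0, 0))
        seg = exposed_segments(a, b)[0]
        chain = open_ring(a, seg)
        assert len(chain.coords) == 39
        n = 40
        # termini are the window flanks
        np.testing.assert_allclose(chain.coords[0], a[(seg.center_bead + 1) % n])
        np.testing.assert_allclose(chain.coords[-1], a[(seg.center_bead - 1) % n])

    def test_distances_conserved_except_cut(self):
        a = circle_ring(40, 6.0)
        b = circle_ring(40, 6.0, center=(30, 0, 0))
        seg = exposed_segments(a, b)[0]
        chain = open_ring(a, seg)
        d_ring = np.linalg.norm(np.diff(a, axis=0), axis=1)
        d_chain = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
        # chain bonds are a subset of ring bonds (same spacing), no new gaps
        assert d_chain.max() <= d_ring.max() + 1e-9
        assert len(d_chain) == 38


class TestBuildClosures:
    @pytest.mark.parametrize("kind,seed", [("deadlocked", 1), ("threaded_free", 2)])
    def test_single_cycle_and_shared_chain_vertices(self, kind, seed):
        _, ca, cb = _chains_for(kind, seed)
        straight, crossed = build_closures(ca, cb, PARAMS)
        n_chain = len(ca.coords) + len(cb.coords)
        for closure in (straight, crossed):
            assert closure.n_chain_beads == n_chain
            assert len(closure.vertices) > n_chain  # plus arc vertices
        # both wirings contain identical chain vertices, differ only in arcs
        np.testing.assert_allclose(
            straight.vertices[: len(ca.coords)], crossed.vertices[: len(ca.coords)]
        )
        assert len(straight.vertices) != len(crossed.vertices) or not np.allclose(
            straight.vertices, crossed.vertices
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_arc_clearance_brute_force(self, seed):
        """Every arc vertex beyond the junction zone clears both chains."""
        kind = ("deadlocked", "threaded_free")[seed % 2]
        _, ca, cb = _chains_for(kind, seed)
        straight, crossed = build_closures(ca, cb, PARAMS)
        chains = np.vstack([ca.coords, cb.coords])
        ends = [ca.coords[0], ca.coords[-1], cb.coords[0], cb.coords[-1]]
        for closure in (straight, crossed):
            arc = closure.vertices[len(ca.coords) :]
            arc = arc[len(cb.coords) :] if False else closure.vertices
            # arc vertices = those not in the chains
            from scipy.spatial.distance import cdist

            d_to_chain = cdist(closure.vertices, chains).min(axis=1)
            is_arc = d_to_chain > 1e-9
            arc_pts = closure.vertices[is_arc]
            # exclude the junction zone: within 1 sigma of any terminus
            d_to_ends = cdist(arc_pts, np.array(ends)).min(axis=1)
            far = arc_pts[d_to_ends >= 1.0]
            assert cdist(far, chains).min() >= PARAMS.eps_arc - 1e-6


class TestClassifyPair:
    @pytest.mark.parametrize("kind", ["separable", "threaded_free", "deadlocked"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_construction_label(self, kind, seed):
        pair = make_labeled_pair(kind, seed)
        v = classify_pair(pair.ring_a, pair.ring_b, PARAMS)
        expect = "deadlocked" if kind == "deadlocked" else "free"
        assert v.verdict == expect

    def test_separable_short_circuits(self):
        pair = make_labeled_pair("separable", 3)
        v = classify_pair(pair.ring_a, pair.ring_b, PARAMS)
        assert v.verdict == "free"
        assert v.reason == "linearly separable"
        assert v.invariants is None  # no reconnection was needed

    def test_rigid_motion_invariance(self):
        pair = make_labeled_pair("deadlocked", 4, jitter=0.0)
        rng = np.random.default_rng(9)
        for _ in range(2):
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            a, b, c, d = q
            R = np.array(
                [
                    [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
                    [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
                    [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
                ]
            )
            t = rng.uniform(-20, 20, 3)
            v = classify_pair(pair.ring_a @ R.T + t, pair.ring_b @ R.T + t, PARAMS)
            assert v.verdict == "deadlocked"

    def test_dilation_never_creates_deadlock(self):
        """Scaling a free pair's separation up keeps it free."""
        pair = make_labeled_pair("threaded_free", 0)
        com = np.vstack([pair.ring_a, pair.ring_b]).mean(axis=0)
        for scale in (1.0, 1.5, 2.5):
            a = com + scale * (pair.ring_a - com)
            b = com + scale * (pair.ring_b - com)
            assert classify_pair(a, b, PARAMS).verdict == "free"

    def test_engulfed_ring_is_indeterminate(self):
        """A ring with no exposed segment cannot be cut."""
        outer = circle_ring(60, 8.0)
        # wavy small ring near the center: every window of the small ring is
        # exposed, but we check the no-selection path via an empty list
        from ringlock.reconnection import select_cut_segments

        assert select_cut_segments(outer, outer + 1.0, [], PARAMS) is None


class TestScanFrame:
    def _frame_from_pairs(self, pairs_list, L=400.0):
        rings = []
        for pair in pairs_list:
            rings += [pair[0], pair[1]]
        coords = np.vstack(rings)
        shift = coords.min() - 5.0
        n = 0
        ring_ids, bonds = [], []
        for r in rings:
            m = len(r)
            ring_ids.append(np.arange(n, n + m))
            bonds += [(n + k, n + (k + 1) % m) for k in range(m)]
            n += m
        topo = RingTopology(
            rings=ring_ids,
            n_beads=n,
            activity=np.zeros(len(rings), bool),
            bond_list=np.array(bonds),
        )
        frame = MeltFrame(coords=np.mod(coords - shift, L), box_side=L, time=0.0)
        return frame, topo

    def test_isolated_circles_scan_clean(self):
        rings = [
            (circle_ring(16, 2.5, center=(20 * k, 0, 0)),
             circle_ring(16, 2.5, center=(20 * k + 10, 0, 0)))
            for k in range(3)
        ]
        frame, topo = self._frame_from_pairs(rings)
        verdicts, edges = scan_frame(frame, topo, PARAMS)
        assert edges == []

    def test_three_disjoint_clasps(self):
        offsets = [(0, 0, 0), (80, 0, 0), (0, 80, 0)]
        pairs_list = []
        for k, off in enumerate(offsets):
            p = make_labeled_pair("deadlocked", k)
            pairs_list.append((p.ring_a + off, p.ring_b + off))
        frame, topo = self._frame_from_pairs(pairs_list)
        verdicts, edges = scan_frame(frame, topo, PARAMS)
        assert sorted(edges) == [(0, 1), (2, 3), (4, 5)]
        # oracle: each pair classified independently gives the same verdict
        for (a, b) in pairs_list:
            assert classify_pair(a, b, PARAMS).verdict == "deadlocked"

    def test_relabeling_invariance(self):
        p0 = make_labeled_pair("deadlocked", 0)
        p1 = (circle_ring(16, 2.5, center=(80, 0, 0)),
              circle_ring(16, 2.5, center=(95, 0, 0)))
        frame, topo = self._frame_from_pairs([(p0.ring_a, p0.ring_b), p1])
        _, edges = scan_frame(frame, topo, PARAMS)
        # permute ring order: swap the clasp to positions 2, 3
        frame2, topo2 = self._frame_from_pairs([p1, (p0.ring_a, p0.ring_b)])
        _, edges2 = scan_frame(frame2, topo2, PARAMS)
        assert edges == [(0, 1)]
        assert edges2 == [(2, 3)]
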