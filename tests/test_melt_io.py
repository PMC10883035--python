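"""I/O, ring traversal extraction, unwrapping and centers."""

from __future__ import annotations

import numpy as np
import pytest

from ringlock.melt_io import (
    FrameError,
    MeltFrame,
    ParseError,
    RingTopology,
    TopologyError,
    Trajectory,
    read_ring_topology,
    read_trajectory,
    read_xyz_frame,
    ring_center,
    unwrap_ring,
    write_frame,
    write_topology_json,
    read_topology_json,
    write_trajectory_dump,
)

from conftest import circle_ring


def _write_data(path, n_atoms, mols, bonds):
    """Minimal LAMMPS data file (molecular style)."""
    lines = [
        "melt fixture",
        "",
        f"{n_atoms} atoms",
        f"{len(bonds)} bonds",
        "1 atom types",
        "1 bond types",
        "",
        "0.0 50.0 xlo xhi",
        "0.0 50.0 ylo yhi",
        "0.0 50.0 zlo zhi",
        "",
        "Atoms",
        "",
    ]
    for i in range(n_atoms):
        lines.append(f"{i + 1} {mols[i] + 1} 1 {1.0 * i} 0.0 0.0")
    lines += ["", "Bonds", ""]
    for k, (a, b) in enumerate(bonds):
        lines.append(f"{k + 1} 1 {a + 1} {b + 1}")
    path.write_text("\n".join(lines) + "\n")


def _cycle_walk_oracle(n_atoms, bonds):
    """Independent cycle extraction by walking adjacency."""
    adj = {i: [] for i in range(n_atoms)}
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    seen, cycles = set(), []
    for start in range(n_atoms):
        if start in seen:
            continue
        walk, prev, cur = [start], None, start
        while True:
            nxt = [x for x in adj[cur] if x != prev]
            nxt = nxt[0] if nxt else adj[cur][0]
            if nxt == start:
                break
            walk.append(nxt)
            prev, cur = cur, nxt
        seen.update(walk)
        cycles.append(walk)
    return cycles


def _same_cycle(a, b) -> bool:
    """Equal up to rotation and reflection."""
    a, b = list(a), list(b)
    if len(a) != len(b):
        return False
    doubled = b + b
    rev = list(reversed(b)) + list(reversed(b))
    return any(
        doubled[i : i + len(a)] == a or rev[i : i + len(a)] == a
        for i in range(len(b))
    )


class TestReadTopology:
    def test_smallest_cycle(self, tmp_path):
        path = tmp_path / "tri.data"
        _write_data(path, 3, [0, 0, 0], [(0, 1), (1, 2), (2, 0)])
        topo = read_ring_topology(path)
        assert topo.n_rings == 1
        assert _same_cycle(topo.rings[0].tolist(), [0, 1, 2])

    def test_permuted_bonds_same_traversals(self, tmp_path):
        rng = np.random.default_rng(3)
        sizes = [5, 8, 6]
        mols, bonds, start = [], [], 0
        for m, size in enumerate(sizes):
            mols += [m] * size
            bonds += [(start + k, start + (k + 1) % size) for k in range(size)]
            start += size
        perm = rng.permutation(len(bonds))
        shuffled = [bonds[k] for k in perm]
        path = tmp_path / "perm.data"
        _write_data(path, sum(sizes), mols, shuffled)
        topo = read_ring_topology(path)
        oracle = _cycle_walk_oracle(sum(sizes), bonds)
        assert topo.n_rings == len(oracle)
        for ring, cyc in zip(topo.rings, oracle):
            assert _same_cycle(ring.tolist(), cyc)

    def test_non_cycle_molecule_rejected(self, tmp_path):
        path = tmp_path / "bad.data"
        _write_data(path, 3, [0, 0, 0], [(0, 1), (1, 2)])  # open chain
        with pytest.raises(TopologyError, match="molecule 0"):
            read_ring_topology(path)

    def test_dangling_bond_rejected(self, tmp_path):
        path = tmp_path / "dangle.data"
        _write_data(path, 3, [0, 0, 0], [(0, 1), (1, 2), (2, 5)])
        with pytest.raises(ParseError):
            read_ring_topology(path)


class TestTrajectoryIO:
    def test_dump_roundtrip(self, tmp_path, short_traj):
        path = tmp_path / "t.dump"
        write_trajectory_dump(short_traj, path)
        back = read_trajectory(path, short_traj.topology)
        assert len(back) == len(short_traj)
        for a, b in zip(short_traj.frames, back.frames):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)
            np.testing.assert_array_equal(a.images, b.images)

    def test_shuffled_atom_lines_resorted(self, tmp_path):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (6, 3))
        header = (
            "ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n6\n"
            "ITEM: BOX BOUNDS pp pp pp\n0 10\n0 10\n0 10\n"
            "ITEM: ATOMS id type x y z ix iy iz\n"
        )
        rows = [
            f"{i + 1} 1 {coords[i, 0]} {coords[i, 1]} {coords[i, 2]} 1 0 -1"
            for i in rng.permutation(6)
        ]
        (tmp_path / "s.dump").write_text(header + "\n".join(rows) + "\n")
        topo = RingTopology(
            rings=[np.arange(6)],
            n_beads=6,
            activity=np.zeros(1, bool),
            bond_list=np.array([(k, (k + 1) % 6) for k in range(6)]),
        )
        traj = read_trajectory(tmp_path / "s.dump", topo)
        np.testing.assert_allclose(traj[0].coords, coords, atol=1e-9)
        # unwrapped = wrapped + image * L
        np.testing.assert_allclose(
            traj[0].unwrapped(), coords + np.array([10.0, 0.0, -10.0]), atol=1e-9
        )

    def test_xyz_roundtrip_with_labels(self, tmp_path, short_traj):
        path = tmp_path / "f.xyz"
        write_frame(short_traj[0], short_traj.topology, path, format="xyz")
        frame, topo, meta = read_xyz_frame(path)
        assert topo.n_rings == short_traj.topology.n_rings
        np.testing.assert_array_equal(
            topo.activity, short_traj.topology.activity
        )
        np.testing.assert_allclose(frame.coords, short_traj[0].coords, atol=1e-8)

    def test_write_frame_errors(self, tmp_path, short_traj):
        with pytest.raises(ValueError, match="unknown format"):
            write_frame(short_traj[0], short_traj.topology, tmp_path / "x", "pdb")

    def test_topology_json_roundtrip(self, tmp_path, short_traj):
        path = tmp_path / "topo.json"
        write_topology_json(short_traj.topology, path)
        back = read_topology_json(path)
        assert back.n_rings == short_traj.topology.n_rings
        for a, b in zip(back.rings, short_traj.topology.rings):
            np.testing.assert_array_equal(a, b)

    def test_timestamps_must_increase(self, short_traj):
        frames = [short_traj[0], short_traj[0]]
        with pytest.raises(FrameError):
            Trajectory(frames=frames, topology=short_traj.topology)


class TestUnwrap:
    def _topo(self, n):
        return RingTopology(
            rings=[np.arange(n)],
            n_beads=n,
            activity=np.zeros(1, bool),
            bond_list=np.array([(k, (k + 1) % n) for k in range(n)]),
        )

    def test_interior_ring_identity(self):
        ring = circle_ring(20, 2.5, center=(10, 10, 10))
        frame = MeltFrame(coords=ring, box_side=20.0, time=0.0)
        np.testing.assert_allclose(unwrap_ring(frame, self._topo(20), 0), ring)

    def test_boundary_straddling_ring(self):
        ring = circle_ring(24, 3.0, center=(0.5, 10, 10))  # crosses x = 0
        L = 20.0
        frame = MeltFrame(coords=np.mod(ring, L), box_side=L, time=0.0)
        out = unwrap_ring(frame, self._topo(24), 0)
        bonds = np.linalg.norm(np.diff(np.vstack([out, out[:1]]), axis=0), axis=1)
        assert bonds.max() < 1.1

    def test_unwrap_is_rigid(self):
        ring = circle_ring(24, 3.0, center=(0.5, 10, 10))
        L = 20.0
        frame = MeltFrame(coords=np.mod(ring, L), box_side=L, time=0.0)
        out = unwrap_ring(frame, self._topo(24), 0)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(out), pdist(ring), atol=1e-9)

    def test_center_translation_equivariance(self):
        ring = circle_ring(16, 2.0, center=(10, 10, 10))
        L = 40.0
        topo = self._topo(16)
        f1 = MeltFrame(coords=np.mod(ring, L), box_side=L, time=0.0)
        v = np.array([3.0, -2.0, 1.0])
        f2 = MeltFrame(coords=np.mod(ring + v, L), box_side=L, time=0.0)
        c1 = ring_center(f1, topo, 0)
        c2 = ring_center(f2, topo, 0)
        np.testing.assert_allclose(c2 - c1, v, atol=1e-9)
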