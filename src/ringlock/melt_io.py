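"""Melt topologies and trajectories: LAMMPS data/dump and extended-XYZ I/O.

All coordinates are stored *wrapped* into the periodic cubic box ``[0, L)``;
unwrapping is done on demand and per ring (see :func:`unwrap_ring`).  Lengths
are in sigma, times in tau, energies in epsilon throughout the package; no
unit conversion layer exists.

Only cubic, non-deforming boxes are supported.  Two dump column dialects are
accepted: ``id type x y z`` and ``id mol type xs ys zs`` (scaled), each with
optional image flags ``ix iy iz``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RinglockError",
    "ParseError",
    "TopologyError",
    "FrameError",
    "UnwrapAmbiguityError",
    "RingTopology",
    "MeltFrame",
    "Trajectory",
    "read_ring_topology",
    "read_trajectory",
    "read_xyz_frame",
    "unwrap_ring",
    "ring_center",
    "write_frame",
    "write_topology_json",
    "read_topology_json",
]

#: FENE maximum bond extension in sigma; unwrapped bond lengths must stay below.
FENE_R0 = 1.5


class RinglockError(Exception):
    """Base class for all package errors."""


class ParseError(RinglockError):
    """Malformed input file."""


class TopologyError(RinglockError):
    """Molecule bond graph is not a single simple cycle."""


class FrameError(RinglockError):
    """A trajectory frame is inconsistent with the topology."""


class UnwrapAmbiguityError(RinglockError):
    """A minimum-image bond is >= half the box: the box is too small."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RingTopology:
    """Ring decomposition of a melt.

    ``rings[r]`` is the bead-id traversal (0-based, cycle order) of molecule
    ``r``.  ``is_ring[r]`` is False for molecules that have been cut open into
    linear chains (see the simulator's ``cut_ring``); their traversal is then
    path order.
    """

    rings: list[np.ndarray]
    n_beads: int
    activity: np.ndarray  # bool, per ring
    bond_list: np.ndarray  # (n_bonds, 2) bead ids
    is_ring: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rings = [np.asarray(r, dtype=np.intp) for r in self.rings]
        self.activity = np.asarray(self.activity, dtype=bool)
        self.bond_list = np.asarray(self.bond_list, dtype=np.intp).reshape(-1, 2)
        if self.is_ring is None:
            self.is_ring = np.ones(len(self.rings), dtype=bool)
        seen = np.concatenate(self.rings) if self.rings else np.empty(0, np.intp)
        if len(np.unique(seen)) != self.n_beads or seen.size != self.n_beads:
            raise TopologyError("bead ids do not partition exactly into rings")

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def beads_per_ring(self) -> np.ndarray:
        return np.array([len(r) for r in self.rings], dtype=np.intp)

    @property
    def ring_of_bead(self) -> np.ndarray:
        out = np.empty(self.n_beads, dtype=np.intp)
        for r, beads in enumerate(self.rings):
            out[beads] = r
        return out


@dataclass
class MeltFrame:
    """One time point: wrapped per-bead coordinates in a periodic cubic box."""

    coords: np.ndarray  # (n_beads, 3), wrapped into [0, L)
    box_side: float
    time: float
    images: np.ndarray | None = None  # optional (n_beads, 3) int image flags

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.box_side <= 0:
            raise FrameError("box side must be positive")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise FrameError("coords must be (n, 3)")
        if self.images is not None:
            self.images = np.asarray(self.images, dtype=np.intp)
            if self.images.shape != self.coords.shape:
                raise FrameError("image flags shape mismatch")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def unwrapped(self) -> np.ndarray:
        """Coordinates with image flags applied (identity if flags absent)."""
        if self.images is None:
            return self.coords.copy()
        return self.coords + self.images * self.box_side


@dataclass
class Trajectory:
    """Time-ordered frames sharing one :class:`RingTopology`."""

    frames: list[MeltFrame]
    topology: RingTopology

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise FrameError("timestamps must be strictly increasing")
        for f in self.frames:
            if f.n_beads != self.topology.n_beads:
                raise FrameError("frame bead count differs from topology")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> MeltFrame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


# ---------------------------------------------------------------------------
# cycle extraction
# ---------------------------------------------------------------------------


def _traverse_cycles(
    n_beads: int, mol_of_bead: np.ndarray, bonds: np.ndarray
) -> list[np.ndarray]:
    """Walk the bond adjacency of every molecule and verify simple cycles."""
    nbrs: list[list[int]] = [[] for _ in range(n_beads)]
    for a, b in bonds:
        if a == b:
            raise ParseError(f"self-bond on bead {a}")
        if not (0 <= a < n_beads and 0 <= b < n_beads):
            raise ParseError(f"dangling bond ({a}, {b}): bead id out of range")
        if mol_of_bead[a] != mol_of_bead[b]:
            raise TopologyError(
                f"inter-molecule bond ({a}, {b}) between molecules "
                f"{mol_of_bead[a]} and {mol_of_bead[b]}"
            )
        nbrs[a].append(b)
        nbrs[b].append(a)

    mol_ids = np.unique(mol_of_bead)
    rings: list[np.ndarray] = []
    for mol in mol_ids:
        beads = np.flatnonzero(mol_of_bead == mol)
        if any(len(nbrs[b]) != 2 for b in beads):
            raise TopologyError(f"molecule {mol} is not a single simple cycle")
        start = int(beads.min())
        walk = [start]
        prev, cur = -1, start
        while True:
            a, b = nbrs[cur]
            nxt = b if a == prev else a
            if nxt == start:
                break
            if len(walk) > len(beads):
                raise TopologyError(f"molecule {mol} is not a single simple cycle")
            walk.append(nxt)
            prev, cur = cur, nxt
        if len(walk) != len(beads):
            raise TopologyError(f"molecule {mol} splits into multiple cycles")
        rings.append(np.array(walk, dtype=np.intp))
    return rings


# ---------------------------------------------------------------------------
# LAMMPS data
# ---------------------------------------------------------------------------

_SECTION_NAMES = {
    "Atoms", "Bonds", "Velocities", "Masses", "Angles", "Dihedrals",
    "Impropers", "Pair", "PairIJ", "Bond", "Angle", "Dihedral", "Improper",
}


def read_ring_topology(data_path: str | Path) -> RingTopology:
    """Read a LAMMPS data file (Atoms ``full`` or ``molecular``) into rings.

    Every molecule must be one simple cycle; ring order follows the cycle
    traversal starting from the molecule's lowest bead id.  Activity labels
    default to passive (they live in the JSON sidecar, not the data file).
    """
    lines = Path(data_path).read_text().splitlines()
    n_atoms = n_bonds = None
    for ln in lines[:50]:
        parts = ln.split("#")[0].split()
        if len(parts) >= 2 and parts[1] == "atoms":
            n_atoms = int(parts[0])
        if len(parts) >= 2 and parts[1] == "bonds":
            n_bonds = int(parts[0])
    if n_atoms is None or n_bonds is None:
        raise ParseError(f"{data_path}: missing atoms/bonds counts in header")

    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(lines):
        head = lines[i].split("#")[0].strip()
        if head.split()[:1] and head.split()[0] in _SECTION_NAMES:
            name = head.split()[0]
            i += 1
            body: list[str] = []
            while i < len(lines):
                s = lines[i].split("#")[0].strip()
                if s and s.split()[0] in _SECTION_NAMES:
                    break
                if s:
                    body.append(s)
                i += 1
            sections[name] = body
        else:
            i += 1

    if "Atoms" not in sections or "Bonds" not in sections:
        raise ParseError(f"{data_path}: needs Atoms and Bonds sections")

    mol_of_bead = np.full(n_atoms, -1, dtype=np.intp)
    for row in sections["Atoms"]:
        parts = row.split()
        if len(parts) < 5:
            raise ParseError(f"{data_path}: short Atoms line: {row!r}")
        bead = int(parts[0]) - 1
        if not 0 <= bead < n_atoms:
            raise ParseError(f"{data_path}: atom id {bead + 1} out of range")
        mol_of_bead[bead] = int(parts[1]) - 1
    if (mol_of_bead < 0).any():
        raise ParseError(f"{data_path}: missing atom ids in Atoms section")

    bonds = np.empty((n_bonds, 2), dtype=np.intp)
    for k, row in enumerate(sections["Bonds"]):
        parts = row.split()
        if len(parts) < 4:
            raise ParseError(f"{data_path}: short Bonds line: {row!r}")
        bonds[k] = (int(parts[2]) - 1, int(parts[3]) - 1)

    rings = _traverse_cycles(n_atoms, mol_of_bead, bonds)
    return RingTopology(
        rings=rings,
        n_beads=n_atoms,
        activity=np.zeros(len(rings), dtype=bool),
        bond_list=bonds,
    )


# ---------------------------------------------------------------------------
# LAMMPS dump
# ---------------------------------------------------------------------------


def _parse_dump_frames(lines: list[str], path: str) -> list[MeltFrame]:
    frames = []
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        time = float(lines[i + 1].split()[0])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError(f"{path}: malformed frame at line {i}")
        n_at = int(lines[i + 3])
        bounds_head = lines[i + 4]
        if not bounds_head.startswith("ITEM: BOX BOUNDS"):
            raise ParseError(f"{path}: missing BOX BOUNDS")
        if any(t in bounds_head for t in ("xy", "xz", "yz")):
            raise ParseError(f"{path}: triclinic boxes are not supported")
        los, his = np.empty(3), np.empty(3)
        for d in range(3):
            lo, hi = lines[i + 5 + d].split()[:2]
            los[d], his[d] = float(lo), float(hi)
        sides = his - los
        if not np.allclose(sides, sides[0], rtol=1e-9, atol=1e-9):
            raise FrameError(f"{path}: box is not cubic at t={time}")
        L = float(sides[0])
        atoms_head = lines[i + 8]
        if not atoms_head.startswith("ITEM: ATOMS"):
            raise ParseError(f"{path}: missing ATOMS item")
        cols = atoms_head.split()[2:]
        col = {c: k for k, c in enumerate(cols)}
        scaled = "xs" in col
        names = ("xs", "ys", "zs") if scaled else ("x", "y", "z")
        if any(c not in col for c in names) or "id" not in col:
            raise ParseError(f"{path}: unsupported dump columns {cols}")
        has_img = all(c in col for c in ("ix", "iy", "iz"))

        body = lines[i + 9 : i + 9 + n_at]
        if len(body) < n_at:
            raise ParseError(f"{path}: truncated frame at t={time}")
        data = np.array([row.split() for row in body], dtype=float)
        ids = data[:, col["id"]].astype(np.intp) - 1
        if len(np.unique(ids)) != n_at or ids.min() != 0 or ids.max() != n_at - 1:
            raise FrameError(f"{path}: missing/duplicate bead id at t={time}")
        xyz = data[:, [col[c] for c in names]]
        if scaled:
            xyz = los + xyz * L
        images = None
        if has_img:
            images = np.zeros((n_at, 3), dtype=np.intp)
            images[ids] = data[:, [col["ix"], col["iy"], col["iz"]]].astype(np.intp)
        coords = np.zeros((n_at, 3))
        coords[ids] = xyz - los  # shift box origin to 0
        coords = np.mod(coords, L)
        frames.append(MeltFrame(coords=coords, box_side=L, time=time, images=images))
        i += 9 + n_at
    return frames


def read_trajectory(dump_path: str | Path, topology: RingTopology) -> Trajectory:
    """Read a text LAMMPS dump; frames time-sorted, rows re-sorted by bead id."""
    lines = Path(dump_path).read_text().splitlines()
    frames = _parse_dump_frames(lines, str(dump_path))
    if not frames:
        raise ParseError(f"{dump_path}: no frames found")
    for f in frames:
        if f.n_beads != topology.n_beads:
            raise FrameError(
                f"{dump_path}: frame has {f.n_beads} beads, topology has "
                f"{topology.n_beads}"
            )
    frames.sort(key=lambda f: f.time)
    return Trajectory(frames=frames, topology=topology)


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------


def read_xyz_frame(path: str | Path) -> tuple[MeltFrame, RingTopology, dict]:
    """Read one extended-XYZ frame with per-atom ``ring`` and ``active`` fields.

    Returns the frame, a topology rebuilt from the ring column (beads of each
    ring are stored contiguously in traversal order), and the free key=value
    comment fields (e.g. a fixture's ground-truth ``label``).
    """
    lines = Path(path).read_text().splitlines()
    n_at = int(lines[0].split()[0])
    comment = lines[1]
    meta: dict[str, str] = {}
    for tok in _split_xyz_comment(comment):
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v.strip('"')
    L = None
    if "Lattice" in meta:
        lat = np.fromstring(meta["Lattice"], sep=" ").reshape(3, 3)
        if not np.allclose(lat, np.diag(np.diag(lat))) or not np.allclose(
            np.diag(lat), lat[0, 0]
        ):
            raise ParseError(f"{path}: only cubic lattices are supported")
        L = float(lat[0, 0])
    rows = [ln.split() for ln in lines[2 : 2 + n_at]]
    if len(rows) < n_at:
        raise ParseError(f"{path}: truncated XYZ frame")
    coords = np.array([r[1:4] for r in rows], dtype=float)
    ring_col = np.array([int(r[4]) for r in rows], dtype=np.intp)
    act_col = np.array([int(r[5]) for r in rows], dtype=bool)
    if L is None:
        span = coords.max() - coords.min()
        L = float(2.0 * span + 10.0)  # open-boundary fixture: roomy box
    rings, activity = [], []
    for rid in np.unique(ring_col):
        beads = np.flatnonzero(ring_col == rid)
        rings.append(beads)
        activity.append(bool(act_col[beads[0]]))
    bonds = []
    for beads in rings:
        bonds.extend((beads[k], beads[(k + 1) % len(beads)]) for k in range(len(beads)))
    topo = RingTopology(
        rings=rings,
        n_beads=n_at,
        activity=np.array(activity),
        bond_list=np.array(bonds, dtype=np.intp),
    )
    time = float(meta.get("Time", 0.0))
    frame = MeltFrame(coords=np.mod(coords, L), box_side=L, time=time)
    return frame, topo, meta


def _split_xyz_comment(comment: str) -> list[str]:
    """Split on whitespace outside double quotes."""
    out, cur, inq = [], [], False
    for ch in comment:
        if ch == '"':
            inq = not inq
            cur.append(ch)
        elif ch.isspace() and not inq:
            if cur:
                out.append("".join(cur))
                cur = []
        else:
            cur.append(ch)
    if cur:
        out.append("".join(cur))
    return out


# ---------------------------------------------------------------------------
# unwrapping and centers
# ---------------------------------------------------------------------------


def minimum_image(delta: np.ndarray, box_side: float) -> np.ndarray:
    """Minimum-image convention displacement(s) for a cubic box."""
    return delta - box_side * np.round(delta / box_side)


def unwrap_ring(
    frame: MeltFrame, topology: RingTopology, ring_id: int
) -> np.ndarray:
    """Make one ring continuous across periodic boundaries.

    The first traversal bead stays at its wrapped position; each subsequent
    bead is placed by the minimum-image displacement from its predecessor.
    """
    beads = topology.rings[ring_id]
    wrapped = frame.coords[beads]
    L = frame.box_side
    deltas = minimum_image(np.diff(wrapped, axis=0), L)
    lengths = np.linalg.norm(deltas, axis=1)
    if (lengths >= L / 2).any():
        raise UnwrapAmbiguityError(
            f"ring {ring_id}: minimum-image bond >= L/2; box too small for ring"
        )
    out = np.empty_like(wrapped)
    out[0] = wrapped[0]
    out[1:] = wrapped[0] + np.cumsum(deltas, axis=0)
    if bool(topology.is_ring[ring_id]):
        closing = np.linalg.norm(minimum_image(wrapped[0] - wrapped[-1], L))
        if closing >= L / 2:
            raise UnwrapAmbiguityError(
                f"ring {ring_id}: closing bond >= L/2; box too small for ring"
            )
    return out


def ring_center(frame: MeltFrame, topology: RingTopology, ring_id: int) -> np.ndarray:
    """Center of mass (equal bead masses) of the unwrapped ring.

    May lie outside ``[0, L)``; no re-wrapping is applied.
    """
    return unwrap_ring(frame, topology, ring_id).mean(axis=0)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_frame(
    frame: MeltFrame,
    topology: RingTopology,
    path: str | Path,
    format: str = "xyz",
    label: str | None = None,
) -> None:
    """Write one frame as extended-XYZ (``"xyz"``) or LAMMPS dump (``"dump"``).

    Ring ids and activity labels are stored as per-atom fields.  ``label``
    (XYZ only) lands in the comment line, e.g. a fixture's ground truth.
    """
    if frame.n_beads == 0 or topology.n_rings == 0:
        raise FrameError("frames must contain at least one ring")
    if frame.n_beads != topology.n_beads:
        raise FrameError("frame/topology bead count mismatch")
    path = Path(path)
    L = frame.box_side
    ring_of = topology.ring_of_bead
    if format == "xyz":
        with path.open("w") as fh:
            fh.write(f"{frame.n_beads}\n")
            comment = (
                f'Lattice="{L:.10g} 0 0 0 {L:.10g} 0 0 0 {L:.10g}" '
                'Properties=species:S:1:pos:R:3:ring:I:1:active:I:1 '
                f"Time={frame.time:.10g}"
            )
            if label is not None:
                comment += f' label="{label}"'
            fh.write(comment + "\n")
            for b in range(frame.n_beads):
                x, y, z = frame.coords[b]
                r = ring_of[b]
                fh.write(
                    f"C {x:.10f} {y:.10f} {z:.10f} {r} "
                    f"{int(topology.activity[r])}\n"
                )
    elif format == "dump":
        with path.open("w") as fh:
            _write_dump_frame(fh, frame, topology)
    else:
        raise ValueError(f"unknown format {format!r}; use 'xyz' or 'dump'")


def _write_dump_frame(fh, frame: MeltFrame, topology: RingTopology) -> None:
    L = frame.box_side
    fh.write("ITEM: TIMESTEP\n")
    fh.write(f"{frame.time:.10g}\n")
    fh.write("ITEM: NUMBER OF ATOMS\n")
    fh.write(f"{frame.n_beads}\n")
    fh.write("ITEM: BOX BOUNDS pp pp pp\n")
    for _ in range(3):
        fh.write(f"0.0 {L:.10f}\n")
    ring_of = topology.ring_of_bead
    if frame.images is not None:
        fh.write("ITEM: ATOMS id mol type x y z ix iy iz\n")
        for b in range(frame.n_beads):
            x, y, z = frame.coords[b]
            ix, iy, iz = frame.images[b]
            fh.write(
                f"{b + 1} {ring_of[b] + 1} 1 {x:.10f} {y:.10f} {z:.10f} "
                f"{ix} {iy} {iz}\n"
            )
    else:
        fh.write("ITEM: ATOMS id mol type x y z\n")
        for b in range(frame.n_beads):
            x, y, z = frame.coords[b]
            fh.write(f"{b + 1} {ring_of[b] + 1} 1 {x:.10f} {y:.10f} {z:.10f}\n")


def write_trajectory_dump(
    traj: Trajectory, path: str | Path
) -> None:
    """Write all frames of a trajectory into one text LAMMPS dump file."""
    with Path(path).open("w") as fh:
        for frame in traj.frames:
            _write_dump_frame(fh, frame, traj.topology)


def write_topology_json(topology: RingTopology, path: str | Path) -> None:
    """JSON sidecar: ring traversals, activity labels, ring/linear flags."""
    obj = {
        "n_beads": topology.n_beads,
        "rings": [r.tolist() for r in topology.rings],
        "activity": topology.activity.astype(int).tolist(),
        "is_ring": topology.is_ring.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(obj))


def read_topology_json(path: str | Path) -> RingTopology:
    obj = json.loads(Path(path).read_text())
    rings = [np.asarray(r, dtype=np.intp) for r in obj["rings"]]
    bonds = []
    for beads, isr in zip(rings, obj["is_ring"]):
        m = len(beads)
        last = m if isr else m - 1
        bonds.extend((beads[k], beads[(k + 1) % m]) for k in range(last))
    return RingTopology(
        rings=rings,
        n_beads=obj["n_beads"],
        activity=np.array(obj["activity"], dtype=bool),
        bond_list=np.array(bonds, dtype=np.intp).reshape(-1, 2),
        is_ring=np.array(obj["is_ring"], dtype=bool),
    )
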