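"""Desk-scale Kremer-Grest Langevin engine for active ring melts.

Bead-spring rings with FENE bonds and purely repulsive truncated-shifted
Lennard-Jones (WCA) excluded volume — the combination forbids chain
crossing, so rings can neither knot nor link during dynamics.  Langevin
integration uses the BAOAB splitting with per-bead friction and per-bead
target temperature, which is what makes *active* rings possible: a stretch
of beads in each active ring is thermostated at T_a > T while the rest of
the melt sits at T.  With the thermostat off the step reduces exactly to
velocity Verlet.

Also here: melt initialization (disjoint coiled rings on a lattice,
contracted to target density without chain crossing), ring cutting, and the
pull-apart oracle used as ground truth for pairwise interlocking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .melt_io import (
    MeltFrame,
    RingTopology,
    RinglockError,
    Trajectory,
    minimum_image,
)

__all__ = [
    "SimParams",
    "SimState",
    "InitFailure",
    "IntegrationFailure",
    "init_melt",
    "forces",
    "potential_energy",
    "kinetic_energy",
    "langevin_step",
    "run",
    "cut_ring",
    "pull_apart_oracle",
]


class InitFailure(RinglockError):
    """Melt could not be packed to the target density."""


class IntegrationFailure(RinglockError):
    """Non-finite coordinate or overstretched FENE bond."""


@dataclass(frozen=True)
class SimParams:
    """Kremer-Grest force field, thermostat map and integrator settings.

    Units: lengths sigma, energies epsilon, times tau, k_B = 1, bead mass 1.
    The production-scale system of record is N = 1600 rings x 400 beads at
    rho = 0.85; desk-scale runs use the same physics at smaller N, beads and
    density.
    """

    n_rings: int = 20
    beads_per_ring: int = 60
    active_count: int = 0
    hot_stretch_length: int = 50
    T: float = 1.0
    T_active: float = 3.0
    density: float = 0.85
    damping: float = 1.5  # velocity relaxation time, tau
    dt: float = 0.005
    fene_k: float = 30.0
    fene_r0: float = 1.5
    lj_epsilon: float = 1.0
    lj_sigma: float = 1.0
    lj_cutoff: float = 2.0 ** (1.0 / 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.active_count <= self.n_rings:
            raise ValueError("active_count must be in [0, n_rings]")
        if self.active_count and self.hot_stretch_length > self.beads_per_ring:
            raise ValueError("hot stretch cannot exceed ring length")
        if self.dt <= 0 or self.fene_r0 <= self.lj_sigma - 0.5:
            raise ValueError("bad integrator/force-field constants")

    @property
    def box_side(self) -> float:
        n_beads = self.n_rings * self.beads_per_ring
        return float((n_beads / self.density) ** (1.0 / 3.0))


@dataclass
class SimState:
    """Integrator state; positions are continuous (unwrapped), box periodic."""

    positions: np.ndarray  # (n, 3) unwrapped
    velocities: np.ndarray
    bead_temps: np.ndarray  # per-bead thermostat target
    box_side: float
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def frame(self) -> MeltFrame:
        wrapped = np.mod(self.positions, self.box_side)
        images = np.floor(self.positions / self.box_side).astype(np.intp)
        return MeltFrame(
            coords=wrapped, box_side=self.box_side, time=self.time, images=images
        )


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def _wca_pair_forces(
    pos: np.ndarray,
    box: float | None,
    params: SimParams,
    pairs: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Accumulated WCA forces and energy for the given index pairs."""
    f = np.zeros_like(pos)
    if len(pairs) == 0:
        return f, 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d = pos[i] - pos[j]
    if box is not None:
        d = minimum_image(d, box)
    r2 = np.einsum("ij,ij->i", d, d)
    rc2 = params.lj_cutoff**2 * params.lj_sigma**2
    mask = r2 < rc2
    if not mask.any():
        return f, 0.0
    i, j, d, r2 = i[mask], j[mask], d[mask], r2[mask]
    s2 = params.lj_sigma**2 / r2
    s6 = s2**3
    eps = params.lj_epsilon
    # U = 4 eps (s12 - s6) + eps ; F = 24 eps (2 s12 - s6) / r^2 * d
    fmag = 24.0 * eps * (2.0 * s6**2 - s6) / r2
    fv = fmag[:, None] * d
    np.add.at(f, i, fv)
    np.add.at(f, j, -fv)
    energy = float(np.sum(4.0 * eps * (s6**2 - s6) + eps))
    return f, energy


def _fene_forces(
    pos: np.ndarray, box: float | None, params: SimParams, bonds: np.ndarray
) -> tuple[np.ndarray, float]:
    f = np.zeros_like(pos)
    if len(bonds) == 0:
        return f, 0.0
    i, j = bonds[:, 0], bonds[:, 1]
    d = pos[i] - pos[j]
    if box is not None:
        d = minimum_image(d, box)
    r2 = np.einsum("ij,ij->i", d, d)
    r02 = params.fene_r0**2
    if (r2 >= r02).any():
        raise IntegrationFailure(
            "FENE bond reached maximum extension (dt too large?)"
        )
    denom = 1.0 - r2 / r02
    fmag = -params.fene_k / denom
    fv = fmag[:, None] * d
    np.add.at(f, i, fv)
    np.add.at(f, j, -fv)
    energy = float(np.sum(-0.5 * params.fene_k * r02 * np.log(denom)))
    return f, energy


def _neighbor_pairs(pos: np.ndarray, box: float | None, cutoff: float) -> np.ndarray:
    if box is not None:
        wrapped = np.mod(pos, box)
        # cKDTree requires strictly inside [0, box)
        wrapped[wrapped >= box] = 0.0
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def forces(
    state: SimState,
    topology: RingTopology,
    params: SimParams,
    periodic: bool = True,
) -> np.ndarray:
    """Total FENE + WCA force per bead (minimum image if periodic)."""
    box = state.box_side if periodic else None
    if params.lj_epsilon == 0.0:
        f_wca = np.zeros_like(state.positions)
    else:
        pairs = _neighbor_pairs(
            state.positions, box, params.lj_cutoff * params.lj_sigma
        )
        f_wca, _ = _wca_pair_forces(state.positions, box, params, pairs)
    f_fene, _ = _fene_forces(state.positions, box, params, topology.bond_list)
    return f_wca + f_fene


def potential_energy(
    state: SimState,
    topology: RingTopology,
    params: SimParams,
    periodic: bool = True,
) -> float:
    box = state.box_side if periodic else None
    pairs = _neighbor_pairs(state.positions, box, params.lj_cutoff * params.lj_sigma)
    _, e_wca = _wca_pair_forces(state.positions, box, params, pairs)
    _, e_fene = _fene_forces(state.positions, box, params, topology.bond_list)
    return e_wca + e_fene


def kinetic_energy(state: SimState) -> float:
    return float(0.5 * np.sum(state.velocities**2))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _coiled_ring(n_beads: int, bond: float, turns: int) -> np.ndarray:
    """A closed (turns, 1) torus winding: unknotted, compact, self-avoiding."""
    contour = n_beads * bond
    r_tube = max(0.55, 0.16 * contour / turns)
    r_major = contour / (2 * np.pi * turns)
    t = np.linspace(0.0, 2 * np.pi, n_beads, endpoint=False)
    theta = turns * t
    radial = r_major + r_tube * np.cos(t)
    pts = np.column_stack(
        [radial * np.cos(theta), radial * np.sin(theta), r_tube * np.sin(t)]
    )
    # rescale to the exact contour length
    closed = np.vstack([pts, pts[:1]])
    length = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
    return pts * (contour / length)


def _ring_extent(n_beads: int, bond: float, turns: int) -> float:
    pts = _coiled_ring(n_beads, bond, turns)
    return float(np.linalg.norm(pts, axis=1).max())


def _quench(
    state: SimState,
    topology: RingTopology,
    params: SimParams,
    n_steps: int,
    max_disp: float = 0.05,
) -> None:
    """Displacement-capped steepest descent; small steps keep topology.

    The step scale sits below the overdamped stability bound of the
    WCA/FENE stiffness, so descent converges instead of bouncing.
    """
    for _ in range(n_steps):
        f = forces(state, topology, params)
        step = 1.5e-3 * f
        norms = np.linalg.norm(step, axis=1, keepdims=True)
        scale = np.minimum(1.0, max_disp / np.maximum(norms, 1e-12))
        state.positions += step * scale


def init_melt(params: SimParams, quench_steps: int = 120) -> tuple[SimState, RingTopology]:
    """Pack coiled, mutually disjoint rings to the target density.

    Rings are laid out as compact multi-turn coils on a cubic lattice in a
    box large enough that they are disjoint (hence unknotted, uncatenated
    and unthreaded by construction), then the box and ring centers are
    contracted stepwise toward the target density with displacement-capped
    relaxation sweeps in between, which cannot cross chains.
    """
    rng = np.random.default_rng(params.seed)
    n, m = params.n_rings, params.beads_per_ring
    bond = 0.97 * params.lj_sigma
    turns = 1
    while _ring_extent(m, bond, turns) > 0.22 * m * bond / turns + 3 and turns < 6:
        turns += 1
    extent = _ring_extent(m, bond, turns)

    n_side = int(np.ceil(n ** (1.0 / 3.0)))
    target_L = params.box_side
    cell0 = 2.0 * extent + 1.5 * params.lj_sigma
    L0 = max(n_side * cell0, target_L)

    template = _coiled_ring(m, bond, turns)
    positions = np.empty((n * m, 3))
    rings = []
    cells = [(i, j, k) for i in range(n_side) for j in range(n_side) for k in range(n_side)]
    from .fixtures import _random_rotation  # seeded rotation helper

    for r in range(n):
        i, j, k = cells[r]
        center = (np.array([i, j, k]) + 0.5) * (L0 / n_side)
        R = _random_rotation(rng)
        positions[r * m : (r + 1) * m] = template @ R.T + center
        rings.append(np.arange(r * m, (r + 1) * m))

    activity = np.zeros(n, dtype=bool)
    if params.active_count:
        activity[rng.choice(n, size=params.active_count, replace=False)] = True
    bonds = np.array(
        [(r * m + b, r * m + (b + 1) % m) for r in range(n) for b in range(m)],
        dtype=np.intp,
    )
    topology = RingTopology(
        rings=rings, n_beads=n * m, activity=activity, bond_list=bonds
    )

    bead_temps = np.full(n * m, params.T)
    state = SimState(
        positions=positions,
        velocities=np.zeros((n * m, 3)),
        bead_temps=bead_temps,
        box_side=L0,
        rng=rng,
    )
    _quench(state, topology, params, quench_steps)

    # contract stepwise: rescale ring centers-of-mass affinely, relax
    while state.box_side > target_L * (1.0 + 1e-9):
        new_L = max(target_L, state.box_side * 0.97)
        scale = new_L / state.box_side
        for beads in topology.rings:
            com = state.positions[beads].mean(axis=0)
            state.positions[beads] += com * (scale - 1.0)
        state.box_side = new_L
        _quench(state, topology, params, quench_steps)

    e = potential_energy(state, topology, params) / state.n_beads
    if not np.isfinite(e) or e > 50.0:
        raise InitFailure(
            f"residual energy {e:.1f} eps/bead at rho={params.density}: "
            "density not achievable from coiled-lattice start"
        )
    state.time = 0.0
    return state, topology


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def langevin_step(
    state: SimState,
    topology: RingTopology,
    params: SimParams,
    force: np.ndarray | None = None,
) -> np.ndarray:
    """One BAOAB step; returns the force at the new positions.

    Friction gamma = 1 / damping per unit mass; the O-step noise amplitude
    uses each bead's own target temperature.  gamma = 0 (damping = inf) or
    T = 0 with zero noise reduce to velocity Verlet.
    """
    dt = params.dt
    if force is None:
        force = forces(state, topology, params)
    v = state.velocities + 0.5 * dt * force
    x = state.positions + 0.5 * dt * v
    gamma = 1.0 / params.damping
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * state.bead_temps)[:, None]
    v = c1 * v + c2 * state.rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    state.positions = x
    if not np.isfinite(x).all():
        raise IntegrationFailure("non-finite coordinate")
    new_force = forces(state, topology, params)
    state.velocities = v + 0.5 * dt * new_force
    state.time += dt
    return new_force


def nve_step(
    state: SimState,
    topology: RingTopology,
    params: SimParams,
    force: np.ndarray | None = None,
) -> np.ndarray:
    """Velocity-Verlet step (no thermostat); for energy-conservation checks."""
    dt = params.dt
    if force is None:
        force = forces(state, topology, params)
    v = state.velocities + 0.5 * dt * force
    state.positions = state.positions + dt * v
    new_force = forces(state, topology, params)
    state.velocities = v + 0.5 * dt * new_force
    state.time += dt
    return new_force


def apply_activity(
    state: SimState, topology: RingTopology, params: SimParams
) -> None:
    """Set the hot-stretch thermostat map: first ``hot_stretch_length``
    beads (in traversal order) of each active ring go to T_active."""
    state.bead_temps[:] = params.T
    for r in np.flatnonzero(topology.activity):
        hot = topology.rings[r][: params.hot_stretch_length]
        state.bead_temps[hot] = params.T_active


def run(
    params: SimParams,
    n_steps: int,
    dump_every: int,
    equil_steps: int = 0,
    state: SimState | None = None,
    topology: RingTopology | None = None,
) -> Trajectory:
    """Equilibrate passively, switch activity on at t = 0, record frames.

    Frames carry image flags, so trajectories unwrap exactly.  The first
    recorded frame is the t = 0 state (activity just switched on).
    """
    if state is None or topology is None:
        state, topology = init_melt(params)
    # draw initial velocities at T
    state.velocities = state.rng.standard_normal(
        state.positions.shape
    ) * np.sqrt(params.T)
    state.bead_temps[:] = params.T
    for _ in range(equil_steps):
        langevin_step(state, topology, params)
    apply_activity(state, topology, params)
    state.time = 0.0
    frames = [state.frame()]
    for step in range(1, n_steps + 1):
        langevin_step(state, topology, params)
        if step % dump_every == 0:
            frames.append(state.frame())
    return Trajectory(frames=frames, topology=topology)


# ---------------------------------------------------------------------------
# interventions
# ---------------------------------------------------------------------------


def cut_ring(
    state: SimState, topology: RingTopology, ring_id: int
) -> tuple[SimState, RingTopology]:
    """Open one ring into a linear chain by removing a single bond.

    The removed bond is the one with the lowest (sorted) bead-id pair, so
    cuts are deterministic.  Returns updated topology (the state itself is
    unchanged: no beads move).
    """
    if not topology.is_ring[ring_id]:
        raise ValueError(f"molecule {ring_id} is already linear")
    beads = topology.rings[ring_id]
    m = len(beads)
    ring_bonds = [
        tuple(sorted((int(beads[k]), int(beads[(k + 1) % m])))) for k in range(m)
    ]
    cut = min(ring_bonds)
    keep = [
        k
        for k, (a, b) in enumerate(topology.bond_list)
        if tuple(sorted((int(a), int(b)))) != cut
    ]
    new_bonds = topology.bond_list[keep]
    # reorder traversal into a path starting after the removed bond
    k_cut = ring_bonds.index(cut)
    path = np.concatenate([beads[k_cut + 1 :], beads[: k_cut + 1]])
    new_rings = list(topology.rings)
    new_rings[ring_id] = path
    is_ring = topology.is_ring.copy()
    is_ring[ring_id] = False
    new_topo = RingTopology(
        rings=new_rings,
        n_beads=topology.n_beads,
        activity=topology.activity.copy(),
        bond_list=new_bonds,
        is_ring=is_ring,
    )
    return state, new_topo


# ---------------------------------------------------------------------------
# pull-apart oracle
# ---------------------------------------------------------------------------


def pull_apart_oracle(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    params: SimParams = SimParams(),
    max_steps: int = 100_000,
    pull_force: float = 8.0,
    check_every: int = 200,
    plateau_tol: float = 2e-2,
    plateau_window: int = 6,
) -> str:
    """Pull two isolated rings apart along their COM axis at T = 0.

    The pair is first quenched (no pull) to remove construction stresses,
    then equal and opposite constant forces (``pull_force`` total per ring,
    spread over its beads) act along the COM separation axis while FENE
    bonds and WCA excluded volume stay on.  Integration is damped
    velocity-Verlet at zero temperature with a per-step displacement cap,
    so chains cannot cross.  Returns ``"separated"`` once the COM distance
    exceeds three times the summed contour radii — or, earlier, once the
    rings are linearly separable with a full bead-diameter margin, after
    which outward pulling cannot re-entangle them; ``"stuck"`` on a COM-
    distance plateau or step exhaustion; ``"indeterminate"`` on integration
    failure.
    """
    from .separability import separating_plane

    a = np.asarray(coords_a, dtype=float).copy()
    b = np.asarray(coords_b, dtype=float).copy()
    na, nb = len(a), len(b)
    pos = np.vstack([a, b])
    vel = np.zeros_like(pos)
    bonds = np.array(
        [((k, (k + 1) % na)) for k in range(na)]
        + [(na + k, na + (k + 1) % nb) for k in range(nb)],
        dtype=np.intp,
    )
    contour = lambda X: np.linalg.norm(
        np.diff(np.vstack([X, X[:1]]), axis=0), axis=1
    ).sum()
    target = 3.0 * (contour(a) + contour(b)) / (2.0 * np.pi)

    dt, gamma, max_disp = 0.01, 1.0, 0.04
    skin = 0.4
    cutoff = params.lj_cutoff * params.lj_sigma
    pairs = _neighbor_pairs(pos, None, cutoff + skin)
    rebuild_every = max(1, int(skin / (2 * max_disp)))

    def internal_forces(pos, pairs):
        f, _ = _wca_pair_forces(pos, None, params, pairs)
        fb, _ = _fene_forces(pos, None, params, bonds)
        return f + fb

    def damped_step(f_ext):
        nonlocal pos, vel
        f = internal_forces(pos, pairs) + f_ext - gamma * vel
        vel = vel + dt * f
        dx = dt * vel
        norms = np.linalg.norm(dx, axis=1, keepdims=True)
        scale = np.minimum(1.0, max_disp / np.maximum(norms, 1e-12))
        dx *= scale
        vel = dx / dt  # keep velocity consistent with the capped move
        pos = pos + dx

    zero_ext = np.zeros_like(pos)
    try:
        # quench construction stresses before pulling
        for step in range(1500):
            if step % rebuild_every == 0:
                pairs = _neighbor_pairs(pos, None, cutoff + skin)
            if (
                step % 50 == 0
                and np.linalg.norm(internal_forces(pos, pairs), axis=1).max() < 3.0
            ):
                break
            damped_step(zero_ext)
        vel[:] = 0.0

        history: list[float] = []
        for step in range(max_steps):
            com_a = pos[:na].mean(axis=0)
            com_b = pos[na:].mean(axis=0)
            axis = com_b - com_a
            dist = float(np.linalg.norm(axis))
            if dist > target:
                return "separated"
            axis = axis / max(dist, 1e-9)
            if step % check_every == 0:
                res = separating_plane(pos[:na], pos[na:])
                if res.separable and res.margin > params.lj_sigma:
                    return "separated"
                history.append(dist)
                if (
                    len(history) > plateau_window
                    and history[-1] - history[-1 - plateau_window] < plateau_tol
                ):
                    return "stuck"
            if step % rebuild_every == 0:
                pairs = _neighbor_pairs(pos, None, cutoff + skin)
            f_ext = np.zeros_like(pos)
            f_ext[:na] = -(pull_force / na) * axis
            f_ext[na:] = (pull_force / nb) * axis
            damped_step(f_ext)
    except (IntegrationFailure, FloatingPointError):
        return "indeterminate"
    return "stuck"
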