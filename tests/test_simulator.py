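"""Kremer-Grest engine: forces, thermostats, init, cutting, pull oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

from ringlock.fixtures import make_labeled_pair
from ringlock.melt_io import RingTopology
from ringlock.separability import candidate_pairs
from ringlock.simulator import (
    SimParams,
    SimState,
    _quench,
    cut_ring,
    forces,
    init_melt,
    kinetic_energy,
    langevin_step,
    nve_step,
    potential_energy,
    pull_apart_oracle,
    run,
)


def _single_ring(m=20, bond=0.9609, center=(10.0, 10.0, 10.0)):
    R = m * bond / (2 * np.pi)
    t = np.linspace(0, 2 * np.pi, m, endpoint=False)
    pos = np.column_stack(
        [R * np.cos(t), R * np.sin(t), np.zeros(m)]
    ) + np.asarray(center)
    topo = RingTopology(
        rings=[np.arange(m)],
        n_beads=m,
        activity=np.zeros(1, bool),
        bond_list=np.array([(k, (k + 1) % m) for k in range(m)]),
    )
    return pos, topo


class TestForces:
    def test_isolated_bead_zero_force(self):
        topo = RingTopology(
            rings=[np.array([0])],
            n_beads=1,
            activity=np.zeros(1, bool),
            bond_list=np.empty((0, 2), dtype=np.intp),
        )
        state = SimState(
            positions=np.array([[5.0, 5.0, 5.0]]),
            velocities=np.zeros((1, 3)),
            bead_temps=np.ones(1),
            box_side=10.0,
        )
        np.testing.assert_allclose(
            forces(state, topo, SimParams(n_rings=1, beads_per_ring=1)), 0.0
        )

    def test_bonded_pair_rest_length(self):
        """Zero-force separation matches a 1-D root find of dU/dr."""
        params = SimParams(n_rings=1, beads_per_ring=2)

        def dU(r):  # FENE attraction + WCA repulsion
            fene = params.fene_k * r / (1 - (r / params.fene_r0) ** 2)
            s6 = (params.lj_sigma / r) ** 6
            wca = -24 * params.lj_epsilon * (2 * s6**2 - s6) / r
            return fene + wca

        r_star = brentq(dU, 0.8, 1.1)
        assert r_star == pytest.approx(0.961, abs=0.005)
        # numerical force at r_star vanishes along the bond
        topo = RingTopology(
            rings=[np.array([0, 1])],
            n_beads=2,
            activity=np.zeros(1, bool),
            bond_list=np.array([[0, 1]]),
        )
        pos = np.array([[5.0, 5, 5], [5.0 + r_star, 5, 5]])
        state = SimState(
            positions=pos,
            velocities=np.zeros((2, 3)),
            bead_temps=np.ones(2),
            box_side=20.0,
        )
        f = forces(state, topo, params)
        assert np.abs(f).max() < 1e-6


class TestIntegration:
    def test_nve_energy_drift_bounded(self):
        pos, topo = _single_ring()
        params = SimParams(n_rings=1, beads_per_ring=20, dt=2.5e-4)
        state = SimState(
            positions=pos,
            velocities=np.zeros_like(pos),
            bead_temps=np.ones(20),
            box_side=40.0,
            rng=np.random.default_rng(0),
        )
        _quench(state, topo, params, 4000)
        state.velocities = 0.05 * np.random.default_rng(1).standard_normal(pos.shape)
        e0 = potential_energy(state, topo, params) + kinetic_energy(state)
        f = None
        for _ in range(10_000):
            f = nve_step(state, topo, params, f)
        e1 = potential_energy(state, topo, params) + kinetic_energy(state)
        assert abs(e1 - e0) / topo.n_beads < 1e-4

    def test_zero_temperature_fixed_point(self):
        """No forces, zero velocity, zero temperature: state is unchanged."""
        topo = RingTopology(
            rings=[np.arange(4)],
            n_beads=4,
            activity=np.zeros(1, bool),
            bond_list=np.empty((0, 2), dtype=np.intp),
        )
        params = SimParams(
            n_rings=1, beads_per_ring=4, lj_epsilon=0.0, T=0.0, dt=0.01
        )
        pos = np.random.default_rng(0).uniform(0, 10, (4, 3))
        state = SimState(
            positions=pos.copy(),
            velocities=np.zeros((4, 3)),
            bead_temps=np.zeros(4),
            box_side=10.0,
            rng=np.random.default_rng(1),
        )
        for _ in range(50):
            langevin_step(state, topo, params)
        np.testing.assert_allclose(state.positions, pos, atol=1e-14)

    def test_equipartition_two_thermostat_groups(self):
        """Free beads reach (3/2)T per group, passive and hot."""
        n = 1500
        topo = RingTopology(
            rings=[np.arange(n)],
            n_beads=n,
            activity=np.zeros(1, bool),
            bond_list=np.empty((0, 2), dtype=np.intp),
        )
        params = SimParams(
            n_rings=1, beads_per_ring=n, lj_epsilon=0.0, dt=0.01, seed=0
        )
        temps = np.where(np.arange(n) < n // 2, params.T, params.T_active)
        state = SimState(
            positions=np.random.default_rng(2).uniform(0, 50, (n, 3)),
            velocities=np.zeros((n, 3)),
            bead_temps=temps,
            box_side=50.0,
            rng=np.random.default_rng(3),
        )
        ke_cold = ke_hot = count = 0.0
        for step in range(2500):
            langevin_step(state, topo, params)
            if step >= 600 and step % 20 == 0:
                v2 = np.sum(state.velocities**2, axis=1)
                ke_cold += 0.5 * v2[: n // 2].mean()
                ke_hot += 0.5 * v2[n // 2 :].mean()
                count += 1
        assert ke_cold / count == pytest.approx(1.5 * params.T, rel=0.02)
        assert ke_hot / count == pytest.approx(1.5 * params.T_active, rel=0.02)


class TestMeltLifecycle:
    def test_init_is_disentangled(self, desk_melt):
        state, topo = desk_melt
        assert candidate_pairs(state.frame(), topo) == []

    def test_run_deterministic_and_bonded(self, desk_params, short_traj):
        other = run(desk_params, n_steps=600, dump_every=150, equil_steps=200)
        for a, b in zip(short_traj.frames, other.frames):
            np.testing.assert_array_equal(a.coords, b.coords)
        from ringlock.melt_io import unwrap_ring

        for frame in short_traj.frames:
            for r in range(short_traj.topology.n_rings):
                x = unwrap_ring(frame, short_traj.topology, r)
                bonds = np.linalg.norm(
                    np.diff(np.vstack([x, x[:1]]), axis=0), axis=1
                )
                assert bonds.max() < desk_params.fene_r0

    def test_hot_stretch_thermostat_map(self):
        params = SimParams(
            n_rings=4,
            beads_per_ring=20,
            density=0.1,
            active_count=2,
            hot_stretch_length=8,
            seed=3,
        )
        traj = run(params, n_steps=10, dump_every=10, equil_steps=0)
        assert int(traj.topology.activity.sum()) == 2


class TestCutRing:
    def test_cut_makes_path(self, desk_melt):
        state, topo = desk_melt
        _, topo2 = cut_ring(state, topo, 0)
        assert not topo2.is_ring[0]
        assert len(topo2.bond_list) == len(topo.bond_list) - 1
        # the cut molecule's traversal is a path visiting every bead once
        path = topo2.rings[0]
        assert len(path) == len(topo.rings[0])
        assert len(np.unique(path)) == len(path)
        with pytest.raises(ValueError, match="already linear"):
            cut_ring(state, topo2, 0)

    def test_energy_drops_by_cut_bond_energy(self, desk_melt, desk_params):
        state, topo = desk_melt
        e_before = potential_energy(state, topo, desk_params)
        _, topo2 = cut_ring(state, topo, 2)
        e_after = potential_energy(state, topo2, desk_params)
        cut_bond = set(map(tuple, topo.bond_list.tolist())) - set(
            map(tuple, topo2.bond_list.tolist())
        )
        (a, b), = cut_bond
        from ringlock.melt_io import minimum_image

        r2 = float(
            np.sum(
                minimum_image(
                    state.positions[a] - state.positions[b], state.box_side
                )
                ** 2
            )
        )
        r02 = desk_params.fene_r0**2
        fene = -0.5 * desk_params.fene_k * r02 * np.log(1 - r2 / r02)
        assert e_before - e_after == pytest.approx(fene, rel=1e-9)

    def test_cut_rings_skipped_by_pair_scan(self, desk_melt):
        state, topo = desk_melt
        for r in range(topo.n_rings):
            _, topo = cut_ring(state, topo, r)
        assert candidate_pairs(state.frame(), topo) == []


class TestPullOracle:
    def test_distant_circles_separate_fast(self):
        pair = make_labeled_pair("separable", 7)
        assert pull_apart_oracle(pair.ring_a, pair.ring_b) == "separated"

    def test_threaded_hairpin_separates(self):
        pair = make_labeled_pair("threaded_free", 7)
        assert pull_apart_oracle(pair.ring_a, pair.ring_b) == "separated"

    def test_clasp_sticks(self):
        pair = make_labeled_pair("deadlocked", 7)
        assert pull_apart_oracle(pair.ring_a, pair.ring_b) == "stuck"
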