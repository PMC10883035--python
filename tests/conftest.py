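"""Shared fixtures: small melts and trajectories built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ringlock.simulator import SimParams, init_melt, run


@pytest.fixture(scope="session")
def desk_params() -> SimParams:
    """Desk-scale melt conditions: 8 rings x 20 beads at rho = 0.2."""
    return SimParams(n_rings=8, beads_per_ring=20, density=0.2, seed=11)


@pytest.fixture(scope="session")
def desk_melt(desk_params):
    """Freshly packed desk melt (state, topology)."""
    return init_melt(desk_params)


@pytest.fixture(scope="session")
def short_traj(desk_params):
    """A short thermal trajectory of the desk melt with image flags."""
    return run(desk_params, n_steps=600, dump_every=150, equil_steps=200)


def circle_ring(n: int, radius: float, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), np.zeros(n)]
    ) + np.asarray(center)
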