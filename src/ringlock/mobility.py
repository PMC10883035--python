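"""Ring mobility and diffusion timescales.

The central observable is the cumulative mobility

    mu(t, t0) = <g3(t, t0)> / (t - t0)

where <g3(a, b)> is the mean squared displacement of ring centers of mass
between times a and b, averaged over a ring subset (default: all rings,
passive and active).  For pure diffusion mu is constant and equals 6D.
The ring self-diffusion time is tau_diff = <Rg^2> / (6 D).

COM displacements use continuously unwrapped trajectories: image counters
are taken from frame image flags when present, otherwise accumulated
frame-to-frame via minimum-image displacements — never minimum image
between distant frames, which would fail once displacements exceed L/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .melt_io import Trajectory, minimum_image

__all__ = [
    "MobilitySeries",
    "DiffusionSummary",
    "com_tracks",
    "g3",
    "mu",
    "group_mobility",
    "tau_diff",
    "log_spaced_times",
]

#: Groups smaller than this fraction of the rings are flagged as scarce.
SCARCE_FRACTION = 0.01


@dataclass(frozen=True)
class MobilitySeries:
    times: np.ndarray
    t0: float
    g3_values: np.ndarray  # sigma^2
    mu_values: np.ndarray  # sigma^2 / tau
    label: str
    scarce: np.ndarray | None = None  # per-time flag: group below threshold
    group_sizes: np.ndarray | None = None


@dataclass(frozen=True)
class DiffusionSummary:
    rg_sq: float  # <Rg^2>, sigma^2
    D: float  # COM diffusion coefficient, sigma^2/tau
    tau_diff: float  # <Rg^2> / (6 D), tau
    fit_window: tuple[float, float]
    fit_r2: float
    sublinear_warning: bool


def com_tracks(traj: Trajectory) -> np.ndarray:
    """(n_frames, n_rings, 3) continuous COM tracks.

    Per-bead positions are unwrapped with image flags when the frames carry
    them, else by accumulating minimum-image displacements between
    consecutive frames; ring COMs are plain means (equal masses).
    """
    topo = traj.topology
    n_frames = len(traj)
    out = np.empty((n_frames, topo.n_rings, 3))
    sizes = topo.beads_per_ring
    uniform = bool((sizes == sizes[0]).all())
    order = np.concatenate(topo.rings) if uniform else None
    have_images = all(f.images is not None for f in traj.frames)
    if have_images:
        for fi, frame in enumerate(traj.frames):
            unwrapped = frame.unwrapped()
            if uniform:
                out[fi] = unwrapped[order].reshape(topo.n_rings, sizes[0], 3).mean(axis=1)
            else:
                for r, beads in enumerate(topo.rings):
                    out[fi, r] = unwrapped[beads].mean(axis=0)
        return out
    # accumulate continuity frame-to-frame
    prev = traj.frames[0].coords.copy()
    cont = prev.copy()
    for fi, frame in enumerate(traj.frames):
        if fi > 0:
            L = frame.box_side
            cont = cont + minimum_image(frame.coords - prev, L)
            prev = frame.coords.copy()
        if uniform:
            out[fi] = cont[order].reshape(topo.n_rings, sizes[0], 3).mean(axis=1)
        else:
            for r, beads in enumerate(topo.rings):
                out[fi, r] = cont[beads].mean(axis=0)
    return out


def _frame_index(traj: Trajectory, t: float) -> int:
    times = traj.times
    idx = int(np.argmin(np.abs(times - t)))
    if abs(times[idx] - t) > 1e-9 * max(1.0, abs(t)):
        raise ValueError(f"no frame at time {t}; nearest is {times[idx]}")
    return idx


def g3(
    traj: Trajectory,
    a: float,
    b: float,
    ring_subset: np.ndarray | list[int] | None = None,
    tracks: np.ndarray | None = None,
) -> float:
    """Mean squared COM displacement between times ``a`` and ``b``."""
    if tracks is None:
        tracks = com_tracks(traj)
    ia, ib = _frame_index(traj, a), _frame_index(traj, b)
    subset = (
        np.arange(tracks.shape[1])
        if ring_subset is None
        else np.asarray(ring_subset, dtype=np.intp)
    )
    if len(subset) == 0:
        raise ValueError("ring subset is empty")
    disp = tracks[ib, subset] - tracks[ia, subset]
    return float(np.mean(np.sum(disp**2, axis=1)))


def mu(
    traj: Trajectory,
    t: float,
    t0: float = 0.0,
    ring_subset: np.ndarray | list[int] | None = None,
    tracks: np.ndarray | None = None,
) -> float:
    """Mobility mu(t, t0) = <g3(t, t0)> / (t - t0); requires t > t0."""
    if t <= t0:
        raise ValueError("mu requires t > t0")
    return g3(traj, t0, t, ring_subset, tracks) / (t - t0)


def log_spaced_times(
    t_min: float, t_max: float, points_per_decade: int = 4
) -> np.ndarray:
    """Base-10 log-spaced grid in [t_min, t_max]."""
    n = max(2, int(np.ceil(np.log10(t_max / t_min) * points_per_decade)) + 1)
    return np.logspace(np.log10(t_min), np.log10(t_max), n)


def group_mobility(
    traj: Trajectory,
    labels_per_frame: dict[float, dict[int, str]],
    times: np.ndarray,
) -> dict[str, MobilitySeries]:
    """Interval mobility mu(t_i, t_{i-1}) per ring label at log-spaced times.

    ``labels_per_frame[t]`` maps ring id -> label (e.g. deadlocked / NtD /
    NtN / unthreaded) at time t; the subset for the interval ending at t_i
    is the set labeled at t_i.  Groups below 1% of the rings (or 3 rings)
    are flagged scarce but still reported.
    """
    times = np.asarray(times, dtype=float)
    tracks = com_tracks(traj)
    n_rings = tracks.shape[1]
    threshold = max(3, int(np.ceil(SCARCE_FRACTION * n_rings)))
    all_labels = sorted({lab for at in labels_per_frame.values() for lab in at.values()})
    out: dict[str, MobilitySeries] = {}
    for label in all_labels:
        ts, g3s, mus, scarce, sizes = [], [], [], [], []
        for t_prev, t_i in zip(times[:-1], times[1:]):
            if t_i not in labels_per_frame:
                raise ValueError(f"no labels for frame time {t_i}")
            subset = [r for r, lab in labels_per_frame[t_i].items() if lab == label]
            if not subset:
                continue
            val = g3(traj, t_prev, t_i, subset, tracks)
            ts.append(t_i)
            g3s.append(val)
            mus.append(val / (t_i - t_prev))
            scarce.append(len(subset) < threshold)
            sizes.append(len(subset))
        out[label] = MobilitySeries(
            times=np.array(ts),
            t0=float(times[0]),
            g3_values=np.array(g3s),
            mu_values=np.array(mus),
            label=label,
            scarce=np.array(scarce, dtype=bool),
            group_sizes=np.array(sizes, dtype=np.intp),
        )
    return out


def radius_of_gyration_sq(traj: Trajectory) -> float:
    """Time- and ring-averaged squared radius of gyration (discrete beads)."""
    from .melt_io import unwrap_ring

    total, count = 0.0, 0
    for frame in traj.frames:
        for r in range(traj.topology.n_rings):
            x = unwrap_ring(frame, traj.topology, r)
            com = x.mean(axis=0)
            total += float(np.mean(np.sum((x - com) ** 2, axis=1)))
            count += 1
    return total / count


def tau_diff(
    traj: Trajectory,
    fit_fraction: tuple[float, float] = (0.5, 1.0),
    rg_sq: float | None = None,
) -> DiffusionSummary:
    """Ring self-diffusion time tau_diff = <Rg^2> / (6 D).

    D comes from a least-squares slope of the COM MSD (from the first
    frame) over the configured late-time window — by default the last half
    of the trajectory, where the MSD of a diffusing ring is linear.  A
    sublinear MSD (poor linear fit) raises a warning but still returns the
    fit with diagnostics.
    """
    tracks = com_tracks(traj)
    times = traj.times
    disp = tracks - tracks[0]
    msd = np.mean(np.sum(disp**2, axis=2), axis=1)
    lo = times[0] + fit_fraction[0] * (times[-1] - times[0])
    hi = times[0] + fit_fraction[1] * (times[-1] - times[0])
    window = (times >= lo) & (times <= hi)
    if window.sum() < 3:
        raise ValueError("fit window holds fewer than 3 frames")
    tw, mw = times[window], msd[window]
    slope, intercept = np.polyfit(tw, mw, 1)
    pred = slope * tw + intercept
    ss_res = float(np.sum((mw - pred) ** 2))
    ss_tot = float(np.sum((mw - mw.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sublinear = r2 < 0.9 or slope <= 0
    if sublinear:
        warnings.warn("COM MSD is not linear over the fit window", stacklevel=2)
    D = max(slope, 1e-300) / 6.0
    rg2 = radius_of_gyration_sq(traj) if rg_sq is None else rg_sq
    return DiffusionSummary(
        rg_sq=rg2,
        D=D,
        tau_diff=rg2 / (6.0 * D),
        fit_window=(float(lo), float(hi)),
        fit_r2=r2,
        sublinear_warning=sublinear,
    )
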