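"""Step-wise integration of the non-autonomous toggle switch.

Parameters are held constant within each dt_step window (sampled at the
window start), the autonomous system is integrated across the window, and
the end state is carried over as the next window's initial condition.  Each
window has a frozen phase portrait against which the trajectory's basin
membership is resolved; because dynamics within a window are autonomous,
the basin label cannot change inside a window — basin changes, and hence
all mechanism events, are resolved at window granularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import ToggleParams, vector_field
from .portrait import PhasePortrait, assign_basin, compute_portrait
from .schedule import ParamSchedule

log = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Time-stamped states with per-window portrait and basin annotations.

    ``window_index`` maps each sample to the dt_step window it belongs to;
    ``window_basin`` holds one basin label per window (an attractor lineage
    id once lineages are tracked, or a portrait-local attractor index
    before; ``None`` where unresolved).
    """

    times: np.ndarray
    states: np.ndarray
    window_index: np.ndarray
    window_basin: list[int | None]
    window_params: list[ToggleParams]
    schedule: ParamSchedule | None = None

    def __post_init__(self):
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have matching lengths")

    @property
    def n_windows(self) -> int:
        return len(self.window_basin)

    def basin_at_sample(self, i: int) -> int | None:
        return self.window_basin[int(self.window_index[i])]

    @property
    def basin_per_sample(self) -> list[int | None]:
        return [self.window_basin[int(k)] for k in self.window_index]


@dataclass
class RunResult:
    """Everything a non-autonomous run produces: the trajectory, the frozen
    portrait of each window, and (after lineage tracking) bifurcations."""

    trajectory: Trajectory
    portraits: list[PhasePortrait]
    schedule: ParamSchedule


def _integrate_window(p: ToggleParams, s0: np.ndarray, t0: float, t1: float,
                      n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    def fld(t, s):
        return vector_field(s, p)

    ts = np.linspace(t0, t1, n_samples + 1)
    sol = solve_ivp(fld, (t0, t1), s0, t_eval=ts, rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(
            f"integration failed in window [{t0}, {t1}]: {sol.message}"
        )
    states = sol.y.T
    if np.min(states) < -1e-10:
        raise RuntimeError(
            f"state went negative ({np.min(states):.3e}) in window [{t0}, {t1}]"
        )
    return ts, np.clip(states, 0.0, None)


def integrate(
    sch: ParamSchedule,
    s0,
    samples_per_step: int = 10,
    portraits: list[PhasePortrait] | None = None,
    basin_t_max: float = 400.0,
    conv_tol: float = 1e-3,
    portrait_grid_n: int = 7,
) -> RunResult:
    """Run the step-wise scheme over the whole schedule horizon.

    Per window: parameters are sampled at the window start, the autonomous
    system is integrated with adaptive error control, and the window-start
    state's basin is resolved against the window's frozen portrait.  Pass
    precomputed ``portraits`` (one per window) to reuse them.
    """
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != (2,) or np.any(~np.isfinite(s0)) or np.any(s0 < 0):
        raise ValueError(f"initial state must be a finite non-negative pair, got {s0!r}")

    if portraits is None:
        portraits = [
            compute_portrait(sch.params_at(t0), grid_n=portrait_grid_n)
            for t0 in sch.window_starts()
        ]
    elif len(portraits) != sch.n_windows:
        raise ValueError("portraits must match the schedule's window count")

    all_t: list[np.ndarray] = []
    all_s: list[np.ndarray] = []
    all_w: list[np.ndarray] = []
    basins: list[int | None] = []
    params: list[ToggleParams] = []
    state = s0
    for k in range(sch.n_windows):
        t0, t1 = sch.window_bounds(k)
        p = sch.continuous_at(t0)
        params.append(p)
        basins.append(assign_basin(state, portraits[k], t_max=basin_t_max,
                                   conv_tol=conv_tol))
        ts, states = _integrate_window(p, state, t0, t1, samples_per_step)
        if k > 0:  # drop duplicated boundary sample
            ts, states = ts[1:], states[1:]
        all_t.append(ts)
        all_s.append(states)
        all_w.append(np.full(len(ts), k))
        state = states[-1]

    traj = Trajectory(
        times=np.concatenate(all_t),
        states=np.concatenate(all_s),
        window_index=np.concatenate(all_w),
        window_basin=basins,
        window_params=params,
        schedule=sch,
    )
    return RunResult(trajectory=traj, portraits=portraits, schedule=sch)


def integrate_autonomous(
    p: ToggleParams,
    s0,
    t_final: float,
    n_samples: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-shot autonomous integration (no windows); reference for the
    degenerate constant-schedule case and workhorse for quasi-potential
    seeding."""
    s0 = np.asarray(s0, dtype=float)
    return _integrate_window(p, s0, 0.0, t_final, n_samples)


def self_intersects(states: np.ndarray, exclusion: int = 1) -> bool:
    """Whether the planar polyline of trajectory states crosses itself.

    Segment pairs closer than ``exclusion`` indices are skipped (adjacent
    segments always share an endpoint).  Autonomous planar trajectories can
    never self-intersect; under a changing phase portrait they can — the
    geometric-capture scenario makes the path loop over itself.
    """
    pts = np.asarray(states, dtype=float)
    n = len(pts) - 1
    if n < 3:
        return False
    a, b = pts[:-1], pts[1:]

    def orient(p, q, r):
        return (q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1]) - (
            q[..., 1] - p[..., 1]
        ) * (r[..., 0] - p[..., 0])

    for i in range(n - 2):
        js = np.arange(i + 1 + exclusion, n)
        if js.size == 0:
            continue
        p1, p2 = a[i], b[i]
        q1, q2 = a[js], b[js]
        d1 = orient(p1[None, :], p2[None, :], q1)
        d2 = orient(p1[None, :], p2[None, :], q2)
        d3 = orient(q1, q2, np.broadcast_to(p1, q1.shape))
        d4 = orient(q1, q2, np.broadcast_to(p2, q1.shape))
        crossing = (d1 * d2 < 0) & (d3 * d4 < 0)
        if np.any(crossing):
            return True
    return False
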