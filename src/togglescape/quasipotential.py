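"""Numerical quasi-potential landscapes for one fixed parameter set.

The toggle switch is not a gradient system (its cross partials differ), so
no closed-form potential exists.  The quasi-potential V_q is built instead
by accumulating increments along sampled autonomous trajectories:

    dV_q = -[(dx/dt)^2 + (dy/dt)^2] dt

which is non-positive by construction and zero exactly at steady states —
a Lyapunov function of the flow, so trajectories always run downhill on
the surface.  Discrete trajectories are stitched into one surface by two
normalisation assumptions: trajectories converging to the same attractor
share a final level (within-basin), and the nearest pair of start points
on opposite sides of a separatrix share an initial level (between-basin).
Linear interpolation of the normalised samples on a triangulation yields
the landscape; no smoothing is applied, so no artefactual minima are
introduced, and cells outside the sampled hull are left absent (NaN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata

from .integrate import Trajectory, integrate_autonomous
from .model import ToggleParams, vector_field
from .portrait import PhasePortrait, compute_portrait

log = logging.getLogger(__name__)


def delta_vq(rate, dt: float) -> float:
    """Quasi-potential increment for one small step: -(fx^2 + fy^2) dt.

    Non-positive for dt > 0, and zero only when the flow vanishes, i.e. at
    a steady state.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    rate = np.asarray(rate, dtype=float)
    return float(-(rate[0] ** 2 + rate[1] ** 2) * dt)


def accumulate(times: np.ndarray, states: np.ndarray, p: ToggleParams) -> np.ndarray:
    """V_q along one autonomous trajectory, provisional zero at the start.

    Each segment's increment uses the flow at the segment midpoint state,
    so the accumulated sequence is non-increasing and refines with denser
    sampling.
    """
    times = np.asarray(times, dtype=float)
    states = np.asarray(states, dtype=float)
    if len(times) != len(states):
        raise ValueError("times and states must match")
    mid = 0.5 * (states[:-1] + states[1:])
    rates = vector_field(mid.T, p)
    dts = np.diff(times)
    if np.any(dts <= 0):
        raise ValueError("times must be strictly increasing")
    dv = -(rates[0] ** 2 + rates[1] ** 2) * dts
    return np.concatenate([[0.0], np.cumsum(dv)])


def accumulate_trajectory(traj: Trajectory) -> np.ndarray:
    """V_q along a packaged trajectory; requires a constant schedule — the
    quasi-potential is only defined per fixed parameter set."""
    params = set(traj.window_params)
    if len(params) != 1:
        raise ValueError(
            "quasi-potential accumulation requires a constant schedule "
            f"(trajectory visits {len(params)} parameter sets)"
        )
    return accumulate(traj.times, traj.states, next(iter(params)))


@dataclass
class _SeedRun:
    states: np.ndarray
    vq: np.ndarray
    basin: int  # attractor index within the portrait


@dataclass
class QuasiPotentialSurface:
    grid_x: np.ndarray
    grid_y: np.ndarray
    V: np.ndarray  # shape (len(grid_x), len(grid_y)); NaN outside sampled hull
    basin_offsets: dict[int, float]
    n_trajectories: int
    params: ToggleParams

    def local_minima(self) -> list[tuple[float, float]]:
        """Interior grid nodes strictly below all eight neighbours (nodes
        with any absent neighbour are excluded)."""
        V = self.V
        out = []
        for i in range(1, V.shape[0] - 1):
            for j in range(1, V.shape[1] - 1):
                patch = V[i - 1:i + 2, j - 1:j + 2].copy()
                if np.any(np.isnan(patch)):
                    continue
                c = V[i, j]
                patch[1, 1] = np.inf
                if c < np.min(patch):
                    out.append((float(self.grid_x[i]), float(self.grid_y[j])))
        return out

    @property
    def grid_cell(self) -> tuple[float, float]:
        return (float(self.grid_x[1] - self.grid_x[0]),
                float(self.grid_y[1] - self.grid_y[0]))


def _truncate_at_convergence(times, states, attractors, conv_tol):
    d = np.linalg.norm(states[:, None, :] - attractors[None, :, :], axis=2)
    hit = np.argwhere(np.min(d, axis=1) < conv_tol)
    if hit.size == 0:
        return times, states, None
    i = int(hit[0, 0])
    basin = int(np.argmin(d[i]))
    i = max(i, 1)
    return times[: i + 1], states[: i + 1], basin


def normalize(runs: list[_SeedRun], pp: PhasePortrait) -> tuple[list[np.ndarray], dict[int, float]]:
    """Apply the two levelling assumptions to accumulated trajectories.

    Within each basin, every trajectory is shifted so its terminal level is
    the basin's common level (the attractor level).  Between basins, each
    basin's additive constant is anchored so that the nearest pair of start
    points lying in different basins share the same initial level.  Returns
    the shifted V_q arrays and the per-basin offsets.
    """
    basins = sorted({r.basin for r in runs})
    by_basin = {b: [r for r in runs if r.basin == b] for b in basins}
    n_att = sum(1 for s in pp.steady_states if s.kind == "attractor")
    missing = [b for b in range(n_att) if b not in by_basin]
    if missing:
        raise ValueError(
            f"no converged trajectory for basin(s) {missing}; "
            "increase the seed grid or integration horizon"
        )

    # within-basin: terminal level zero, then the basin offset is added
    shifted = {id(r): r.vq - r.vq[-1] for r in runs}

    offsets: dict[int, float] = {basins[0]: 0.0}
    anchored = {basins[0]}
    while len(anchored) < len(basins):
        best = None  # (dist, basin, offset)
        for b in basins:
            if b in anchored:
                continue
            for r in by_basin[b]:
                for b2 in anchored:
                    for r2 in by_basin[b2]:
                        d = float(np.linalg.norm(r.states[0] - r2.states[0]))
                        if best is None or d < best[0]:
                            off = (shifted[id(r2)][0] + offsets[b2]) - shifted[id(r)][0]
                            best = (d, b, off)
        assert best is not None
        _, b, off = best
        offsets[b] = off
        anchored.add(b)

    out = [shifted[id(r)] + offsets[r.basin] for r in runs]
    return out, offsets


def build_surface(
    p: ToggleParams,
    seed_grid_n: int = 10,
    grid_out: int | tuple[int, int] = 60,
    t_max: float = 60.0,
    conv_tol: float = 1e-3,
    sample_dt: float = 0.05,
    portrait: PhasePortrait | None = None,
) -> QuasiPotentialSurface:
    """Full landscape construction for one fixed parameter set.

    ``seed_grid_n``^2 initial conditions are spread over the trapping box;
    each is integrated to convergence, accumulated, truncated at its
    attractor (avoiding unbounded zero-increment tails), normalised, and
    the scattered samples are linearly interpolated on a triangulation
    onto the output grid.
    """
    if portrait is None:
        portrait = compute_portrait(p, with_separatrices=False)
    att = np.array([s.position for s in portrait.attractors])
    if len(att) == 0:
        raise ValueError("portrait has no attractors")
    xmax, ymax = p.trapping_box()
    if isinstance(grid_out, int):
        grid_out = (grid_out, grid_out)

    n_samples = int(np.ceil(t_max / sample_dt))
    runs: list[_SeedRun] = []
    for x0 in np.linspace(0.0, xmax, seed_grid_n):
        for y0 in np.linspace(0.0, ymax, seed_grid_n):
            times, states = integrate_autonomous(p, (x0, y0), t_max, n_samples)
            times, states, basin = _truncate_at_convergence(times, states, att, conv_tol)
            if basin is None:
                log.debug("seed (%.2f, %.2f) did not converge; skipped", x0, y0)
                continue
            vq = accumulate(times, states, p)
            runs.append(_SeedRun(states=states, vq=vq, basin=basin))
    if not runs:
        raise RuntimeError("no seed trajectory converged")

    values, offsets = normalize(runs, portrait)

    pts = np.vstack([r.states for r in runs])
    vals = np.concatenate(values)
    gx = np.linspace(0.0, xmax, grid_out[0])
    gy = np.linspace(0.0, ymax, grid_out[1])
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    V = griddata(pts, vals, (xx, yy), method="linear")

    lineage_offsets = {}
    att_idx = [i for i, s in enumerate(portrait.steady_states) if s.kind == "attractor"]
    for rank, off in offsets.items():
        key = portrait.steady_states[att_idx[rank]].lineage_id
        lineage_offsets[key if key is not None else att_idx[rank]] = off

    return QuasiPotentialSurface(
        grid_x=gx, grid_y=gy, V=V, basin_offsets=lineage_offsets,
        n_trajectories=len(runs), params=p,
    )
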