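"""Readers and writers for portraits, trajectories, surfaces and event logs.

Tabular results go to CSV, structured records to JSON; everything written
here is re-readable by the matching reader with full value fidelity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .events import MechanismEvent
from .integrate import Trajectory
from .model import ToggleParams
from .portrait import PhasePortrait, SteadyState
from .quasipotential import QuasiPotentialSurface


# -- phase portraits -------------------------------------------------------

def portrait_to_dict(pp: PhasePortrait) -> dict:
    return {
        "params": pp.params.as_dict(),
        "regime": pp.regime,
        "steady_states": [
            {
                "position": [s.x, s.y],
                "kind": s.kind,
                "eigenvalues": [[float(np.real(e)), float(np.imag(e))]
                                for e in s.eigenvalues],
                "lineage_id": s.lineage_id,
            }
            for s in pp.steady_states
        ],
        "separatrices": [poly.tolist() for poly in pp.separatrices],
    }


def portrait_from_dict(d: dict) -> PhasePortrait:
    states = [
        SteadyState(
            position=np.array(s["position"], dtype=float),
            kind=s["kind"],
            eigenvalues=np.array([complex(re, im) for re, im in s["eigenvalues"]]),
            lineage_id=s.get("lineage_id"),
        )
        for s in d["steady_states"]
    ]
    return PhasePortrait(
        params=ToggleParams.from_dict(d["params"]),
        steady_states=states,
        regime=d["regime"],
        separatrices=[np.array(p, dtype=float) for p in d["separatrices"]],
    )


def write_portrait(pp: PhasePortrait, path) -> None:
    Path(path).write_text(json.dumps(portrait_to_dict(pp), indent=2))


def read_portrait(path) -> PhasePortrait:
    return portrait_from_dict(json.loads(Path(path).read_text()))


def separatrices_to_frame(pp: PhasePortrait) -> pd.DataFrame:
    rows = []
    for i, poly in enumerate(pp.separatrices):
        for x, y in poly:
            rows.append({"separatrix_id": i, "x": x, "y": y})
    return pd.DataFrame(rows, columns=["separatrix_id", "x", "y"])


# -- trajectories ----------------------------------------------------------

def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    basin = traj.basin_per_sample
    return pd.DataFrame({
        "t": traj.times,
        "x": traj.states[:, 0],
        "y": traj.states[:, 1],
        "basin_id": [(-1 if b is None else b) for b in basin],
        "portrait_index": traj.window_index.astype(int),
    })


def write_trajectory(traj: Trajectory, csv_path, sidecar_path=None) -> None:
    """CSV of samples plus a JSON sidecar with per-window parameters (and
    the schedule, if the trajectory carries one)."""
    trajectory_to_frame(traj).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        sidecar = {
            "window_params": [p.as_dict() for p in traj.window_params],
            "window_basin": [(-1 if b is None else b) for b in traj.window_basin],
            "schedule": traj.schedule.to_dict() if traj.schedule else None,
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_trajectory(csv_path, sidecar_path) -> Trajectory:
    df = pd.read_csv(csv_path)
    sidecar = json.loads(Path(sidecar_path).read_text())
    from .schedule import ParamSchedule

    return Trajectory(
        times=df["t"].to_numpy(),
        states=df[["x", "y"]].to_numpy(),
        window_index=df["portrait_index"].to_numpy(),
        window_basin=[None if b == -1 else int(b)
                      for b in sidecar["window_basin"]],
        window_params=[ToggleParams.from_dict(p)
                       for p in sidecar["window_params"]],
        schedule=(ParamSchedule.from_dict(sidecar["schedule"])
                  if sidecar.get("schedule") else None),
    )


# -- quasi-potential surfaces ---------------------------------------------

def write_surface(surf: QuasiPotentialSurface, csv_path, header_path) -> None:
    """Long-format (x, y, V) CSV — absent cells omitted — plus a JSON
    header with the grid spec and basin offsets."""
    xx, yy = np.meshgrid(surf.grid_x, surf.grid_y, indexing="ij")
    df = pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(), "V": surf.V.ravel()})
    df.dropna().to_csv(csv_path, index=False)
    header = {
        "grid_x": surf.grid_x.tolist(),
        "grid_y": surf.grid_y.tolist(),
        "basin_offsets": {str(k): float(v) for k, v in surf.basin_offsets.items()},
        "n_trajectories": surf.n_trajectories,
        "params": surf.params.as_dict(),
    }
    Path(header_path).write_text(json.dumps(header, indent=2))


def read_surface(csv_path, header_path) -> QuasiPotentialSurface:
    header = json.loads(Path(header_path).read_text())
    gx = np.array(header["grid_x"])
    gy = np.array(header["grid_y"])
    V = np.full((len(gx), len(gy)), np.nan)
    df = pd.read_csv(csv_path)
    # the grids are uniform; recover indices robustly to CSV float round-trip
    ix = np.round((df["x"].to_numpy() - gx[0]) / (gx[1] - gx[0])).astype(int)
    iy = np.round((df["y"].to_numpy() - gy[0]) / (gy[1] - gy[0])).astype(int)
    V[ix, iy] = df["V"].to_numpy()
    return QuasiPotentialSurface(
        grid_x=gx, grid_y=gy, V=V,
        basin_offsets={int(k): v for k, v in header["basin_offsets"].items()},
        n_trajectories=header["n_trajectories"],
        params=ToggleParams.from_dict(header["params"]),
    )


# -- event logs ------------------------------------------------------------

def events_to_records(events: list[MechanismEvent], notes: list[str]) -> dict:
    return {
        "events": [
            {
                "kind": e.kind,
                "t_start": e.t_start,
                "t_end": e.t_end,
                "basin_before": e.basin_before,
                "basin_after": e.basin_after,
                "delay": e.delay,
                "sub_label": e.sub_label,
                "bifurcation": (
                    {"kind": e.bifurcation.kind, "time": e.bifurcation.time,
                     "location": e.bifurcation.location.tolist()}
                    if e.bifurcation is not None else None
                ),
                "note": e.note,
            }
            for e in events
        ],
        "notes": notes,
    }


def write_events(events: list[MechanismEvent], notes: list[str], path) -> None:
    Path(path).write_text(json.dumps(events_to_records(events, notes), indent=2))


def read_events(path) -> dict:
    return json.loads(Path(path).read_text())
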