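"""Steady-state lineages across a portrait sequence, and the four-way
classification of trajectory-shaping mechanisms.

A non-autonomous run yields one frozen phase portrait per parameter window.
Lineage tracking gives each steady state a persistent identity across
windows so that "the same attractor" is meaningful over time; births and
deaths are reconciled with detected bifurcations.  The classifier then
reads the trajectory's per-window basin labels and the lineage table to
name the mechanism shaping each qualitative change:

* transition — the trajectory's attractor is annihilated by a bifurcation
  and the trajectory converges to a surviving attractor, after a delay;
* pursuit — the trajectory chases a moving attractor inside one basin,
  either keeping (stabilising) or reversing its direction;
* capture, topological — a separatrix created by an earlier bifurcation in
  the run sweeps over the trajectory, recruiting it into the new basin;
* capture, geometric — a pre-existing separatrix moves (basin geometry
  only, no bifurcation) and overtakes the trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .integrate import RunResult, Trajectory
from .portrait import (BifurcationEvent, PhasePortrait, SteadyState,
                       _mutual_nearest_matches, detect_bifurcations)

log = logging.getLogger(__name__)


@dataclass
class LineageRecord:
    lineage_id: int
    kind: str
    first_step: int
    last_step: int
    positions: dict[int, np.ndarray] = field(default_factory=dict)
    birth_event: BifurcationEvent | None = None
    death_event: BifurcationEvent | None = None

    def alive_at(self, k: int) -> bool:
        return self.first_step <= k <= self.last_step


@dataclass
class LineageTable:
    """Persistent identities of steady states across a portrait sequence."""

    records: dict[int, LineageRecord]
    step_map: list[dict[int, int]]  # per step: state index -> lineage id
    bifurcations: list[BifurcationEvent]
    times: list[float]

    @property
    def n_steps(self) -> int:
        return len(self.step_map)

    def lineage_of(self, step: int, state_index: int) -> int | None:
        return self.step_map[step].get(state_index)

    def position(self, lineage_id: int, step: int) -> np.ndarray | None:
        return self.records[lineage_id].positions.get(step)


def track_lineages(
    portraits: list[PhasePortrait],
    match_radius: float = 0.05,
    times: list[float] | None = None,
) -> LineageTable:
    """Greedy mutual-nearest (kind-aware) matching of steady states across
    consecutive portraits.

    Unmatched states become births/deaths; each is linked to a co-located
    bifurcation event of that step when one exists.  Also stamps lineage
    ids onto the ``SteadyState`` records of the portraits.
    """
    if times is None:
        times = list(range(len(portraits)))
    records: dict[int, LineageRecord] = {}
    step_map: list[dict[int, int]] = []
    bifs: list[BifurcationEvent] = []
    next_id = 0

    first = {}
    for i, s in enumerate(portraits[0].steady_states):
        rec = LineageRecord(lineage_id=next_id, kind=s.kind, first_step=0, last_step=0)
        rec.positions[0] = s.position
        records[next_id] = rec
        s.lineage_id = next_id
        first[i] = next_id
        next_id += 1
    step_map.append(first)

    for k in range(1, len(portraits)):
        prev, curr = portraits[k - 1], portraits[k]
        pairs = _mutual_nearest_matches(prev.steady_states, curr.steady_states,
                                        match_radius)
        step_events = detect_bifurcations(prev, curr, t=times[k],
                                          match_radius=match_radius)
        bifs.extend(step_events)
        # states detect_bifurcations attributed to an event are genuine
        # births/deaths; leftover unmatched same-kind pairs are fast-moving
        # continuations (e.g. near a fold) and keep their lineage
        event_died = {id(s) for ev in step_events for s in ev.died}
        event_born = {id(s) for ev in step_events for s in ev.born}
        # a pitchfork upgrade may claim a matched pair as death + birth
        pairs = [(i, j) for i, j in pairs
                 if id(prev.steady_states[i]) not in event_died
                 and id(curr.steady_states[j]) not in event_born]
        left_prev = [i for i, s in enumerate(prev.steady_states)
                     if i not in {a for a, _ in pairs}
                     and id(s) not in event_died]
        left_curr = [j for j, s in enumerate(curr.steady_states)
                     if j not in {b for _, b in pairs}
                     and id(s) not in event_born]
        cont = []
        for i in left_prev:
            for j in left_curr:
                si, sj = prev.steady_states[i], curr.steady_states[j]
                if si.kind != sj.kind:
                    continue
                d = float(np.linalg.norm(si.position - sj.position))
                if d <= 10.0 * match_radius:
                    cont.append((d, i, j))
        used_i, used_j = set(), set()
        for d, i, j in sorted(cont):
            if i in used_i or j in used_j:
                continue
            pairs.append((i, j))
            used_i.add(i)
            used_j.add(j)
        curr_map: dict[int, int] = {}
        matched_curr = set()
        for i, j in pairs:
            lid = step_map[k - 1].get(i)
            if lid is None:
                continue
            rec = records[lid]
            rec.last_step = k
            rec.positions[k] = curr.steady_states[j].position
            curr.steady_states[j].lineage_id = lid
            curr_map[j] = lid
            matched_curr.add(j)

        def nearest_event(pos):
            best, best_d = None, np.inf
            for ev in step_events:
                d = float(np.linalg.norm(ev.location - pos))
                if d < best_d:
                    best, best_d = ev, d
            return best if best is not None and best_d <= 10 * match_radius else None

        # deaths
        matched_prev = {i for i, _ in pairs}
        for i, s in enumerate(prev.steady_states):
            if i in matched_prev:
                continue
            lid = step_map[k - 1].get(i)
            if lid is not None:
                ev = nearest_event(s.position)
                records[lid].death_event = ev
                if ev is not None and lid not in ev.involved_lineages:
                    ev.involved_lineages.append(lid)
        # births
        for j, s in enumerate(curr.steady_states):
            if j in matched_curr:
                continue
            ev = nearest_event(s.position)
            rec = LineageRecord(lineage_id=next_id, kind=s.kind,
                                first_step=k, last_step=k, birth_event=ev)
            rec.positions[k] = s.position
            records[next_id] = rec
            s.lineage_id = next_id
            curr_map[j] = next_id
            if ev is not None:
                ev.involved_lineages.append(next_id)
            next_id += 1
        step_map.append(curr_map)

    return LineageTable(records=records, step_map=step_map,
                        bifurcations=bifs, times=list(times))


def relabel_basins(traj: Trajectory, lineage: LineageTable) -> list[int | None]:
    """Translate per-window portrait-local attractor indices into persistent
    lineage ids."""
    out: list[int | None] = []
    for k, b in enumerate(traj.window_basin):
        out.append(None if b is None else lineage.lineage_of(k, b))
    return out


@dataclass
class MechanismEvent:
    kind: str  # transition | pursuit | capture_topological | capture_geometric
    t_start: float
    t_end: float
    basin_before: int | None = None
    basin_after: int | None = None
    bifurcation: BifurcationEvent | None = None
    delay: float | None = None
    sub_label: str | None = None  # pursuit only: stabilising | reversing
    note: str = ""


def classify(
    run: RunResult,
    lineage: LineageTable | None = None,
    eps_move: float = 1e-4,
    eps_conv: float = 1e-2,
    min_steps: int = 3,
    match_radius: float = 0.05,
) -> tuple[list[MechanismEvent], list[str]]:
    """Classify every qualitative event of a run.

    Returns the event list plus notes for steps that could not be resolved
    (a basin-change step is never silently dropped).  Basin-change rules,
    evaluated per window k against the previous resolved window:

    1. the old basin's attractor died at or before k  -> transition;
    2. old attractor alive, gaining attractor born by a bifurcation earlier
       in the run                                     -> capture_topological;
    3. old attractor alive, gaining attractor existed from the start
                                                      -> capture_geometric.

    The delay of a transition or topological capture is measured from the
    bifurcation that created the gaining attractor's lineage (the event the
    basin change is causally downstream of); if the gaining lineage has no
    in-run birth, the old attractor's death time is used.

    Within a basin, a pursuit episode is flagged while the basin's
    attractor moves more than ``eps_move`` per window and the state stays
    further than ``eps_conv`` from it, sustained for at least ``min_steps``
    windows; the episode is ``stabilising`` if every velocity component
    keeps its sign and ``reversing`` if one flips.
    """
    traj = run.trajectory
    sch = run.schedule
    if lineage is None:
        lineage = track_lineages(run.portraits, match_radius=match_radius,
                                 times=[sch.window_bounds(k)[0]
                                        for k in range(sch.n_windows)])
    basins = relabel_basins(traj, lineage)
    n = len(basins)
    times = [sch.window_bounds(k)[0] for k in range(n)]

    events: list[MechanismEvent] = []
    notes: list[str] = []

    # ---- basin-change events -------------------------------------------
    last_resolved: tuple[int, int] | None = None  # (step, basin lineage)
    for k in range(n):
        b = basins[k]
        if b is None:
            notes.append(f"window {k} (t={times[k]:g}): basin unresolved, skipped")
            continue
        if last_resolved is not None and b != last_resolved[1]:
            k_prev, b_prev = last_resolved
            old_rec = lineage.records.get(b_prev)
            new_rec = lineage.records.get(b)
            old_dead = old_rec is not None and old_rec.last_step < k
            t_change = times[k]
            if old_dead:
                kind = "transition"
                causal = (new_rec.birth_event if new_rec is not None and
                          new_rec.birth_event is not None else old_rec.death_event)
            elif new_rec is not None and new_rec.first_step > 0:
                kind = "capture_topological"
                causal = new_rec.birth_event
            else:
                kind = "capture_geometric"
                causal = None
            delay = None
            if kind in ("transition", "capture_topological"):
                if causal is not None:
                    delay = t_change - causal.time
                elif old_rec is not None and old_rec.death_event is not None:
                    delay = t_change - old_rec.death_event.time
            events.append(MechanismEvent(
                kind=kind, t_start=times[k_prev], t_end=t_change,
                basin_before=b_prev, basin_after=b,
                bifurcation=causal, delay=delay,
            ))
        last_resolved = (k, b)

    # ---- pursuit episodes ----------------------------------------------
    change_steps = set()
    for ev in events:
        change_steps.add(ev.t_end)
    flags = np.zeros(n, dtype=bool)
    for k in range(1, n):
        b, b_prev = basins[k], basins[k - 1]
        if b is None or b != b_prev:
            continue
        pos_k = lineage.position(b, k)
        pos_km1 = lineage.position(b, k - 1)
        if pos_k is None or pos_km1 is None:
            continue
        if np.linalg.norm(pos_k - pos_km1) <= eps_move:
            continue
        idx = np.where(traj.window_index == k)[0]
        state_k = traj.states[idx[0]]
        if np.linalg.norm(state_k - pos_k) <= eps_conv:
            continue
        flags[k] = True

    k = 1
    while k < n:
        if not flags[k]:
            k += 1
            continue
        k0 = k
        while k < n and flags[k]:
            k += 1
        if k - k0 >= min_steps:
            idx = np.where((traj.window_index >= k0 - 1) & (traj.window_index < k))[0]
            seg = traj.states[idx]
            disp = np.diff(seg, axis=0)
            sub = "stabilising"
            for comp in range(2):
                moves = disp[np.abs(disp[:, comp]) > 1e-7, comp]
                if moves.size and np.min(moves) < 0 < np.max(moves):
                    sub = "reversing"
            events.append(MechanismEvent(
                kind="pursuit", t_start=times[k0], t_end=times[k - 1],
                basin_before=basins[k0], basin_after=basins[k0],
                sub_label=sub,
            ))

    events.sort(key=lambda e: (e.t_end, e.t_start))
    return events, notes
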