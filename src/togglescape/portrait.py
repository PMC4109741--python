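"""Phase portraits of the autonomous toggle switch at one parameter set.

Steady states are found by multi-start Newton-type root finding over the
trapping box, classified by the eigenvalues of the analytic Jacobian, and
labelled with the dynamical regime (monostable / bistable / tristable).
Separatrices are traced as the stable manifolds of saddles by reverse-time
integration; basins of attraction are resolved by forward integration.
Consecutive portraits of a parameter sweep are compared to detect and
classify bifurcations (supracritical/subcritical pitchfork, saddle-node).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import ToggleParams, jacobian, vector_field

log = logging.getLogger(__name__)

#: |Re(eigenvalue)| below this flags the portrait as near-bifurcation.
STABILITY_EPS = 1e-8


@dataclass
class SteadyState:
    """A root of the vector field with its linear stability."""

    position: np.ndarray
    kind: str  # "attractor" | "saddle" | "repeller" | "marginal"
    eigenvalues: np.ndarray
    lineage_id: int | None = None

    @property
    def x(self) -> float:
        return float(self.position[0])

    @property
    def y(self) -> float:
        return float(self.position[1])


@dataclass
class PhasePortrait:
    params: ToggleParams
    steady_states: list[SteadyState]
    regime: str = "other"
    separatrices: list[np.ndarray] = field(default_factory=list)

    @property
    def attractors(self) -> list[SteadyState]:
        return [s for s in self.steady_states if s.kind == "attractor"]

    @property
    def saddles(self) -> list[SteadyState]:
        return [s for s in self.steady_states if s.kind == "saddle"]

    @property
    def near_bifurcation(self) -> bool:
        return any(s.kind == "marginal" for s in self.steady_states)


@dataclass
class BifurcationEvent:
    """A topological change between two consecutive portraits."""

    kind: str  # supracritical_pitchfork | subcritical_pitchfork | saddle_node | unclassified
    time: float
    location: np.ndarray
    died: list[SteadyState] = field(default_factory=list)
    born: list[SteadyState] = field(default_factory=list)
    involved_lineages: list[int] = field(default_factory=list)
    note: str = ""


def _classify_kind(eigvals: np.ndarray) -> str:
    re = np.real(eigvals)
    if np.any(np.abs(re) <= STABILITY_EPS):
        return "marginal"
    if np.all(re < 0):
        return "attractor"
    if np.all(re > 0):
        return "repeller"
    return "saddle"


def find_steady_states(
    p: ToggleParams,
    grid_n: int = 7,
    tol: float = 1e-9,
    merge_radius: float = 1e-3,
) -> list[SteadyState]:
    """All steady states in the trapping box, stability-classified.

    Root finding is started from a regular ``grid_n`` x ``grid_n`` grid over
    the trapping box; converged roots are de-duplicated by ``merge_radius``
    and kept only if the residual is below ``tol``.  The model has at most
    five roots, all inside the trapping box, and always at least one.
    """
    if grid_n * grid_n < 25:
        raise ValueError("need at least a 5x5 start grid (25 starts)")
    xmax, ymax = p.trapping_box()
    xs = np.linspace(0.0, xmax, grid_n)
    ys = np.linspace(0.0, ymax, grid_n)
    roots: list[np.ndarray] = []
    fun = lambda s: vector_field(s, p)
    jac = lambda s: jacobian(s, p)
    for x0 in xs:
        for y0 in ys:
            sol = root(fun, np.array([x0, y0]), jac=jac, method="hybr", tol=1e-12)
            if not sol.success:
                log.debug("root start (%.3f, %.3f) did not converge", x0, y0)
                continue
            r = sol.x
            # clip the tiny negative undershoots Newton can produce on the axes
            r = np.where((r < 0) & (r > -1e-9), 0.0, r)
            if np.any(r < 0) or r[0] > xmax * 1.05 + 0.1 or r[1] > ymax * 1.05 + 0.1:
                continue
            if np.max(np.abs(vector_field(r, p))) >= tol:
                continue
            if any(np.linalg.norm(r - q) < merge_radius for q in roots):
                continue
            roots.append(r)
    if not roots:
        raise RuntimeError("no steady states found; the model guarantees at least one")
    states = []
    for r in sorted(roots, key=lambda q: (q[0], q[1])):
        ev = np.linalg.eigvals(jacobian(r, p))
        states.append(SteadyState(position=r, kind=_classify_kind(ev), eigenvalues=ev))
    return states


def label_regime(n_attractors: int, n_saddles: int) -> str:
    """Regime from the attractor/saddle census: (1,0), (2,1), (3,2) map to
    monostable, bistable, tristable; anything else is 'other'."""
    return {
        (1, 0): "monostable",
        (2, 1): "bistable",
        (3, 2): "tristable",
    }.get((n_attractors, n_saddles), "other")


def compute_separatrix(
    saddle: SteadyState,
    p: ToggleParams,
    horizon: float = 200.0,
    eps: float = 1e-6,
    n_points: int = 200,
) -> np.ndarray:
    """Stable manifold of ``saddle``, traced as a polyline through it.

    The stable manifold is the basin boundary through the saddle.  It is
    traced by integrating the time-reversed field from the saddle perturbed
    by +/- eps along the stable eigenvector (under time reversal the stable
    direction becomes repelling, so the reversed flow walks outward along
    the manifold) until the trajectory leaves the trapping box or the time
    horizon is exhausted.
    """
    if saddle.kind != "saddle":
        raise ValueError(f"separatrix requires a saddle, got {saddle.kind!r}")
    ev, vecs = np.linalg.eig(jacobian(saddle.position, p))
    stable = np.where(np.real(ev) < 0)[0]
    if len(stable) != 1 or np.abs(np.imag(ev[stable[0]])) > 1e-10:
        raise ValueError("non-generic saddle: no unique real stable eigenvector")
    v = np.real(vecs[:, stable[0]])
    v = v / np.linalg.norm(v)

    xmax, ymax = p.trapping_box()
    x_hi, y_hi = 1.2 * xmax + 0.2, 1.2 * ymax + 0.2

    def rev_field(t, s):
        return -vector_field(s, p)

    def leave_box(t, s):
        return min(s[0] + 0.05, s[1] + 0.05, x_hi - s[0], y_hi - s[1])

    leave_box.terminal = True
    leave_box.direction = -1

    branches = []
    for sign in (+1.0, -1.0):
        s0 = saddle.position + sign * eps * v
        sol = solve_ivp(
            rev_field, (0.0, horizon), s0, events=leave_box,
            rtol=1e-8, atol=1e-10, dense_output=True, max_step=horizon / 50,
        )
        t_end = sol.t[-1]
        ts = np.linspace(0.0, t_end, n_points)
        branches.append(sol.sol(ts).T)
    # concatenate: reversed first branch, saddle, second branch
    poly = np.vstack([branches[0][::-1], saddle.position[None, :], branches[1]])
    return poly


def compute_portrait(
    p: ToggleParams,
    grid_n: int = 7,
    tol: float = 1e-9,
    merge_radius: float = 1e-3,
    with_separatrices: bool = True,
) -> PhasePortrait:
    """Full portrait: steady states, regime label, separatrices."""
    states = find_steady_states(p, grid_n=grid_n, tol=tol, merge_radius=merge_radius)
    pp = PhasePortrait(params=p, steady_states=states)
    pp.regime = label_regime(len(pp.attractors), len(pp.saddles))
    if with_separatrices:
        for s in pp.saddles:
            try:
                pp.separatrices.append(compute_separatrix(s, p))
            except ValueError as exc:
                log.warning("separatrix skipped: %s", exc)
    return pp


def _polyline_distance(s: np.ndarray, poly: np.ndarray) -> float:
    """Distance from a point to a polyline (min over segments)."""
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", s[None, :] - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - s[None, :], axis=1)))


def assign_basin(
    s,
    pp: PhasePortrait,
    t_max: float = 400.0,
    conv_tol: float = 1e-3,
) -> int | None:
    """Index (into ``pp.steady_states``) of the attractor whose basin holds
    ``s``, or ``None`` if unresolved.

    Resolution is by forward autonomous integration until the state comes
    within ``conv_tol`` of an attractor.  Points within ``conv_tol`` of a
    separatrix are reported unresolved rather than forced to a side: the
    basin boundary is a measure-zero set on which the label is not defined.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("state must lie in the non-negative quadrant")
    att_idx = [i for i, st in enumerate(pp.steady_states) if st.kind == "attractor"]
    if not att_idx:
        return None
    positions = np.array([pp.steady_states[i].position for i in att_idx])

    d0 = np.linalg.norm(positions - s[None, :], axis=1)
    if np.min(d0) < conv_tol:
        return att_idx[int(np.argmin(d0))]
    for poly in pp.separatrices:
        if _polyline_distance(s, poly) < conv_tol:
            return None

    p = pp.params

    def fld(t, st):
        return vector_field(st, p)

    t, state = 0.0, s
    chunk = 10.0
    while t < t_max:
        sol = solve_ivp(fld, (0.0, chunk), state, rtol=1e-8, atol=1e-10,
                        dense_output=True)
        ts = np.linspace(0.0, sol.t[-1], 30)
        pts = sol.sol(ts).T
        d = np.linalg.norm(pts[:, None, :] - positions[None, :, :], axis=2)
        hit = np.argwhere(d < conv_tol)
        if hit.size:
            return att_idx[int(hit[0, 1])]
        state = sol.y[:, -1]
        t += chunk
    return None


# ---------------------------------------------------------------------------
# bifurcation detection between consecutive portraits
# ---------------------------------------------------------------------------

def _mutual_nearest_matches(
    prev_states: list[SteadyState],
    curr_states: list[SteadyState],
    match_radius: float,
) -> list[tuple[int, int]]:
    """Kind-aware greedy mutual-nearest matching within ``match_radius``.

    Equidistant candidates (within 1e-9) are tie-broken by lexicographic
    position, which keeps the matching deterministic.
    """
    pairs: list[tuple[int, int]] = []
    used_prev: set[int] = set()
    used_curr: set[int] = set()
    cands = []
    for i, sp in enumerate(prev_states):
        for j, sc in enumerate(curr_states):
            if sp.kind != sc.kind:
                continue
            d = float(np.linalg.norm(sp.position - sc.position))
            if d <= match_radius:
                cands.append((d, tuple(sp.position), tuple(sc.position), i, j))
    for d, _, _, i, j in sorted(cands):
        if i in used_prev or j in used_curr:
            continue
        pairs.append((i, j))
        used_prev.add(i)
        used_curr.add(j)
    return pairs


def _group_by_proximity(items: list[tuple[str, SteadyState]], radius: float):
    """Single-linkage grouping of (role, state) items by position."""
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(items[i][1].position - items[j][1].position) <= radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[str, SteadyState]]] = {}
    for i, it in enumerate(items):
        groups.setdefault(find(i), []).append(it)
    return list(groups.values())


def _census(states: list[SteadyState]) -> tuple[int, int]:
    kinds = [s.kind for s in states]
    return kinds.count("attractor"), kinds.count("saddle")


def _template_kind(died: list[SteadyState], born: list[SteadyState]) -> str | None:
    cd, cb = _census(died), _census(born)
    if cd == (1, 0) and cb == (2, 1):
        return "supracritical_pitchfork"
    if cd == (2, 1) and cb == (1, 0):
        return "supracritical_pitchfork"  # reverse direction of the same fold of branches
    if cd == (0, 1) and cb == (1, 2):
        return "subcritical_pitchfork"
    if cd == (1, 2) and cb == (0, 1):
        return "subcritical_pitchfork"
    if cd == (1, 1) and cb == (0, 0):
        return "saddle_node"
    if cd == (0, 0) and cb == (1, 1):
        return "saddle_node"
    return None


def detect_bifurcations(
    prev: PhasePortrait,
    curr: PhasePortrait,
    t: float,
    match_radius: float = 0.05,
) -> list[BifurcationEvent]:
    """Classify the topological change (if any) between two consecutive
    portraits of a sweep.

    Steady states are matched kind-aware by mutual nearest neighbour within
    ``match_radius``; unmatched deaths/births are grouped by proximity
    (within 10x the radius) and each group is classified against the three
    templates of this model: an attractor replaced by two attractors and a
    saddle (supracritical pitchfork), a saddle replaced by an attractor and
    two saddles (subcritical pitchfork), and a co-located attractor-saddle
    pair annihilating or appearing (saddle-node).  A group fitting no
    template is first reduced by pairing same-kind deaths with births (a
    fast-moving state, not a topological event); anything still unexplained
    is reported as ``unclassified`` rather than dropped.

    Close to a pitchfork the offspring separate like the square root of the
    parameter distance, so the converting state can spuriously match one
    offspring and shrink the group to a saddle-node signature.  A group that
    classifies as a saddle-node is therefore re-examined: if pulling an
    adjacent fast-moving matched pair into the group upgrades it to a
    pitchfork template, the pitchfork wins and that pair counts as a
    death + birth rather than a continuation.
    """
    pairs = _mutual_nearest_matches(prev.steady_states, curr.steady_states, match_radius)
    matched_prev = {i for i, _ in pairs}
    matched_curr = {j for _, j in pairs}
    died = [("died", s) for i, s in enumerate(prev.steady_states) if i not in matched_prev]
    born = [("born", s) for j, s in enumerate(curr.steady_states) if j not in matched_curr]
    if not died and not born:
        return []

    events: list[BifurcationEvent] = []
    for group in _group_by_proximity(died + born, 10.0 * match_radius):
        g_died = [s for role, s in group if role == "died"]
        g_born = [s for role, s in group if role == "born"]
        kind = _template_kind(g_died, g_born)
        note = ""
        if kind is None:
            # reduce same-kind death/birth pairs (continuation of a state
            # that moved further than match_radius in one window)
            for k in ("attractor", "saddle", "repeller", "marginal"):
                while True:
                    di = [s for s in g_died if s.kind == k]
                    bi = [s for s in g_born if s.kind == k]
                    if not di or not bi:
                        break
                    d0, b0 = min(
                        ((x, y) for x in di for y in bi),
                        key=lambda xy: np.linalg.norm(xy[0].position - xy[1].position),
                    )
                    g_died = [s for s in g_died if s is not d0]
                    g_born = [s for s in g_born if s is not b0]
            if not g_died and not g_born:
                continue  # pure continuation, no topological event
            kind = _template_kind(g_died, g_born)
            if kind is None:
                kind = "unclassified"
                note = (
                    f"census change died={_census(g_died)} born={_census(g_born)} "
                    "fits no pitchfork/saddle-node template"
                )
        if kind == "saddle_node":
            upgraded = _try_pitchfork_upgrade(
                g_died, g_born, pairs, prev, curr, match_radius)
            if upgraded is not None:
                kind, g_died, g_born = upgraded
        loc = np.mean([s.position for s in g_died + g_born], axis=0)
        events.append(BifurcationEvent(kind=kind, time=t, location=loc,
                                       died=g_died, born=g_born, note=note))
    return sorted(events, key=lambda e: (e.location[0], e.location[1]))


def _try_pitchfork_upgrade(g_died, g_born, pairs, prev, curr, match_radius):
    """If a matched pair moved fast and sits inside the group, adding it as
    a death + birth may reveal a pitchfork hidden by a spurious match."""
    centroid = np.mean([s.position for s in g_died + g_born], axis=0)
    for i, j in pairs:
        sp, sc = prev.steady_states[i], curr.steady_states[j]
        moved = float(np.linalg.norm(sp.position - sc.position))
        near = min(
            float(np.linalg.norm(sp.position - centroid)),
            float(np.linalg.norm(sc.position - centroid)),
        )
        if moved <= 0.5 * match_radius or near > 10.0 * match_radius:
            continue
        kind = _template_kind(g_died + [sp], g_born + [sc])
        if kind in ("supracritical_pitchfork", "subcritical_pitchfork"):
            return kind, g_died + [sp], g_born + [sc]
    return None
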