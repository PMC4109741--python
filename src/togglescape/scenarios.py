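"""Canonical parameter sets and schedules for the five reference runs.

The toggle-switch model does not dictate parameter values; the baseline
used here was discovered once by regime scanning (the discovery script is
kept at scripts/discover_scenarios.py) and is frozen so that every
scenario is fully deterministic.  The symmetric baseline sits in the
bistable regime.  Raising the auto-activation thresholds a = c walks the
portrait through a subcritical pitchfork (the diagonal saddle converts in
place into the central attractor plus two flanking saddles, near
a = c ~ 0.643) into tristability, and then through two simultaneous
saddle-node bifurcations (near a = c ~ 0.749) into monostability.
Ramping both external activations keeps the portrait bistable while the
attractors move; ramping one repression threshold (b only) breaks the
symmetry and sweeps the separatrix without any bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ToggleParams
from .portrait import compute_portrait, find_steady_states, label_regime
from .schedule import ParamSchedule, Ramp

#: Symmetric bistable baseline: moderate external activation, permissive
#: auto-activation threshold, unit decay.  Attractors at ~(1.15, 0.32) and
#: ~(0.32, 1.15); diagonal saddle at ~(0.60, 0.60).
BASELINE = ToggleParams(alpha_x=0.3, alpha_y=0.3, a=0.3, b=0.5, c=0.3, d=0.5,
                        lambda_x=1.0, lambda_y=1.0)

#: a = c value of the subcritical pitchfork (bistable -> tristable) and of
#: the two simultaneous saddle-nodes (tristable -> monostable) at BASELINE,
#: from regime_scan bisection.
A_C_PITCHFORK = 0.6426
A_C_SADDLE_NODE = 0.7490

SCENARIO_NAMES = (
    "transition",
    "pursuit_up",
    "pursuit_down",
    "capture_topological",
    "capture_geometric",
)


@dataclass(frozen=True)
class Scenario:
    """A schedule + initial condition with its expected event signature.

    ``expected`` maps basin-change kinds to exact counts; ``min_pursuits``
    and ``expected_pursuit_sublabel`` constrain pursuit episodes where the
    scenario is about them.
    """

    name: str
    schedule: ParamSchedule
    s0: tuple[float, float]
    expected: dict[str, int] = field(default_factory=dict)
    min_pursuits: int = 0
    expected_pursuit_sublabel: str | None = None
    expects_self_crossing: bool = False
    description: str = ""


def regime_scan(
    baseline: ToggleParams,
    param: str,
    lo: float,
    hi: float,
    n: int = 25,
    refine_boundaries: bool = True,
    rel_width: float = 1e-4,
):
    """Regime label at ``n`` evenly spaced values of one parameter (or a
    coupled alias such as ``a_c`` / ``alpha``), with regime boundaries
    refined by bisection to the requested relative width.

    Returns ``(points, boundaries)``: points is a list of (value, regime),
    boundaries a list of (value, regime_below, regime_above).  Finding no
    regime change is a valid result, not an error.
    """
    from .schedule import _COUPLED

    if lo >= hi:
        raise ValueError("need lo < hi")
    targets = _COUPLED.get(param, (param,))

    def regime_at(v: float) -> str:
        ss = find_steady_states(baseline.replace(**{t: v for t in targets}))
        n_att = sum(1 for s in ss if s.kind == "attractor")
        n_sad = sum(1 for s in ss if s.kind == "saddle")
        return label_regime(n_att, n_sad)

    values = np.linspace(lo, hi, n)
    points = [(float(v), regime_at(float(v))) for v in values]

    boundaries = []
    if refine_boundaries and n > 1:
        for (v0, r0), (v1, r1) in zip(points, points[1:]):
            if r0 == r1:
                continue
            a_, b_ = v0, v1
            while (b_ - a_) / max(abs(b_), 1e-12) > rel_width:
                m = 0.5 * (a_ + b_)
                if regime_at(m) == r0:
                    a_ = m
                else:
                    b_ = m
            boundaries.append((0.5 * (a_ + b_), r0, r1))
    return points, boundaries


def _high_x_attractor(p: ToggleParams) -> tuple[float, float]:
    pp = compute_portrait(p, with_separatrices=False)
    s = max(pp.attractors, key=lambda st: st.x).position
    return float(s[0]), float(s[1])


def make_scenario(name: str) -> Scenario:
    """One of the five canonical non-autonomous runs.

    * ``transition`` — slow symmetric a = c up-ramp through the pitchfork
      and the double saddle-node, started exactly at the high-x attractor.
      The trajectory tracks its moving attractor until the saddle-node
      annihilates it, then switches basin with a delay relative to the
      pitchfork that created the central attractor.
    * ``pursuit_up`` — both external activations ramped up over a range
      where the attractor moves monotonically away from the origin; the
      trajectory chases it without changing direction (stabilising).
    * ``pursuit_down`` — activations ramped down; the attractor moves
      against the incoming trajectory, which reverses direction
      (reversing).  Both pursuit runs stay bistable and never change basin.
    * ``capture_topological`` — the same a = c up-ramp family but fast and
      started away from the attractor near the saddle: the basin born at
      the pitchfork expands over the still-transient trajectory before the
      saddle-node, recruiting it (a capture caused by a preceding
      bifurcation).
    * ``capture_geometric`` — one repression threshold (b only) ramped up,
      staying inside the bistable regime: the separatrix sweeps towards
      the high-y attractor and overtakes the converging trajectory with no
      bifurcation anywhere in the run, looping the path over itself.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    b = BASELINE
    if name == "transition":
        sch = ParamSchedule(
            baseline=b,
            ramps=(Ramp("a_c", 0.0, 30.0, 0.3, 0.9),),
            dt_step=0.5, t_final=36.0,
        )
        return Scenario(
            name=name, schedule=sch, s0=_high_x_attractor(b),
            expected={"transition": 1, "capture_topological": 0,
                      "capture_geometric": 0},
            description="annihilation of the occupied attractor; delayed switch",
        )
    if name == "pursuit_up":
        base = b.replace(alpha_x=0.12, alpha_y=0.12)
        sch = ParamSchedule(
            baseline=base,
            ramps=(Ramp("alpha", 0.0, 5.0, 0.12, 0.24),),
            dt_step=0.25, t_final=6.0,
        )
        return Scenario(
            name=name, schedule=sch, s0=_high_x_attractor(base),
            expected={"transition": 0, "capture_topological": 0,
                      "capture_geometric": 0},
            min_pursuits=1, expected_pursuit_sublabel="stabilising",
            description="attractor moves outward; trajectory chases, same direction",
        )
    if name == "pursuit_down":
        base = b.replace(alpha_x=0.45, alpha_y=0.45)
        sch = ParamSchedule(
            baseline=base,
            ramps=(Ramp("alpha", 0.0, 10.0, 0.45, 0.15),),
            dt_step=0.5, t_final=12.0,
        )
        return Scenario(
            name=name, schedule=sch, s0=(0.70, 0.40),
            expected={"transition": 0, "capture_topological": 0,
                      "capture_geometric": 0},
            min_pursuits=1, expected_pursuit_sublabel="reversing",
            description="attractor moves against the incoming trajectory; "
                        "direction reverses",
        )
    if name == "capture_topological":
        sch = ParamSchedule(
            baseline=b,
            ramps=(Ramp("a_c", 0.0, 3.0, 0.3, 0.9),),
            dt_step=0.1, t_final=4.0,
        )
        return Scenario(
            name=name, schedule=sch, s0=(0.66, 0.50),
            expected={"transition": 0, "capture_topological": 1,
                      "capture_geometric": 0},
            description="basin born at the pitchfork expands over the slow "
                        "trajectory before the saddle-node",
        )
    # capture_geometric
    sch = ParamSchedule(
        baseline=b,
        ramps=(Ramp("b", 0.0, 6.0, 0.5, 0.62),),
        dt_step=0.2, t_final=10.0,
    )
    return Scenario(
        name=name, schedule=sch, s0=(0.70, 0.90),
        expected={"transition": 0, "capture_topological": 0,
                  "capture_geometric": 1},
        expects_self_crossing=True,
        description="asymmetric repression threshold shifts the separatrix "
                    "over the trajectory; no bifurcation anywhere in the run",
    )
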