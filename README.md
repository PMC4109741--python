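# togglescape

Transient dynamics and quasi-potential (Waddington) landscapes of a
**non-autonomous genetic toggle switch**.

Developmental gene-regulatory processes are shaped not only by where a
dynamical system ends up (its attractors) but by how it gets there — and
the underlying regulatory parameters themselves change over time.
`togglescape` is a desk-scale toolkit for studying exactly that, on the
canonical two-gene toggle switch with auto-activation:

```
dx/dt = α_x + [x⁴/(a⁴+x⁴)]·[b⁴/(b⁴+y⁴)] − λ_x·x
dy/dt = α_y + [y⁴/(c⁴+y⁴)]·[d⁴/(d⁴+x⁴)] − λ_y·y
```

`x`, `y` are protein concentrations of two mutually repressing genes with
quartic-Hill auto-activation (thresholds `a`, `c`), mutual repression
(thresholds `b`, `d`), linear external activation (`α_x`, `α_y`) and
linear decay (`λ_x`, `λ_y`).  Depending on parameters the phase portrait
is monostable, bistable or tristable, and the regimes convert into each
other through supracritical/subcritical pitchfork and saddle-node
bifurcations.

The package provides, for time-dependent parameter schedules:

* **Step-wise non-autonomous integration** — parameters follow
  piecewise-linear ramps sampled-and-held per `dt_step` window; the
  autonomous system is integrated per window and the end state carried
  forward, so each window has a frozen phase portrait.
* **Phase portraits** — multi-start root finding, eigenvalue stability
  classification, separatrices traced as saddle stable manifolds, basins
  of attraction, and regime labels; consecutive portraits are compared to
  detect and classify bifurcations.
* **Quasi-potential landscapes** — the toggle switch is not a gradient
  system, so the landscape is built numerically by accumulating
  `ΔV_q = −[(dx/dt)² + (dy/dt)²]Δt` along sampled trajectories (a
  Lyapunov function of the flow), normalising within and between basins,
  and interpolating to a grid.
* **Mechanism classification** — steady states are tracked as lineages
  across the portrait sequence and each qualitative trajectory-shaping
  event is automatically labelled as one of four mechanisms:
  * **transition** — the occupied attractor is annihilated by a
    bifurcation and the trajectory converges to a surviving attractor,
    with a delay;
  * **pursuit** — the trajectory chases a moving attractor inside one
    basin (sub-labelled *stabilising* or *reversing*);
  * **capture (topological)** — a separatrix created by an earlier
    bifurcation sweeps over the trajectory and recruits it;
  * **capture (geometric)** — a pre-existing separatrix moves (basin
    geometry only, no bifurcation) and overtakes the trajectory.

## Worked example

The five canonical scenarios (frozen schedules + initial conditions that
exhibit each mechanism) are packaged.  Running the transition scenario —
a slow symmetric up-ramp of the auto-activation thresholds `a = c` from
0.3 to 0.9, started exactly on the high-`x` attractor:

```sh
$ togglescape scenario --name transition --out out/transition
transition: {"pursuit": 2, "transition": 1} self_crossing=False
```

The event log (`out/transition/events.json`) contains:

```
pursuit/stabilising   ends t=22.0
transition            t=22.5  delay=5.0
pursuit/reversing     ends t=30.0
```

Read: while the ramp moves the occupied attractor, the trajectory chases
it (pursuit).  At `a = c ≈ 0.643` a subcritical pitchfork creates the
central low/low attractor; at `a = c ≈ 0.749` two simultaneous
saddle-nodes annihilate the outer attractors, and the trajectory switches
into the central basin at `t = 22.5` — a delay of 5.0 time units after
the pitchfork that created its new attractor.  The geometric-capture
scenario instead reports `self_crossing=True`: the moving separatrix
recruits the trajectory with no bifurcation anywhere in the run, looping
the path over itself — something an autonomous planar system can never do.

Library use mirrors the CLI:

```python
from togglescape import make_scenario, integrate
from togglescape.events import classify

sc = make_scenario("capture_geometric")
run = integrate(sc.schedule, sc.s0)
events, notes = classify(run)
print([(e.kind, e.sub_label) for e in events])
# [('pursuit', 'reversing'), ('capture_geometric', None), ('pursuit', 'reversing')]
```

Other commands: `togglescape portrait`, `simulate`, `landscape`,
`classify`, `scan` (regime scanning with bisection-refined boundaries).
Schedule configs are small YAML/JSON files; see
`ParamSchedule.from_file`.

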