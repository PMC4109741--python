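# Methods

## Model

The system is the two-gene toggle switch with auto-activation:

```
dx/dt = α_x + [x⁴/(a⁴+x⁴)]·[b⁴/(b⁴+y⁴)] − λ_x·x
dy/dt = α_y + [y⁴/(c⁴+y⁴)]·[d⁴/(d⁴+x⁴)] − λ_y·y
```

All production terms are bounded by `α + 1`, so the box
`[0, (α_x+1)/λ_x] × [0, (α_y+1)/λ_y]` is forward-invariant and traps
every steady state and every long-run trajectory; the package uses this
box for root-finding starts, seed grids and separatrix truncation.  The
Hill exponent 4 is a fixed property of the model (exposed read-only as
`HILL_N`), not a tunable parameter: it sets the sigmoid sharpness that
makes multistability possible at biologically plausible thresholds.

Parameter units: `α` in concentration/time, thresholds in concentration,
`λ` in 1/time.  Time and concentration are in arbitrary (model) units
throughout.

A diagnostic `gradient_condition_residual` evaluates
`max |∂(dx/dt)/∂y − ∂(dy/dt)/∂x|` over a grid.  A vanishing residual
identifies a gradient system, for which a closed-form potential would
exist.  For this model the residual vanishes only in degenerate limits
(e.g. repression thresholds so large that the repression factors pin to
one); in every interesting regime the system is *not* a gradient system,
which is why the landscape must be constructed numerically.

## Non-autonomous scheme

Time dependence is expressed as piecewise-linear ramps per parameter
(coupled aliases `a_c`, `b_d`, `alpha` ramp symmetric pairs together).
The run is approximated step-wise: ramps are sampled at the start of each
`dt_step` window (left-sample convention; any consistent convention
converges as `dt_step → 0`), held constant, the autonomous system is
integrated across the window (adaptive RK45, rtol 1e-8, atol 1e-10 — the
field is smooth and non-stiff at these scales), and the end state seeds
the next window.  Overlapping ramps for one parameter are a configuration
error rather than last-wins, because silent precedence rules hide typos.

There is no canonical `dt_step`; it is user-set, and the step-halving
behaviour of the terminal state is the practical convergence check (the
test suite asserts that the dt → dt/2 → dt/4 differences contract).
Basin membership is evaluated once per window against that window's
frozen portrait: within a window the dynamics are autonomous, so the
label cannot change mid-window, and all basin-change events are resolved
at window granularity.  Exact crossing times are deliberately not
root-found; the window boundary is the resolution of the method.

## Phase portraits

Steady states: multi-start `scipy.optimize.root` (hybr, analytic
Jacobian) from a 7×7 grid over the trapping box, roots deduplicated with
a 1e-3 merge radius and kept at residual < 1e-9.  The model has at most
five roots, so a 7×7 grid is generous; a brute-force 400×400 sign-change
search is kept in the test suite as an independent oracle.  Stability is
classified from the Jacobian eigenvalues with a ±1e-8 dead band: a
portrait with an eigenvalue real part inside the band is flagged
near-bifurcation ("marginal") instead of being force-classified.

Regimes: (1 attractor, 0 saddles) monostable, (2, 1) bistable, (3, 2)
tristable, anything else `other`.

Separatrices are the saddles' stable manifolds, traced by integrating the
time-reversed field from the saddle displaced ±1e-6 along the stable
eigenvector, truncated at a slightly inflated trapping box.  Basin
assignment integrates forward until the state comes within `conv_tol`
(default 1e-3) of an attractor; points within `conv_tol` of a separatrix
polyline are reported *unresolved* rather than forced to a side — the
boundary is a measure-zero set on which the label is not defined.

### Bifurcation detection

Consecutive portraits are compared by kind-aware mutual-nearest matching
within `match_radius` (default 0.05 concentration units).  Unmatched
births/deaths are grouped by single-linkage proximity at 10× the radius
and classified against the three templates this model exhibits:

* attractor → two attractors + saddle (supracritical pitchfork),
* saddle → attractor + two saddles (subcritical pitchfork),
* co-located attractor–saddle pair appearing/annihilating (saddle-node),

in either direction.  Two robustness rules matter in practice.  First,
near a fold the surviving states move fast (√-scaling), so a group that
fits no template is reduced by pairing same-kind deaths with births —
continuations, not events.  Second, near a pitchfork the offspring
separate like √(parameter distance) and the converting state can
spuriously match one offspring, shrinking the group to a saddle-node
signature; a saddle-node group is therefore re-examined and upgraded to a
pitchfork when pulling an adjacent fast-moving matched pair into it
completes a pitchfork template.  Groups that still fit nothing are
reported `unclassified` with diagnostics, never dropped.

## Quasi-potential

The increment along a trajectory segment is

```
ΔV_q = −[(dx/dt)² + (dy/dt)²] Δt
```

evaluated at the segment midpoint state.  (The sum of both squared
components is the form forced by substituting `Δx = (dx/dt)Δt`,
`Δy = (dy/dt)Δt` into `ΔV_q = −(dx/dt)Δx − (dy/dt)Δy`.)  It is
non-positive, vanishes exactly at steady states, and makes `V_q` a
Lyapunov function: trajectories always run downhill, and attractors are
local minima.  `V_q` is defined per fixed parameter set only;
accumulation over a non-constant schedule is rejected.

Surfaces are built from a `seed_grid_n`² grid of initial conditions
(default 10×10) over the trapping box, each integrated to convergence and
truncated there (avoiding unbounded zero-increment tails), then
normalised by the two standard levelling assumptions: trajectories
converging to the same attractor share a final level, and the nearest
pair of start points lying in different basins share an initial level.
"Adjacent" is operationalised as the minimal-Euclidean-distance pair of
seeds with different basin labels — the least-assumption reading; for
more than two basins, basins are anchored one at a time through their
nearest already-anchored neighbour.  The normalised samples are linearly
interpolated on a Delaunay triangulation; no smoothing is applied (it
could manufacture artefactual minima), and grid nodes outside the sampled
hull stay NaN rather than being extrapolated.

There is no canonical seed count; refinement stability (doubling
`seed_grid_n` changes node values little away from the separatrix, where
the accumulated level is genuinely discontinuous) is the practical check
and is asserted in the tests.

## Mechanism classification

Steady states are tracked as lineages by the same kind-aware matching,
reconciled with detected bifurcations so that births/deaths carry a
causal link.  Per window `k`, with `B(k)` the trajectory's basin lineage:

1. `B(k) ≠ B(k−1)` and the old attractor's lineage ended at or before
   `k` → **transition**;
2. old attractor alive, gaining attractor born by a bifurcation earlier
   in the run → **capture (topological)**;
3. old attractor alive, gaining attractor existed from the start →
   **capture (geometric)**.

Rule 1 takes precedence when the old attractor dies in the same window as
the basin change.  The *delay* of a transition or topological capture is
measured from the bifurcation that created the gaining attractor's
lineage: that is the event the basin change is causally downstream of,
and it makes the delay strictly positive (the basin change can never
precede the birth of the basin).  When the gaining lineage has no in-run
birth, the old attractor's death time is the fallback reference.
Windows with unresolved basins are skipped for rules 1–3 and reported in
the notes, never silently dropped.

Pursuit is qualitative in origin and needs thresholds to be operational:
an episode is flagged while the basin's attractor moves more than
`eps_move` (default 1e-4 concentration units per window) and the state
stays further than `eps_conv` (default 1e-2) from it, sustained for at
least `min_steps` (default 3) windows.  The episode is *stabilising* if
every velocity component of the trajectory keeps its sign over the
episode and *reversing* if one flips (displacements below 1e-7 are
treated as numerical jitter).  All three thresholds are exposed.

Capture into a basin created before the modelled window would be
indistinguishable from geometric capture; the run start is treated as the
epistemic boundary, so such events classify as geometric.

## Canonical scenarios

The model fixes no parameter values, so the packaged baseline
(`α = 0.3`, `a = c = 0.3`, `b = d = 0.5`, `λ = 1`) was discovered once by
regime scanning and frozen (`scripts/discover_scenarios.py`).  The
selection criterion was a *clean* route along the `a = c` sweep: many
otherwise-plausible baselines pass through a narrow window of extra
diagonal folds (up to seven steady states) between the bistable and
tristable regimes; the packaged baseline shows the textbook route — the
diagonal saddle converts in place through a subcritical pitchfork at
`a = c ≈ 0.6426`, and the outer attractor–saddle pairs annihilate in two
simultaneous saddle-nodes at `a = c ≈ 0.7490`, both refined by bisection
to 1e-4 relative width.

The five scenarios and their design logic:

* **transition** — slow `a = c` ramp 0.3 → 0.9 over 30 time units
  (`dt_step` 0.5), started exactly on the high-x attractor.  Starting *on*
  the attractor keeps the trajectory inside its shrinking basin until the
  saddle-node, producing a pure transition (with pursuit episodes while
  the attractor moves, as expected).
* **pursuit_up / pursuit_down** — `α` ramped 0.12 → 0.24 over 5 units,
  and 0.45 → 0.15 over 10 units.  The up-ramp range was chosen so the
  attractor's motion is monotone in both components (beyond `α ≈ 0.24`
  its x-coordinate turns around, which would contaminate the stabilising
  sub-label); the down-ramp starts the trajectory on the far side of the
  attractor's path so the attractor overtakes it and the direction
  reverses.  Both stay inside the bistable band (`α ∈ [0.10, 0.477]`).
* **capture_topological** — the same `a = c` ramp family but fast
  (0.3 → 0.9 over 3 units, `dt_step` 0.1) and started away from the
  attractor near the saddle: the trajectory is still transient when the
  pitchfork-born central basin expands over it, before the saddle-node.
  The contrast with the transition scenario is purely initial condition
  and ramp speed — same schedule family, different mechanism.
* **capture_geometric** — only `b` ramped 0.5 → 0.62 over 6 units,
  deliberately stopping short of the saddle-node at `b ≈ 0.6265`, so *no*
  bifurcation occurs anywhere in the run and the capture is unambiguously
  geometric.  The start point was chosen so the post-capture turn crosses
  the inbound leg, producing the self-intersecting path that autonomous
  planar systems cannot show.

Everything is deterministic: fixed start grids, no randomness anywhere in
the pipeline.

## Problem sizes

Default problem sizes throughout are chosen as the smallest that leave a
comfortable margin on every check: 25-point sweeps for the regime census,
10×10 seed grids and 60×60 output grids for surfaces, 400×400 grids for
the brute-force oracle, 10 random parameter sets per regime for the
cross-check.  The full test suite runs in about a minute.

## Limitations

* Mechanism events are resolved at `dt_step` granularity; sub-window
  timing (e.g. the exact separatrix-crossing instant) is out of scope.
* The classifier's pursuit thresholds are declared, not derived; runs
  with attractor motion near `eps_move` may flag or miss borderline
  episodes.
* The quasi-potential is a visualisation device with the Lyapunov
  property, not a stochastic (Fokker–Planck / large-deviation) potential;
  no probabilistic validation is attempted.
* Bifurcation classification assumes the three templates this model
  exhibits; exotic codimension-2 coincidences would be reported
  `unclassified`.
* Everything is specific to the planar toggle switch; the event taxonomy
  may be incomplete in higher dimensions.
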