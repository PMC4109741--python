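"""Time-dependence of parameters: piecewise-linear ramps, sampled and held.

A :class:`ParamSchedule` describes how the toggle-switch parameters change
over a run.  The continuous description is a set of linear ramps per
parameter; the system is integrated with a step-wise approximation that
samples the ramps once per ``dt_step`` window (at the window start, a
left-sample convention) and holds them constant within it.  Any consistent
sampling convention converges to the continuous schedule as dt_step -> 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import yaml

from .model import ToggleParams

_PARAM_NAMES = ("alpha_x", "alpha_y", "a", "b", "c", "d", "lambda_x", "lambda_y")

#: Convenience aliases that ramp two parameters in lockstep (the symmetric
#: sweeps of the canonical simulations change a and c, or both alphas,
#: simultaneously).
_COUPLED = {
    "a_c": ("a", "c"),
    "b_d": ("b", "d"),
    "alpha": ("alpha_x", "alpha_y"),
    "lambda": ("lambda_x", "lambda_y"),
}


@dataclass(frozen=True)
class Ramp:
    """Linear change of one parameter from v0 at t0 to v1 at t1."""

    param: str
    t0: float
    t1: float
    v0: float
    v1: float

    def __post_init__(self):
        if self.param not in _PARAM_NAMES and self.param not in _COUPLED:
            raise ValueError(f"unknown parameter {self.param!r}")
        if not self.t1 > self.t0:
            raise ValueError(f"ramp for {self.param!r} needs t1 > t0")

    def targets(self) -> tuple[str, ...]:
        return _COUPLED.get(self.param, (self.param,))

    def value(self, t: float) -> float:
        if t <= self.t0:
            return self.v0
        if t >= self.t1:
            return self.v1
        frac = (t - self.t0) / (self.t1 - self.t0)
        return self.v0 + frac * (self.v1 - self.v0)


@dataclass(frozen=True)
class ParamSchedule:
    """Baseline parameters plus ramps, with the step size of the piecewise-
    constant approximation.

    Outside all ramp segments a parameter holds its most recent value
    (baseline before its first segment, the last segment's end value after).
    Overlapping segments for one parameter are a configuration error.
    """

    baseline: ToggleParams
    ramps: tuple[Ramp, ...] = ()
    dt_step: float = 0.5
    t_final: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "ramps", tuple(self.ramps))
        if self.dt_step <= 0:
            raise ValueError("dt_step must be > 0")
        if self.t_final <= 0:
            raise ValueError("t_final must be > 0")
        per_target: dict[str, list[Ramp]] = {}
        for r in self.ramps:
            for tgt in r.targets():
                per_target.setdefault(tgt, []).append(r)
        for tgt, rs in per_target.items():
            rs = sorted(rs, key=lambda r: r.t0)
            for prev, nxt in zip(rs, rs[1:]):
                if nxt.t0 < prev.t1:
                    raise ValueError(
                        f"overlapping ramps for parameter {tgt!r}: "
                        f"[{prev.t0}, {prev.t1}] and [{nxt.t0}, {nxt.t1}]"
                    )
        # evaluated parameters must be valid at every window start and at
        # ramp endpoints (linear segments cannot violate bounds in between
        # if the endpoints are valid)
        for t in list(self.window_starts()) + [
            tt for r in self.ramps for tt in (r.t0, r.t1) if 0 <= tt <= self.t_final
        ]:
            self.continuous_at(t)  # raises via ToggleParams validation

    # -- continuous description -------------------------------------------

    def continuous_at(self, t: float) -> ToggleParams:
        """Exact ramp values at time t (no sample-and-hold)."""
        vals = self.baseline.as_dict()
        per_target: dict[str, list[Ramp]] = {}
        for r in self.ramps:
            for tgt in r.targets():
                per_target.setdefault(tgt, []).append(r)
        for tgt, rs in per_target.items():
            rs = sorted(rs, key=lambda r: r.t0)
            v = vals[tgt]
            for r in rs:
                if t < r.t0:
                    break
                v = r.value(t)
            vals[tgt] = v
        return ToggleParams(**vals)

    # -- step-wise approximation ------------------------------------------

    @property
    def n_windows(self) -> int:
        return math.ceil(self.t_final / self.dt_step - 1e-12)

    def window_starts(self):
        return [k * self.dt_step for k in range(self.n_windows)]

    def window_bounds(self, k: int) -> tuple[float, float]:
        t0 = k * self.dt_step
        return t0, min(t0 + self.dt_step, self.t_final)

    def window_index(self, t: float) -> int:
        if t < 0 or t > self.t_final:
            raise ValueError(f"time {t} outside schedule horizon [0, {self.t_final}]")
        return min(int(t / self.dt_step), self.n_windows - 1)

    def params_at(self, t: float) -> ToggleParams:
        """Sampled-and-held parameters governing the window containing t."""
        k = self.window_index(t)
        return self.continuous_at(k * self.dt_step)

    @property
    def is_constant(self) -> bool:
        return all(r.v0 == r.v1 for r in self.ramps)

    # -- config round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.as_dict(),
            "ramps": [
                {"param": r.param, "t0": r.t0, "t1": r.t1, "v0": r.v0, "v1": r.v1}
                for r in self.ramps
            ],
            "dt_step": self.dt_step,
            "t_final": self.t_final,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSchedule":
        try:
            baseline = ToggleParams.from_dict(d["baseline"])
            ramps = tuple(
                Ramp(
                    param=str(r["param"]), t0=float(r["t0"]), t1=float(r["t1"]),
                    v0=float(r["v0"]), v1=float(r["v1"]),
                )
                for r in d.get("ramps", [])
            )
            return cls(
                baseline=baseline, ramps=ramps,
                dt_step=float(d["dt_step"]), t_final=float(d["t_final"]),
            )
        except KeyError as exc:
            raise ValueError(f"schedule config missing key {exc.args[0]!r}") from exc

    @classmethod
    def from_file(cls, path) -> "ParamSchedule":
        with open(path) as fh:
            text = fh.read()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"schedule config {path} is not a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
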