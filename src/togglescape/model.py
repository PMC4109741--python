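"""Toggle-switch vector field, Jacobian, and the gradient-system diagnostic.

The model is a two-gene mutual-repression circuit with auto-activation:

    dx/dt = alpha_x + [x^4 / (a^4 + x^4)] * [b^4 / (b^4 + y^4)] - lambda_x * x
    dy/dt = alpha_y + [y^4 / (c^4 + y^4)] * [d^4 / (d^4 + x^4)] - lambda_y * y

``x`` and ``y`` are protein concentrations.  Auto-activation and mutual
repression are quartic Hill sigmoids; external activation and decay are
linear.  The Hill exponent is a fixed property of the model, not a tunable
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace, asdict

import numpy as np

#: Fixed Hill exponent of the auto-activation and repression sigmoids.
HILL_N: int = 4


@dataclass(frozen=True)
class ToggleParams:
    """One instantaneous parameter set of the toggle switch.

    Attributes
    ----------
    alpha_x, alpha_y : float
        External (linear) activation rates, >= 0, concentration/time.
    a, c : float
        Auto-activation thresholds for x and y, > 0, concentration.
    b, d : float
        Mutual-repression thresholds (b: repression of X by Y;
        d: repression of Y by X), > 0, concentration.
    lambda_x, lambda_y : float
        Linear decay rates, > 0, 1/time.
    """

    alpha_x: float
    alpha_y: float
    a: float
    b: float
    c: float
    d: float
    lambda_x: float = 1.0
    lambda_y: float = 1.0

    def __post_init__(self) -> None:
        vals = asdict(self)
        for name, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
        for name in ("a", "b", "c", "d", "lambda_x", "lambda_y"):
            if vals[name] <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {vals[name]!r}")
        for name in ("alpha_x", "alpha_y"):
            if vals[name] < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {vals[name]!r}")

    def replace(self, **kwargs) -> "ToggleParams":
        return _dc_replace(self, **kwargs)

    def swapped(self) -> "ToggleParams":
        """Parameter set with the roles of the two genes exchanged."""
        return ToggleParams(
            alpha_x=self.alpha_y, alpha_y=self.alpha_x,
            a=self.c, b=self.d, c=self.a, d=self.b,
            lambda_x=self.lambda_y, lambda_y=self.lambda_x,
        )

    @property
    def is_symmetric(self) -> bool:
        return self == self.swapped()

    def trapping_box(self) -> tuple[float, float]:
        """Upper corner (x_max, y_max) of the forward-invariant box.

        The production terms are bounded by alpha + 1, so for
        x > (alpha_x + 1)/lambda_x the flow points inward (dx/dt < 0), and
        symmetrically for y.  All steady states and long-run trajectories lie
        inside [0, x_max] x [0, y_max].
        """
        return (self.alpha_x + 1.0) / self.lambda_x, (self.alpha_y + 1.0) / self.lambda_y

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ToggleParams":
        required = ("alpha_x", "alpha_y", "a", "b", "c", "d")
        allowed = required + ("lambda_x", "lambda_y")
        missing = [k for k in required if k not in d]
        unknown = [k for k in d if k not in allowed]
        if missing or unknown:
            raise ValueError(
                f"bad parameter mapping: missing {missing}, unknown {unknown}"
            )
        return cls(**{k: float(v) for k, v in d.items()})


def _hill_act(u, k):
    """Activating quartic Hill term u^4/(k^4 + u^4)."""
    u4 = u ** HILL_N
    return u4 / (k ** HILL_N + u4)


def _hill_rep(u, k):
    """Repressing quartic Hill term k^4/(k^4 + u^4)."""
    k4 = k ** HILL_N
    return k4 / (k4 + u ** HILL_N)


def _check_state(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape[0] != 2:
        raise ValueError(f"state must have two components, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("state contains non-finite components")
    return s


def vector_field(s, p: ToggleParams) -> np.ndarray:
    """Rates (dx/dt, dy/dt) at state ``s``.

    ``s`` may be a pair or an array of shape (2, ...) for vectorised
    evaluation over a grid.
    """
    s = _check_state(s)
    x, y = s[0], s[1]
    fx = p.alpha_x + _hill_act(x, p.a) * _hill_rep(y, p.b) - p.lambda_x * x
    fy = p.alpha_y + _hill_act(y, p.c) * _hill_rep(x, p.d) - p.lambda_y * y
    return np.stack([fx, fy])


def jacobian(s, p: ToggleParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the vector field at ``s``.

    d/du [u^4/(k^4+u^4)] = 4 k^4 u^3 / (k^4 + u^4)^2, which vanishes at
    u = 0 — so at the origin the Jacobian is diag(-lambda_x, -lambda_y).
    """
    s = _check_state(s)
    x, y = float(s[0]), float(s[1])
    n = HILL_N

    def d_act(u, k):
        k4, u4 = k ** n, u ** n
        return n * k4 * u ** (n - 1) / (k4 + u4) ** 2

    def d_rep(u, k):
        k4, u4 = k ** n, u ** n
        return -n * k4 * u ** (n - 1) / (k4 + u4) ** 2

    j11 = d_act(x, p.a) * _hill_rep(y, p.b) - p.lambda_x
    j12 = _hill_act(x, p.a) * d_rep(y, p.b)
    j21 = _hill_act(y, p.c) * d_rep(x, p.d)
    j22 = d_act(y, p.c) * _hill_rep(x, p.d) - p.lambda_y
    return np.array([[j11, j12], [j21, j22]])


def gradient_condition_residual(
    p: ToggleParams,
    region: tuple[float, float, float, float] | None = None,
    grid_n: int = 50,
) -> float:
    """Max of |d(dx/dt)/dy - d(dy/dt)/dx| over a grid on ``region``.

    A planar system admits a closed-form potential exactly when the cross
    partials of its two components agree everywhere; a residual of zero on
    the region identifies a gradient system there.  The toggle switch is not
    a gradient system in its interesting regimes, which is what motivates
    the numerically constructed quasi-potential.

    ``region`` is (x_lo, x_hi, y_lo, y_hi); defaults to the trapping box.
    """
    if region is None:
        xmax, ymax = p.trapping_box()
        region = (0.0, xmax, 0.0, ymax)
    x_lo, x_hi, y_lo, y_hi = map(float, region)
    if not (x_hi > x_lo and y_hi > y_lo):
        raise ValueError(f"degenerate region {region!r}")
    if x_lo < 0 or y_lo < 0:
        raise ValueError("region must lie in the non-negative quadrant")
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    xs = np.linspace(x_lo, x_hi, grid_n)
    ys = np.linspace(y_lo, y_hi, grid_n)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    # residual = |J12 - J21|, evaluated vectorised
    f_y = _hill_act(xx, p.a) * (-HILL_N * p.b ** HILL_N * yy ** (HILL_N - 1)
                                / (p.b ** HILL_N + yy ** HILL_N) ** 2)
    g_x = _hill_act(yy, p.c) * (-HILL_N * p.d ** HILL_N * xx ** (HILL_N - 1)
                                / (p.d ** HILL_N + xx ** HILL_N) ** 2)
    return float(np.max(np.abs(f_y - g_x)))
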