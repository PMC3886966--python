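"""The 8-parameter clock-forced kinetic model of relative PPARalpha mRNA.

State X(t) is relative PPARalpha mRNA expression (dimensionless, normalized so
the lean-control 6 AM level is ~1).  The clock enters through a 24-h-periodic
BMAL1 drive B(t):

    dX/dt = v0 + v_p * B(t)^n / (K_p^n + B(t)^n)
               - v_d * X / (K_d + X) - delta_p * X

The eight parameters cover basal synthesis (v0), BMAL1-activated synthesis
(maximum rate v_p, activation constant K_p, Hill coefficient n), saturable
specific degradation (v_d, K_d), non-specific first-order degradation
(delta_p) and the initial state X0 at the 6 AM reference point.  The model
has no feedback from PPARalpha onto the clock: B(t) is an input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from .forcing import ClockForcing

PARAM_NAMES = ("v0", "v_p", "K_p", "n", "v_d", "K_d", "delta_p", "X0")

#: 6 AM, the reference point expression is normalized to; integration starts here
T_START_H = 6.0


class IntegrationError(RuntimeError):
    """Adaptive integration failed; carries the last good time."""

    def __init__(self, message: str, last_time: float):
        self.last_time = last_time
        super().__init__(f"{message} (last good time t = {last_time:.3f} h)")


class ConvergenceError(RuntimeError):
    """Periodic solution did not converge within the period budget."""


@dataclass(frozen=True)
class PparModelParams:
    """The eight kinetic parameters, all non-negative; n restricted to [1, 8]."""

    v0: float
    v_p: float
    K_p: float
    n: float
    v_d: float
    K_d: float
    delta_p: float
    X0: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (1.0 <= self.n <= 8.0):
            raise ValueError(f"Hill coefficient n must lie in [1, 8], got {self.n}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "PparModelParams":
        a = np.asarray(a, dtype=float)
        if a.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got shape {a.shape}")
        return cls(**dict(zip(PARAM_NAMES, a)))

    def replace(self, **kw) -> "PparModelParams":
        return replace(self, **kw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PparModelParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Trajectory:
    """Model output X on a time grid, tagged with its parameters and forcing."""

    times: np.ndarray
    values: np.ndarray
    params: PparModelParams
    forcing_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")


def hill_activation(b, K_p: float, n: float):
    """BMAL1 occupancy term B^n / (K_p^n + B^n) in [0, 1]."""
    b = np.asarray(b, dtype=float)
    bn = b**n
    return bn / (K_p**n + bn)


def rhs(t: float, x: float, p: PparModelParams, f: ClockForcing) -> float:
    """Instantaneous dX/dt at time t (hours) and state x (expression)."""
    b = f(t)
    synthesis = p.v0 + p.v_p * hill_activation(b, p.K_p, p.n)
    clearance = p.v_d * x / (p.K_d + x) + p.delta_p * x
    return float(synthesis - clearance)


def simulate(p: PparModelParams, f: ClockForcing, t_grid,
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Adaptive stiff-capable integration from X0 at t = 6 h, reported on t_grid.

    Non-negativity holds by construction: at x = 0 the right-hand side is
    v0 + v_p * hill >= 0 for valid parameters.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] < T_START_H:
        raise ValueError(f"t_grid must start at or after t = {T_START_H} h")

    sol = solve_ivp(
        lambda t, x: [rhs(t, x[0], p, f)],
        (T_START_H, float(t_grid[-1])),
        [p.X0],
        t_eval=t_grid if t_grid[0] > T_START_H or len(t_grid) > 1 else None,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else T_START_H)
    values = np.interp(t_grid, sol.t, sol.y[0]) if sol.t.shape != t_grid.shape else sol.y[0]
    return Trajectory(times=t_grid, values=np.clip(values, 0.0, None), params=p,
                      forcing_id=f.mode)


def periodic_solution(p: PparModelParams, f: ClockForcing, *,
                      tol: float = 1e-6, max_periods: int = 200,
                      n_grid: int = 241, rtol: float = 1e-8,
                      atol: float = 1e-10) -> Trajectory:
    """Entrained one-period trajectory, independent of the initial state.

    Integrates period after period from X0 until the sampled trajectory of two
    successive periods differs by less than ``tol`` everywhere, then returns
    the final period on [6, 30] h.  Requires dissipation (delta_p + v_d > 0).
    """
    if p.delta_p + p.v_d <= 0:
        raise ValueError("periodic solution requires delta_p + v_d > 0 (dissipative)")
    rel = np.linspace(0.0, 24.0, n_grid)
    x0 = p.X0
    prev = None
    for k in range(max_periods):
        sol = solve_ivp(
            lambda t, x: [rhs(t, x[0], p, f)],
            (T_START_H, T_START_H + 24.0), [x0],
            t_eval=T_START_H + rel, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(sol.message, float(sol.t[-1]))
        cur = sol.y[0]
        if prev is not None and np.max(np.abs(cur - prev)) < tol:
            return Trajectory(times=T_START_H + rel, values=np.clip(cur, 0.0, None),
                              params=p, forcing_id=f.mode)
        prev = cur
        x0 = float(cur[-1])
    raise ConvergenceError(
        f"periodic solution not converged to {tol} within {max_periods} periods"
    )


def steady_state(p: PparModelParams, b_const: float,
                 tol: float = 1e-12) -> float:
    """Algebraic steady state under constant forcing, by bisection.

    Solves v0 + v_p * hill(b) = v_d * X/(K_d + X) + delta_p * X for X >= 0.
    The left side is constant and the right side is strictly increasing from 0,
    so the root is unique when delta_p + v_d > 0.
    """
    synthesis = p.v0 + p.v_p * float(hill_activation(b_const, p.K_p, p.n))
    if p.delta_p + p.v_d <= 0:
        raise ValueError("steady state requires delta_p + v_d > 0")

    def g(x):
        return synthesis - (p.v_d * x / (p.K_d + x) + p.delta_p * x)

    if synthesis == 0.0:
        return 0.0
    hi = 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("no finite steady state found")
    return float(bisect(g, 0.0, hi, xtol=tol))
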