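"""24-h-periodic BMAL1 drive B(t) for the PPARalpha equation.

Two modes are provided:

* **empirical** (default for fitting): a periodic cubic interpolant through the
  measured BMAL1 group means, exact at the knots and clipped at zero.
* **mechanistic**: a minimal entrainable Goodwin-type three-variable oscillator
  (delayed negative feedback through a steep Hill repression) driven by a
  12:12 square-wave light term, integrated past its transient and returned as
  the final-cycle interpolant rescaled to a target mesor/amplitude.

Both satisfy B(t + 24) = B(t) and B(t) >= 0 for all real t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .data_io import ANCHOR_HOUR, GroupMeanCurve, unwrap_times

PERIOD_H = 24.0


class InsufficientDataError(ValueError):
    """Fewer than 4 distinct knot times for empirical forcing."""


class EntrainmentWarning(UserWarning):
    """Oscillator failed to lock to the 24-h light cycle; carries the period."""

    def __init__(self, period_h: float):
        self.period_h = period_h
        super().__init__(
            f"oscillator period {period_h:.3f} h deviates from 24 h by more than 0.1 h"
        )


@dataclass(frozen=True)
class ClockForcing:
    """Periodic non-negative drive; call with any real time in hours."""

    mode: str
    fn: Callable[[np.ndarray], np.ndarray]
    period_h: float = PERIOD_H

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.clip(self.fn(t), 0.0, None)
        return float(out) if out.ndim == 0 else out


def cosinor_forcing(mesor: float = 1.0, amplitude: float = 0.5,
                    acrophase_h: float = 10.0) -> ClockForcing:
    """Analytic cosinor drive M + A cos(2 pi (t - phi)/24); handy ground truth."""
    if amplitude > mesor:
        raise ValueError("amplitude must not exceed mesor (B must stay >= 0)")

    def fn(t):
        return mesor + amplitude * np.cos(2 * np.pi * (t - acrophase_h) / PERIOD_H)

    return ClockForcing(mode="empirical", fn=fn)


def empirical_forcing(curve: GroupMeanCurve, anchor: float = ANCHOR_HOUR) -> ClockForcing:
    """Periodic cubic interpolation through (time, mean) knots of a BMAL1 curve.

    Periodic closure appends the first knot at +24 h; negative interpolant
    values (possible from cubic overshoot) are clipped to zero at evaluation.
    """
    t, m, _, _ = curve.unwrapped(anchor)
    if len(np.unique(t)) < 4:
        raise InsufficientDataError(
            f"empirical forcing needs >= 4 distinct times, got {len(np.unique(t))}"
        )
    knots = np.append(t, t[0] + PERIOD_H)
    vals = np.append(m, m[0])
    spline = CubicSpline(knots, vals, bc_type="periodic")
    t0 = knots[0]

    def fn(tt):
        return spline(t0 + np.mod(tt - t0, PERIOD_H))

    return ClockForcing(mode="empirical", fn=fn)


@dataclass(frozen=True)
class OscillatorParams:
    """Goodwin-type core: x1 -| x3 loop with light input on x1.

    dx1/dt = v1 / (1 + (x3/K)^hill) + L(t) - d1 x1
    dx2/dt = k2 x1 - d2 x2
    dx3/dt = k3 x2 - d3 x3

    L(t) is a square wave: light_amplitude during the photoperiod, else 0.
    Scaling all rates (v1, k2, k3, d1, d2, d3, light_amplitude) by c rescales
    time by 1/c with an identical waveform.  Defaults give a free-running
    period close to (but not at) 24 h so that the light term entrains it.
    """

    v1: float = 0.5393
    K: float = 1.0
    hill: float = 10.0
    k2: float = 0.16179
    k3: float = 0.16179
    d1: float = 0.16179
    d2: float = 0.16179
    d3: float = 0.16179
    light_amplitude: float = 0.03236
    lights_on_hour: float = 6.0
    photoperiod_h: float = 12.0

    def __post_init__(self) -> None:
        for name in ("v1", "K", "hill", "k2", "k3", "d1", "d2", "d3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.light_amplitude < 0:
            raise ValueError("light_amplitude must be >= 0")

    def scaled(self, c: float) -> "OscillatorParams":
        """Jointly scale all production/degradation rates by c (time rescale)."""
        return replace(self, v1=self.v1 * c, k2=self.k2 * c, k3=self.k3 * c,
                       d1=self.d1 * c, d2=self.d2 * c, d3=self.d3 * c,
                       light_amplitude=self.light_amplitude * c)


def _light(t: np.ndarray, p: OscillatorParams) -> np.ndarray:
    zt = np.mod(t - p.lights_on_hour, PERIOD_H)
    return np.where(zt < p.photoperiod_h, p.light_amplitude, 0.0)


def _goodwin_rhs(t, y, p: OscillatorParams):
    x1, x2, x3 = y
    dx1 = p.v1 / (1.0 + (max(x3, 0.0) / p.K) ** p.hill) + float(_light(t, p)) - p.d1 * x1
    dx2 = p.k2 * x1 - p.d2 * x2
    dx3 = p.k3 * x2 - p.d3 * x3
    return [dx1, dx2, dx3]


def integrate_oscillator(p: OscillatorParams, n_periods: int = 40,
                         grid_per_hour: int = 10):
    """Integrate the oscillator from a generic start; returns (t, x1) arrays."""
    t_end = n_periods * PERIOD_H
    t_eval = np.linspace(0.0, t_end, int(t_end * grid_per_hour) + 1)
    sol = solve_ivp(_goodwin_rhs, (0.0, t_end), [0.1, 0.1, 0.1], args=(p,),
                    t_eval=t_eval, method="LSODA", rtol=1e-8, atol=1e-10,
                    max_step=0.25)
    if not sol.success:
        raise RuntimeError(f"oscillator integration failed: {sol.message}")
    return sol.t, sol.y[0]


def measure_period(t: np.ndarray, x: np.ndarray, n_cycles: int = 5) -> float:
    """Mean interval between the last upward mean-crossings of x(t)."""
    xc = x - x.mean()
    idx = np.nonzero((xc[:-1] < 0) & (xc[1:] >= 0))[0]
    if len(idx) < n_cycles + 1:
        raise RuntimeError("too few oscillation cycles to measure a period")
    # linear interpolation of each crossing time
    frac = -xc[idx] / (xc[idx + 1] - xc[idx])
    crossings = t[idx] + frac * (t[idx + 1] - t[idx])
    last = crossings[-(n_cycles + 1):]
    return float(np.mean(np.diff(last)))


def free_running_period(p: OscillatorParams, n_periods: int = 40) -> float:
    """Intrinsic period with the light term switched off."""
    dark = replace(p, light_amplitude=0.0)
    t, x1 = integrate_oscillator(dark, n_periods=n_periods)
    keep = t >= (n_periods // 2) * PERIOD_H  # discard transient half
    return measure_period(t[keep], x1[keep])


def mechanistic_forcing(p: OscillatorParams | None = None, *,
                        mesor: float = 1.0, amplitude: float = 0.5,
                        n_periods: int = 40, discard_periods: int = 30,
                        period_tol_h: float = 0.1) -> ClockForcing:
    """Entrained oscillator drive, rescaled to a target mesor and amplitude.

    Integrates >= 10 periods, discards the transient, verifies the entrained
    period is within ``period_tol_h`` of 24 h (otherwise an
    :class:`EntrainmentWarning` carrying the measured period is issued) and
    returns a periodic interpolant of the final cycle of x1.
    """
    if p is None:
        p = OscillatorParams()
    if n_periods - discard_periods < 2:
        raise ValueError("need at least 2 retained periods")
    t, x1 = integrate_oscillator(p, n_periods=n_periods)
    keep = t >= discard_periods * PERIOD_H
    period = measure_period(t[keep], x1[keep])
    if abs(period - PERIOD_H) > period_tol_h:
        warnings.warn(EntrainmentWarning(period))

    # final full cycle, anchored at absolute clock time
    t0 = (n_periods - 1) * PERIOD_H
    sel = t >= t0 - 1e-9
    tc, xc = t[sel], x1[sel]
    lo, hi = xc.min(), xc.max()
    half_range = (hi - lo) / 2.0
    if half_range <= 0:
        raise RuntimeError("oscillator output is flat; cannot build a drive")
    scaled = mesor + amplitude * (xc - (lo + hi) / 2.0) / half_range
    # periodic closure: force the endpoints to agree exactly
    scaled[-1] = scaled[0]
    spline = CubicSpline(tc, scaled, bc_type="periodic")

    def fn(tt):
        return spline(t0 + np.mod(tt - t0, PERIOD_H))

    return ClockForcing(mode="mechanistic", fn=fn)
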