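"""Global sensitivity analysis: Latin hypercube sampling + PRCC.

Partial rank correlation coefficients follow the standard construction: all
columns (parameters and output) are rank-transformed (average ties); the PRCC
of parameter j is the Pearson correlation between the residuals of
rank-regressing parameter j on all other parameters and of rank-regressing
the output on all other parameters.  Significance uses
t = PRCC * sqrt((n - 2 - k) / (1 - PRCC^2)) with k the number of adjusted
parameters, against a two-sided t distribution.

Model output is the entrained periodic solution X evaluated at the light/dark
switch points (6 AM and 6 PM by default).  A dummy parameter that the model
never reads is included by default as a built-in false-positive control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from . import _kernels
from .forcing import ClockForcing
from .model import PARAM_NAMES, PparModelParams, T_START_H

DUMMY_NAME = "dummy"


class ConfigError(ValueError):
    """Sensitivity configuration violates a precondition."""


class DegenerateInputError(ValueError):
    """A sample column is constant; PRCC is undefined for it."""


class SimulationCensusError(RuntimeError):
    """More than the tolerated fraction of model evaluations failed."""


@dataclass
class PrccConfig:
    n_samples: int = 1000
    eval_times_h: tuple[float, ...] = (6.0, 18.0)
    bounds: dict[str, tuple[float, float]] | None = None  # None: +/-50% of center
    seed: int = 0
    include_dummy: bool = True
    n_warm_periods: int = 8
    step_h: float = 0.05
    max_failure_fraction: float = 0.01


@dataclass
class PrccResult:
    """Long-format PRCC table: one row per (parameter, eval time)."""

    table: pd.DataFrame  # columns: parameter, time_h, prcc, t, p, n

    def lookup(self, parameter: str, time_h: float) -> pd.Series:
        m = (self.table["parameter"] == parameter) & (self.table["time_h"] == time_h)
        return self.table.loc[m].iloc[0]

    def significant(self, alpha: float = 0.001) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha]


def latin_hypercube(bounds, n: int, seed: int) -> np.ndarray:
    """Stratified sample: per parameter, one value in each of n equal strata.

    ``bounds`` is a (d, 2) array of [lo, hi]; returns an (n, d) matrix.
    Deterministic given the seed.
    """
    bounds = np.asarray(bounds, dtype=float)
    if not np.all(np.isfinite(bounds)):
        raise ConfigError("bounds must be finite")
    d = bounds.shape[0]
    sampler = qmc.LatinHypercube(d=d, seed=np.random.default_rng(seed))
    u = sampler.random(n)
    return qmc.scale(u, bounds[:, 0], bounds[:, 1])


def _rank_residuals(ranks: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of column j and of the last column against all other columns."""
    n, m = ranks.shape
    others = [c for c in range(m - 1) if c != j]
    design = np.column_stack([np.ones(n)] + [ranks[:, c] for c in others])
    coef_x, *_ = np.linalg.lstsq(design, ranks[:, j], rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ranks[:, -1], rcond=None)
    return ranks[:, j] - design @ coef_x, ranks[:, -1] - design @ coef_y


def prcc(samples: np.ndarray, outputs: np.ndarray,
         names: list[str] | None = None) -> pd.DataFrame:
    """PRCC of every sample column against one output vector.

    Returns a frame with columns parameter, prcc, t, p, n.
    """
    samples = np.asarray(samples, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    n, d = samples.shape
    if names is None:
        names = [f"p{j}" for j in range(d)]
    for j in range(d):
        if np.ptp(samples[:, j]) == 0:
            raise DegenerateInputError(f"column {names[j]!r} is constant")
    if np.ptp(outputs) == 0:
        raise DegenerateInputError("output is constant")

    ranks = np.column_stack(
        [stats.rankdata(samples[:, j]) for j in range(d)]
        + [stats.rankdata(outputs)]
    )
    k = d - 1  # parameters adjusted for
    rows = []
    for j in range(d):
        rx, ry = _rank_residuals(ranks, j)
        denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
        r = float(np.sum(rx * ry) / denom) if denom > 0 else 0.0
        r = min(max(r, -1.0), 1.0)
        df = n - 2 - k
        if abs(r) < 1.0:
            t = r * np.sqrt(df / (1.0 - r**2))
        else:
            t = np.inf * np.sign(r)
        p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        rows.append(dict(parameter=names[j], prcc=r, t=float(t), p=float(p), n=n))
    return pd.DataFrame(rows)


def default_bounds_around(p_center: PparModelParams,
                          rel: float = 0.5) -> dict[str, tuple[float, float]]:
    """+/- rel bounds around a fitted center, clipping n into its [1, 8] domain."""
    out = {}
    for name in PARAM_NAMES:
        c = getattr(p_center, name)
        lo, hi = (1 - rel) * c, (1 + rel) * c
        if name == "n":
            lo, hi = max(lo, 1.0), min(hi, 8.0)
        out[name] = (lo, hi)
    return out


def run_sensitivity(p_center: PparModelParams, f: ClockForcing,
                    cfg: PrccConfig | None = None) -> PrccResult:
    """LHS draw -> entrained model output at each eval time -> PRCC per time."""
    cfg = cfg or PrccConfig()
    bounds = cfg.bounds or default_bounds_around(p_center)
    names = list(PARAM_NAMES)
    barr = [bounds[nm] for nm in names]
    if cfg.include_dummy:
        names.append(DUMMY_NAME)
        barr.append((0.0, 1.0))
    barr = np.asarray(barr, dtype=float)
    if cfg.n_samples <= len(names) + 2:
        raise ConfigError(
            f"n_samples must exceed number of parameters + 2 "
            f"({cfg.n_samples} <= {len(names) + 2})")
    for nm, (lo, hi) in zip(names, barr):
        if not lo < hi:
            raise ConfigError(f"degenerate bounds for {nm}: ({lo}, {hi})")

    samples = latin_hypercube(barr, cfg.n_samples, cfg.seed)
    thetas = np.ascontiguousarray(samples[:, : len(PARAM_NAMES)])

    # sample the entrained trajectory at each clock hour requested
    h = cfg.step_h
    steps_per_period = int(round(24.0 / h))
    n_steps = (cfg.n_warm_periods + 1) * steps_per_period
    rel = (np.mod(np.asarray(cfg.eval_times_h, float) - T_START_H, 24.0)) / h
    if not np.allclose(rel, np.round(rel), atol=1e-9):
        raise ConfigError("eval times must lie on the integration step grid")
    idx = cfg.n_warm_periods * steps_per_period + np.round(rel).astype(np.int64)
    order = np.argsort(idx)
    idx_sorted = idx[order]
    tt = T_START_H + np.arange(2 * n_steps + 1) * (h / 2.0)
    bgrid = np.asarray(f(tt), dtype=float)
    out = _kernels.rk4_sample_batch(thetas, bgrid, h, n_steps, idx_sorted)
    out = out[:, np.argsort(order)]  # back to eval_times order

    bad = ~np.all(np.isfinite(out), axis=1)
    if bad.mean() > cfg.max_failure_fraction:
        raise SimulationCensusError(
            f"{bad.sum()} / {len(bad)} simulations failed "
            f"(> {cfg.max_failure_fraction:.0%} tolerated)")
    good = ~bad

    frames = []
    for i, t_eval in enumerate(cfg.eval_times_h):
        tab = prcc(samples[good], out[good, i], names=names)
        tab.insert(1, "time_h", float(t_eval))
        frames.append(tab)
    return PrccResult(table=pd.concat(frames, ignore_index=True))
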