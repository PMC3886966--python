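"""Synthetic datasets with the statistical structure the analysis assumes.

Every downstream stage (group means, AUC, factorial tests, ODE fitting, PRCC,
ChIP quantification) is exercised against data generated here with known
ground truth.  The generator emulates the study design: 4 groups
(lean/obese x control/HFD), 6 clock times at 4-h spacing over 24 h, 3-5
animals per group per time, cosinor-shaped group means, multiplicative
lognormal noise (qPCR-typical, positivity-preserving).  The lognormal factor
is mean-corrected (mu = -sigma^2/2) so the expected value of every draw is
exactly the generating mean.

Named scenarios encode the qualitative effect patterns the analysis must
detect: amplitude loss under HFD, an interaction confined to the obese-HFD
group, and a stepwise increase in the non-specific mRNA degradation rate
delta_p (lean-control < lean-HFD < obese-control < obese-HFD) with reduced
maximal synthesis v_p in offspring of obese dams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import (DIET_LEVELS, GROUPS, MATERNAL_LEVELS, SAMPLING_TIMES_H,
                      TimecourseDataset)
from .forcing import ClockForcing, cosinor_forcing
from .model import PparModelParams, periodic_solution
from .qpcr import ANTIBODIES, REGIONS

DEFAULT_TIMES = SAMPLING_TIMES_H

SCENARIOS = ("null", "hfd_amplitude_loss", "interaction_obese_hfd",
             "stepwise_degradation")


class SpecError(ValueError):
    """A generator specification violates an invariant."""


def _sigma_from_cv(cv: float) -> float:
    """Lognormal sigma giving a multiplicative coefficient of variation cv."""
    return math.sqrt(math.log(1.0 + cv**2))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    s = _sigma_from_cv(cv)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


# ---------------------------------------------------------------------------
# cosinor-shaped expression datasets

@dataclass(frozen=True)
class CosinorCell:
    """Rhythm descriptors of one group: mesor M, amplitude A, acrophase phi."""

    mesor: float
    amplitude: float
    acrophase_h: float

    def __post_init__(self) -> None:
        if self.mesor <= 0:
            raise SpecError("mesor must be > 0")
        if not (0.0 <= self.amplitude <= self.mesor):
            raise SpecError("need 0 <= amplitude <= mesor (non-negative means)")
        if not (0.0 <= self.acrophase_h < 24.0):
            raise SpecError("acrophase must lie in [0, 24)")

    def mean_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.mesor + self.amplitude * np.cos(
            2.0 * np.pi * (t - self.acrophase_h) / 24.0)


@dataclass(frozen=True)
class CosinorSpec:
    gene: str
    cells: dict[tuple[str, str], CosinorCell]
    noise_cv: float = 0.10
    n_per_cell: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.cells) != set(GROUPS):
            raise SpecError(f"cells must cover all groups {GROUPS}")
        if self.noise_cv < 0:
            raise SpecError("noise_cv must be >= 0")
        if not (3 <= self.n_per_cell <= 5):
            raise SpecError("n_per_cell must be in 3..5 (study design)")


def synth_dataset(spec: CosinorSpec, times=DEFAULT_TIMES,
                  rng: np.random.Generator | None = None) -> TimecourseDataset:
    """Draw a full cross-sectional dataset from a cosinor specification."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows = []
    counter = 0
    for maternal, diet in GROUPS:
        cell = spec.cells[(maternal, diet)]
        for t in times:
            mu = float(cell.mean_at(t))
            noise = _lognormal_factor(rng, spec.noise_cv, spec.n_per_cell)
            for r in range(spec.n_per_cell):
                counter += 1
                rows.append(dict(
                    animal_id=f"A{counter:04d}", maternal=maternal, diet=diet,
                    time_h=float(t), gene=spec.gene,
                    value=mu * float(noise[r])))
    df = pd.DataFrame(rows)
    return TimecourseDataset(df, provenance=dict(
        generator="cosinor", gene=spec.gene, noise_cv=spec.noise_cv,
        n_per_cell=spec.n_per_cell, seed=spec.seed))


#: default positive-limb rhythm (CLOCK/BMAL1 peak 10 AM); the negative limb
#: (Per/Cry) peaks antiphasically at 6 PM
BASE_CELL = CosinorCell(mesor=1.0, amplitude=0.5, acrophase_h=10.0)
NEGATIVE_LIMB_CELL = CosinorCell(mesor=1.0, amplitude=0.5, acrophase_h=18.0)


def cosinor_scenario(name: str, gene: str = "BMAL1", *,
                     base: CosinorCell | None = None, noise_cv: float = 0.10,
                     n_per_cell: int = 4, seed: int = 0) -> CosinorSpec:
    """Named effect scenarios on the cosinor generator.

    * ``null``: all four groups identical.
    * ``hfd_amplitude_loss``: both HFD groups lose half their amplitude.
    * ``interaction_obese_hfd``: only the obese-HFD group is affected — its
      level drops to 75% and its amplitude to 40% of base, the synthetic
      analogue of an interaction-only suppression pattern.  The combined
      deficit keeps the peak-time group contrast detectable at the study's
      n = 4 per cell.
    """
    if name not in ("null", "hfd_amplitude_loss", "interaction_obese_hfd"):
        raise SpecError(f"unknown cosinor scenario {name!r}; "
                        f"stepwise_degradation is an ODE scenario")
    base = base or (NEGATIVE_LIMB_CELL if gene.lower().startswith(("per", "cry"))
                    else BASE_CELL)
    cells = {g: base for g in GROUPS}
    if name == "hfd_amplitude_loss":
        hfd = replace(base, amplitude=0.5 * base.amplitude)
        cells = {g: (hfd if g[1] == "HFD" else base) for g in GROUPS}
    elif name == "interaction_obese_hfd":
        hit = replace(base, mesor=0.75 * base.mesor,
                      amplitude=0.4 * base.amplitude)
        cells = {g: (hit if g == ("obese", "HFD") else base) for g in GROUPS}
    return CosinorSpec(gene=gene, cells=cells, noise_cv=noise_cv,
                       n_per_cell=n_per_cell, seed=seed)


# ---------------------------------------------------------------------------
# clock-forced PPARalpha groups with known kinetic truth

def default_bmal1_forcing() -> ClockForcing:
    """The BMAL1 drive used for generation: cosinor, mesor 1, amplitude 0.5,
    peak 10 AM (the positive-limb waveform)."""
    return cosinor_forcing(mesor=BASE_CELL.mesor, amplitude=BASE_CELL.amplitude,
                           acrophase_h=BASE_CELL.acrophase_h)


def stepwise_degradation_params() -> dict[tuple[str, str], PparModelParams]:
    """Ground-truth kinetics of the four groups.

    delta_p rises stepwise (lean-control < lean-HFD < obese-control <
    obese-HFD) and v_p is reduced in offspring of obese dams; non-specific
    decay dominates clearance, matching the mechanism the analysis is meant
    to recover.  X0 is a placeholder here; the generator replaces it with the
    periodic-solution value at 6 AM so sampled animals sit on the limit cycle.
    """
    base = dict(v0=0.05, K_p=1.0, n=2.0, v_d=0.1, K_d=0.5, X0=1.0)
    table = {
        ("lean", "control"): dict(v_p=1.0, delta_p=0.10),
        ("lean", "HFD"): dict(v_p=1.0, delta_p=0.15),
        ("obese", "control"): dict(v_p=0.7, delta_p=0.22),
        ("obese", "HFD"): dict(v_p=0.7, delta_p=0.32),
    }
    return {g: PparModelParams(**base, **spec) for g, spec in table.items()}


def synth_ppar_groups(f: ClockForcing | None = None,
                      params_by_group: dict[tuple[str, str], PparModelParams] | None = None,
                      *, gene: str = "PPARA", noise_cv: float = 0.05,
                      n_per_cell: int = 4, times=DEFAULT_TIMES,
                      seed: int = 0) -> tuple[TimecourseDataset, pd.DataFrame]:
    """Sample the four groups' entrained model trajectories with noise.

    Returns the dataset plus a ground-truth table (one row per group with the
    generating parameters, X0 set to the periodic-solution 6 AM value) for
    closed-loop recovery tests.
    """
    f = f or default_bmal1_forcing()
    params_by_group = params_by_group or stepwise_degradation_params()
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    counter = 0
    for maternal, diet in GROUPS:
        if (maternal, diet) not in params_by_group:
            raise SpecError(f"scenario lacks parameters for ({maternal}, {diet})")
        p = params_by_group[(maternal, diet)]
        traj = periodic_solution(p, f)
        p_true = p.replace(X0=float(traj.values[0]))
        wrapped = np.mod(traj.times, 24.0)
        means = {}
        for t in times:
            i = int(np.argmin(np.abs(wrapped - (t % 24.0))))
            means[t] = float(traj.values[i])
        for t in times:
            noise = _lognormal_factor(rng, noise_cv, n_per_cell)
            for r in range(n_per_cell):
                counter += 1
                rows.append(dict(
                    animal_id=f"P{counter:04d}", maternal=maternal, diet=diet,
                    time_h=float(t), gene=gene, value=means[t] * float(noise[r])))
        rec = {"maternal": maternal, "diet": diet}
        rec.update({k: getattr(p_true, k) for k in
                    ("v0", "v_p", "K_p", "n", "v_d", "K_d", "delta_p", "X0")})
        truth.append(rec)
    ds = TimecourseDataset(pd.DataFrame(rows), provenance=dict(
        generator="stepwise_degradation", gene=gene, noise_cv=noise_cv,
        n_per_cell=n_per_cell, seed=seed))
    return ds, pd.DataFrame(truth)


def recovery_bounds(truth: pd.DataFrame,
                    rel: float = 0.5) -> dict[str, tuple[float, float]]:
    """Search boxes for the closed-loop recovery study.

    For each kinetic parameter the box spans the range of the generating
    values across the four groups, widened by ``rel`` (default +/-50%) — the
    same convention the PRCC sensitivity analysis uses around a fitted
    center.  One common box serves all groups, so group differences (the
    stepwise delta_p order) are not encoded in the search region.  The Hill
    coefficient is clipped to its [1, 8] domain.
    """
    from .model import PARAM_NAMES  # local import to avoid cycle at load
    out = {}
    for name in PARAM_NAMES:
        lo = (1.0 - rel) * float(truth[name].min())
        hi = (1.0 + rel) * float(truth[name].max())
        if name == "n":
            lo, hi = max(lo, 1.0), min(hi, 8.0)
        out[name] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# ChIP-qPCR Ct tables with known percent-input targets

def default_chip_targets() -> dict[tuple[str, str, float, str, str], float]:
    """Percent-input targets per (antibody, region, time_h, maternal, diet).

    Emulates the qualitative enrichment pattern of the emulated study: the
    activating mark H3K4me3 is high at 6 AM and low at 6 PM in control-fed
    groups, with the obese-HFD group losing most of its 6 AM enrichment (an
    interaction-only effect); the repressive mark H3K27me3 rises under HFD at
    6 AM and only in obese-HFD at 6 PM.  IgG sits well below every specific
    mark.  Effect sizes are set so the interaction is detectable at the
    triplicate level with the default Ct noise.
    """
    targets: dict[tuple[str, str, float, str, str], float] = {}
    h3k4_6am = {("lean", "control"): 8.0, ("lean", "HFD"): 8.0,
                ("obese", "control"): 8.0, ("obese", "HFD"): 3.0}
    h3k27_6pm = {("lean", "control"): 1.0, ("lean", "HFD"): 1.0,
                 ("obese", "control"): 1.0, ("obese", "HFD"): 4.0}
    for region in REGIONS:
        for g in GROUPS:
            targets[("H3K4me3", region, 6.0, *g)] = h3k4_6am[g]
            targets[("H3K4me3", region, 18.0, *g)] = 3.0
            targets[("H3K27me3", region, 6.0, *g)] = 3.0 if g[1] == "HFD" else 1.0
            targets[("H3K27me3", region, 18.0, *g)] = h3k27_6pm[g]
            targets[("IgG", region, 6.0, *g)] = 0.05
            targets[("IgG", region, 18.0, *g)] = 0.05
    return targets


def synth_chip(targets: dict | None = None, *, input_fraction: float = 0.01,
               ct_input_mean: float = 24.0, noise_sd_ct: float = 0.15,
               n_replicates: int = 3, seed: int = 0) -> pd.DataFrame:
    """Emit (ct_ip, ct_input) pairs whose percent-input recovers the targets.

    Inverts %input = 100 * f * 2^(ct_input - ct_ip), then adds independent
    Gaussian Ct noise (sd ``noise_sd_ct``) to both channels.  Returns a long
    table with one row per replicate measurement.
    """
    targets = targets if targets is not None else default_chip_targets()
    igg = {k: v for k, v in targets.items() if k[0] == "IgG"}
    for key, pct in targets.items():
        if pct < 0:
            raise SpecError(f"negative percent-input target for {key}")
        if key[0] != "IgG":
            match = igg.get(("IgG",) + key[1:])
            if match is not None and match >= pct:
                raise SpecError(
                    f"IgG target must sit below the specific mark for {key}")
    rng = np.random.default_rng(seed)
    rows = []
    for (antibody, region, time_h, maternal, diet), pct in sorted(targets.items()):
        if pct <= 0:
            raise SpecError("percent-input targets must be > 0 to invert Cts")
        delta = math.log2(100.0 * input_fraction / pct)
        for r in range(n_replicates):
            ct_input = ct_input_mean + rng.normal(0.0, noise_sd_ct)
            ct_ip = ct_input_mean + delta + rng.normal(0.0, noise_sd_ct)
            rows.append(dict(
                sample_pool=f"{maternal}-{diet}", antibody=antibody,
                region=region, time_h=float(time_h), maternal=maternal,
                diet=diet, replicate=r + 1, ct_ip=ct_ip, ct_input=ct_input,
                input_fraction=input_fraction))
    return pd.DataFrame(rows)
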