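"""qPCR quantification: standard curves, reference normalization, ChIP percent-input.

Relative quantification follows the log-linear standard-curve model
Ct = a + b * log10(quantity) with b < 0; the amplification efficiency is
E = 10^(-1/b) - 1 (b = -3.32 corresponds to E ~ 1, i.e. perfect doubling).
Expression values are normalized to a reference transcript (SRP14 in the
emulated study) by simple division.

ChIP enrichment is expressed as percent of input.  The input aliquot is a
fraction f of the chromatin used for the IP, so the Ct of a hypothetical
100% input would be ct_input + log2(f) (f < 1 means the full input would
amplify -log2(f) cycles earlier).  Hence

    %input = 100 * 2^((ct_input + log2 f) - ct_ip) = 100 * f * 2^(ct_input - ct_ip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

ANTIBODIES = ("H3K4me3", "H3K27me3", "IgG")
REGIONS = ("upstream_500", "downstream_500")


class StandardCurveError(ValueError):
    """Standard-curve fit is impossible or yields an invalid curve."""


class NormalizationError(ValueError):
    """Reference quantity is non-positive."""


class ChipMeasurementError(ValueError):
    """A ChIP Ct record violates an invariant."""


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear calibration of Ct against log10 template quantity."""

    gene: str
    intercept_a: float  # Ct at unit quantity
    slope_b: float      # Ct change per decade of quantity; negative
    r2: float

    def __post_init__(self) -> None:
        if not self.slope_b < 0:
            raise StandardCurveError(
                f"slope must be negative (got {self.slope_b}); Ct falls as template rises"
            )
        eff = self.efficiency
        if not (0.0 < eff <= 1.2):
            raise StandardCurveError(
                f"amplification efficiency {eff:.3f} outside (0, 1.2]"
            )

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope_b) - 1.0

    def predict_ct(self, log10_quantity):
        return self.intercept_a + self.slope_b * np.asarray(log10_quantity, dtype=float)


def fit_standard_curve(points, gene: str = "") -> StandardCurve:
    """OLS of Ct on log10 quantity over >= 3 points with >= 3 distinct quantities."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise StandardCurveError("need >= 3 (log10 quantity, Ct) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise StandardCurveError("need >= 3 distinct quantities")
    if np.ptp(x) == 0:
        raise StandardCurveError("zero variance in quantity")
    res = stats.linregress(x, y)
    return StandardCurve(gene=gene, intercept_a=float(res.intercept),
                         slope_b=float(res.slope), r2=float(res.rvalue**2))


def relative_quantity(ct, curve: StandardCurve):
    """Invert the standard curve: quantity = 10^((ct - a)/b); decreasing in ct."""
    ct = np.asarray(ct, dtype=float)
    q = 10.0 ** ((ct - curve.intercept_a) / curve.slope_b)
    return float(q) if q.ndim == 0 else q


def normalize_to_reference(target_q, ref_q):
    """Relative expression = target quantity / reference quantity."""
    ref = np.asarray(ref_q, dtype=float)
    if np.any(ref <= 0):
        raise NormalizationError("reference quantity must be > 0")
    out = np.asarray(target_q, dtype=float) / ref
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ChipMeasurement:
    """One IP/input Ct pair from a pooled-liver ChIP-qPCR assay."""

    sample_pool: str
    antibody: str
    region: str
    time_h: float
    ct_ip: float
    ct_input: float
    input_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.antibody not in ANTIBODIES:
            raise ChipMeasurementError(f"antibody {self.antibody!r} not in {ANTIBODIES}")
        if self.region not in REGIONS:
            raise ChipMeasurementError(f"region {self.region!r} not in {REGIONS}")
        if not (0.0 < self.input_fraction < 1.0 or self.input_fraction == 1.0):
            raise ChipMeasurementError(
                f"input_fraction {self.input_fraction} outside (0, 1]"
            )
        for name in ("ct_ip", "ct_input"):
            ct = getattr(self, name)
            if not (0.0 < ct < 45.0):
                raise ChipMeasurementError(f"{name} {ct} outside (0, 45)")


def percent_input(m: ChipMeasurement) -> float:
    """ChIP enrichment as percent of (dilution-adjusted) input chromatin."""
    adj = m.ct_input + math.log2(m.input_fraction)
    return 100.0 * 2.0 ** (adj - m.ct_ip)


def percent_input_arrays(ct_ip, ct_input, input_fraction):
    """Vectorized percent-input for table-level computation."""
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    f = np.asarray(input_fraction, dtype=float)
    return 100.0 * f * 2.0 ** (ct_input - ct_ip)


def fold_over_igg(specific_pct, igg_pct):
    """Secondary ChIP statistic: specific-antibody enrichment over matched IgG."""
    igg = np.asarray(igg_pct, dtype=float)
    if np.any(igg <= 0):
        raise ChipMeasurementError("IgG enrichment must be > 0 for a fold ratio")
    out = np.asarray(specific_pct, dtype=float) / igg
    return float(out) if out.ndim == 0 else out
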