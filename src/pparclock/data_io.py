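"""Shared data model and tabular I/O for cross-sectional circadian timecourses.

The study design this package targets is a 2 x 2 factorial (maternal phenotype
{lean, obese} x post-weaning diet {control, HFD}) sampled every 4 h over 24 h,
with 3-5 animals per group per clock time.  Sampling is cross-sectional: each
animal contributes a single observation, so curves exist only at the group
level (mean +/- SEM per clock time).

Clock time is encoded as hours after midnight on [0, 24).  The light schedule
is 12:12 with lights-on at 6 AM, so Zeitgeber time is ZT = (time_h - 6) mod 24.
When a curve is laid out for interpolation or integration it is "unwrapped"
from the 6 AM anchor: the 2 AM sample becomes hour 26 so that times increase
strictly from 6 to 26.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MATERNAL_LEVELS = ("lean", "obese")
DIET_LEVELS = ("control", "HFD")
GROUPS = tuple((m, d) for m in MATERNAL_LEVELS for d in DIET_LEVELS)

#: clock hours sampled in the emulated design (stored on [0, 24))
SAMPLING_TIMES_H = (6.0, 10.0, 14.0, 18.0, 22.0, 2.0)

#: the anchor used to unwrap curves (lights-on, 6 AM)
ANCHOR_HOUR = 6.0

REQUIRED_COLUMNS = ("animal_id", "maternal", "diet", "time_h", "gene", "value")


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class RowValidationError(ValueError):
    """A data row violates an invariant; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GeneLookupError(KeyError):
    """Requested gene is not present in the dataset."""


def unwrap_times(times: Sequence[float], anchor: float = ANCHOR_HOUR) -> np.ndarray:
    """Map clock times onto [anchor, anchor + 24) so curves are orderable.

    With the default 6 AM anchor the 2 AM sample maps to hour 26.
    """
    t = np.asarray(times, dtype=float)
    return anchor + np.mod(t - anchor, 24.0)


def _validate_frame(df: pd.DataFrame, *, lines: Sequence[int] | None = None) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}'")

    def _line(i: int) -> int | None:
        return None if lines is None else lines[i]

    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for i, (_, row) in enumerate(out.iterrows()):
        try:
            t = float(row["time_h"])
        except (TypeError, ValueError):
            raise RowValidationError(
                f"unparseable time_h {row['time_h']!r}", _line(i)
            ) from None
        if not (0.0 <= t < 24.0) or not np.isfinite(t):
            raise RowValidationError(f"time_h {t} outside [0, 24)", _line(i))
        try:
            v = float(row["value"])
        except (TypeError, ValueError):
            raise RowValidationError(
                f"unparseable value {row['value']!r}", _line(i)
            ) from None
        if not np.isfinite(v) or v < 0:
            raise RowValidationError(f"value {v} must be finite and >= 0", _line(i))
        if row["maternal"] not in MATERNAL_LEVELS:
            raise RowValidationError(
                f"maternal {row['maternal']!r} not in {MATERNAL_LEVELS}", _line(i)
            )
        if row["diet"] not in DIET_LEVELS:
            raise RowValidationError(
                f"diet {row['diet']!r} not in {DIET_LEVELS}", _line(i)
            )
    out["time_h"] = out["time_h"].astype(float)
    out["value"] = out["value"].astype(float)
    out["animal_id"] = out["animal_id"].astype(str)
    out["gene"] = out["gene"].astype(str)
    return out


@dataclass
class TimecourseDataset:
    """Per-animal relative-expression observations, long format.

    ``df`` holds one row per observation with columns
    animal_id, maternal, diet, time_h, gene, value.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _validate_frame(self.df).reset_index(drop=True)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["gene"].unique()))

    @property
    def n_observations(self) -> int:
        return len(self.df)

    def design(self, gene: str | None = None) -> pd.DataFrame:
        """Replicate counts per (maternal, diet, time_h) cell.

        Returns a frame with one row per design cell and a column ``n``.
        """
        sub = self.df if gene is None else self.df[self.df["gene"] == gene]
        return (
            sub.groupby(["maternal", "diet", "time_h"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )

    def cell(self, gene: str, maternal: str, diet: str, time_h: float) -> np.ndarray:
        sub = self.df
        mask = (
            (sub["gene"] == gene)
            & (sub["maternal"] == maternal)
            & (sub["diet"] == diet)
            & (np.isclose(sub["time_h"], time_h))
        )
        return sub.loc[mask, "value"].to_numpy()


@dataclass
class GroupMeanCurve:
    """Mean +/- SEM timecourse of one gene in one (maternal, diet) group."""

    gene: str
    maternal: str
    diet: str
    times: np.ndarray  # clock hours, strictly increasing within [0, 24)
    means: np.ndarray
    sems: np.ndarray
    ns: np.ndarray
    singleton_cells: tuple[float, ...] = ()  # times with n = 1 (sem reported 0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sems = np.asarray(self.sems, dtype=float)
        self.ns = np.asarray(self.ns, dtype=int)
        if not (len(self.times) == len(self.means) == len(self.sems) == len(self.ns)):
            raise ValueError("times/means/sems/ns must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.sems < 0):
            raise ValueError("sems must be non-negative")

    def unwrapped(self, anchor: float = ANCHOR_HOUR):
        """Return (times, means, sems, ns) ordered from the anchor hour.

        The 2 AM point becomes hour 26 under the default 6 AM anchor.
        """
        t = unwrap_times(self.times, anchor)
        order = np.argsort(t)
        return t[order], self.means[order], self.sems[order], self.ns[order]


def read_timecourse(path: str | Path, dialect: str = "csv") -> TimecourseDataset:
    """Read a long-format timecourse table (CSV or TSV, header required)."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        rows = list(reader)
    df = pd.DataFrame(rows, columns=[h.strip() for h in header])
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    # data starts on physical line 2 (after the header)
    validated = _validate_frame(df, lines=list(range(2, 2 + len(df))))
    return TimecourseDataset(validated, provenance={"path": str(path)})


def write_timecourse(ds: TimecourseDataset, path: str | Path, dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    ds.df.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, sep=sep, index=False)


def group_means(ds: TimecourseDataset, gene: str) -> list[GroupMeanCurve]:
    """Per-(maternal, diet) mean/SEM curves for one gene.

    mean is the arithmetic mean, sem the sample SD (ddof=1) over sqrt(n); a
    cell with a single animal gets sem 0 and is flagged in
    ``singleton_cells``.  Times are sorted ascending within [0, 24).
    """
    if gene not in ds.genes:
        raise GeneLookupError(gene)
    sub = ds.df[ds.df["gene"] == gene]
    curves = []
    for maternal, diet in GROUPS:
        cell = sub[(sub["maternal"] == maternal) & (sub["diet"] == diet)]
        if cell.empty:
            continue
        g = cell.groupby("time_h")["value"]
        stats = g.agg(["mean", "std", "count"]).sort_index()
        n = stats["count"].to_numpy()
        sd = stats["std"].to_numpy()
        sem = np.where(n > 1, sd / np.sqrt(n), 0.0)
        singles = tuple(stats.index[n == 1])
        curves.append(
            GroupMeanCurve(
                gene=gene,
                maternal=maternal,
                diet=diet,
                times=stats.index.to_numpy(),
                means=stats["mean"].to_numpy(),
                sems=sem,
                ns=n,
                singleton_cells=singles,
            )
        )
    return curves


def group_mean_table(curves: Iterable[GroupMeanCurve]) -> pd.DataFrame:
    """Flatten curves to a table with mean, sem, n columns (write-ready)."""
    recs = []
    for c in curves:
        for t, m, s, n in zip(c.times, c.means, c.sems, c.ns):
            recs.append(
                dict(gene=c.gene, maternal=c.maternal, diet=c.diet,
                     time_h=t, mean=m, sem=s, n=n)
            )
    return pd.DataFrame(recs)
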