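"""Circadian timecourse statistics: trapezoidal 24-h AUC, per-timepoint t-tests,
2x2 factorial ANOVA and Student-Newman-Keuls letter groupings.

AUC is computed on group means (sampling is cross-sectional, so per-animal
AUCs do not exist) with a delta-method standard error from the per-time SEMs.
Curves are unwrapped from the 6 AM anchor (2 AM -> hour 26) and closed
periodically by appending the first point at +24 h, so the integral spans a
full 24 h.  Group comparisons of AUCs use Z contrasts on (auc, se_auc),
including the maternal x diet interaction contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .data_io import (ANCHOR_HOUR, GROUPS, GroupMeanCurve, TimecourseDataset,
                      group_means, unwrap_times)


class InsufficientReplicationError(ValueError):
    """A statistical test needs more replicates than the cell provides."""


class DesignError(ValueError):
    """A factorial cell is empty or the input violates the design."""


# ---------------------------------------------------------------------------
# trapezoidal AUC

def _trapezoid_weights(times: np.ndarray, closure: str) -> np.ndarray:
    """Per-point weights w_i such that AUC = sum w_i y_i."""
    t = np.asarray(times, dtype=float)
    m = len(t)
    w = np.zeros(m)
    gaps = np.diff(t)
    if closure == "periodic":
        wrap = (t[0] + 24.0) - t[-1]
        if wrap <= 0:
            raise ValueError("curve span exceeds one 24-h period")
        w[0] = (gaps[0] + wrap) / 2.0
        w[-1] = (gaps[-1] + wrap) / 2.0
        w[1:-1] = (gaps[:-1] + gaps[1:]) / 2.0
        # the closure point shares the first point's value, hence wrap/2 twice
    elif closure == "open":
        w[0] = gaps[0] / 2.0
        w[-1] = gaps[-1] / 2.0
        w[1:-1] = (gaps[:-1] + gaps[1:]) / 2.0
    else:
        raise ValueError(f"unknown closure {closure!r}")
    return w


def trapezoid_auc(times, values, closure: str = "periodic") -> float:
    """Trapezoidal-rule AUC over strictly increasing (unwrapped) times.

    ``periodic`` closure appends (t0 + 24, y0) so the span is a full 24 h;
    ``open`` integrates only the observed span.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 2 or len(t) != len(y):
        raise ValueError("need >= 2 (time, value) pairs of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing (unwrap first); "
                         "duplicates are not allowed")
    if closure == "periodic":
        t = np.append(t, t[0] + 24.0)
        y = np.append(y, y[0])
    elif closure != "open":
        raise ValueError(f"unknown closure {closure!r}")
    return float(np.trapezoid(y, t))


@dataclass
class AucRecord:
    gene: str
    maternal: str
    diet: str
    auc: float
    se_auc: float
    closure: str
    n_times: int
    se_available: bool = True


def auc_with_error(curve: GroupMeanCurve, closure: str = "periodic",
                   anchor: float = ANCHOR_HOUR) -> AucRecord:
    """AUC of the mean curve with a delta-method SE from per-time SEMs.

    se_auc = sqrt(sum w_i^2 sem_i^2) with w_i the trapezoid weight of point i,
    assuming independence across cross-sectional timepoints.  Curves with any
    single-animal cell get ``se_available = False`` (their SEM is undefined).
    """
    t, m, s, n = curve.unwrapped(anchor)
    if len(t) < 4:
        raise ValueError("AUC requires >= 4 distinct timepoints")
    w = _trapezoid_weights(t, closure)
    auc = trapezoid_auc(t, m, closure)
    se = float(np.sqrt(np.sum(w**2 * s**2)))
    return AucRecord(gene=curve.gene, maternal=curve.maternal, diet=curve.diet,
                     auc=auc, se_auc=se, closure=closure, n_times=len(t),
                     se_available=bool(np.all(n > 1)))


# ---------------------------------------------------------------------------
# per-timepoint lean vs obese comparison

@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    significant: bool  # at the conventional 0.05 threshold


def timepoint_ttest(ds: TimecourseDataset, gene: str, time_h: float,
                    diet: str) -> TTestResult:
    """Pooled-variance two-tailed t-test, lean vs obese, at one clock time."""
    a = ds.cell(gene, "lean", diet, time_h)
    b = ds.cell(gene, "obese", diet, time_h)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicationError(
            f"need n >= 2 per cell (got {len(a)} lean, {len(b)} obese)")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), df=len(a) + len(b) - 2, p=float(p),
                       significant=bool(p < 0.05))


# ---------------------------------------------------------------------------
# factorial ANOVA + SNK letters

@dataclass
class AnovaTable:
    effects: dict[str, dict[str, float]]  # name -> {F, df_num, df_den, p}
    posthoc: dict[str, str] | None        # group label -> letters, if interaction
    mse: float
    df_resid: int

    def p(self, effect: str) -> float:
        return self.effects[effect]["p"]


def _group_label(maternal: str, diet: str) -> str:
    return f"{maternal}-{diet}"


def two_way_anova(df: pd.DataFrame, value_col: str = "value",
                  alpha: float = 0.05) -> AnovaTable:
    """Fixed-effects 2x2 ANOVA (Type II SS) on maternal x diet cells.

    ``df`` needs columns maternal, diet and ``value_col`` with >= 2
    replicates per cell.  When the interaction is significant at ``alpha``,
    a one-way ANOVA across the four groups is followed by SNK letter
    assignment.
    """
    for m, d in GROUPS:
        cell = df[(df["maternal"] == m) & (df["diet"] == d)]
        if len(cell) < 2:
            raise DesignError(f"cell ({m}, {d}) has {len(cell)} < 2 replicates")
    work = df.loc[:, ["maternal", "diet", value_col]].rename(
        columns={value_col: "y"})
    fit = ols("y ~ C(maternal) * C(diet)", data=work).fit()
    tab = anova_lm(fit, typ=2)
    key = {"maternal": "C(maternal)", "diet": "C(diet)",
           "interaction": "C(maternal):C(diet)"}
    df_resid = int(tab.loc["Residual", "df"])
    mse = float(tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"])
    effects = {}
    for name, row in key.items():
        effects[name] = dict(F=float(tab.loc[row, "F"]),
                             df_num=int(tab.loc[row, "df"]),
                             df_den=df_resid,
                             p=float(tab.loc[row, "PR(>F)"]))
    posthoc = None
    if effects["interaction"]["p"] < alpha:
        means = {_group_label(m, d): work[(work["maternal"] == m)
                                          & (work["diet"] == d)]["y"].mean()
                 for m, d in GROUPS}
        ns = {_group_label(m, d): int(((work["maternal"] == m)
                                       & (work["diet"] == d)).sum())
              for m, d in GROUPS}
        posthoc = snk_posthoc(means, mse, df_resid, ns, alpha=alpha)
    return AnovaTable(effects=effects, posthoc=posthoc, mse=mse,
                      df_resid=df_resid)


def snk_marked_intervals(ordered_means: np.ndarray, ordered_ns: np.ndarray,
                         mse: float, df: int,
                         alpha: float = 0.05) -> list[tuple[int, int]]:
    """Student-Newman-Keuls recursion on means sorted descending.

    Returns the intervals [i, j] (inclusive, in sorted order) declared
    homogeneous.  The observed studentized range q = (m_i - m_j)/SE with
    SE = sqrt(mse/2 * (1/n_i + 1/n_j)) is compared against the critical value
    for the span r = j - i + 1; a non-significant range stops the recursion
    below it.
    """
    if df <= 0:
        raise ValueError("residual df must be > 0")
    if mse < 0:
        raise ValueError("mse must be >= 0")
    homogeneous: list[tuple[int, int]] = []

    def rec(i: int, j: int) -> None:
        if i >= j:
            return
        se = np.sqrt(mse / 2.0 * (1.0 / ordered_ns[i] + 1.0 / ordered_ns[j]))
        span = j - i + 1
        if se == 0:
            significant = ordered_means[i] > ordered_means[j]
        else:
            q_obs = (ordered_means[i] - ordered_means[j]) / se
            q_crit = studentized_range.ppf(1.0 - alpha, span, df)
            significant = q_obs > q_crit
        if not significant:
            homogeneous.append((i, j))
            return
        rec(i, j - 1)
        rec(i + 1, j)

    rec(0, len(ordered_means) - 1)
    return homogeneous


def _letters_from_intervals(n: int, intervals: list[tuple[int, int]]) -> list[str]:
    """Compact letter display from homogeneous intervals over sorted means."""
    # maximal intervals only (drop those nested in another)
    iv = sorted(set(intervals))
    maximal = [a for a in iv
               if not any(b != a and b[0] <= a[0] and a[1] <= b[1] for b in iv)]
    # singletons for means covered by no interval
    covered = np.zeros(n, dtype=bool)
    for i, j in maximal:
        covered[i:j + 1] = True
    for i in range(n):
        if not covered[i]:
            maximal.append((i, i))
    maximal.sort()
    letters = [""] * n
    for idx, (i, j) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for k in range(i, j + 1):
            letters[k] += ch
    return letters


def snk_posthoc(means: dict[str, float], mse: float, df: int,
                ns: dict[str, int], alpha: float = 0.05) -> dict[str, str]:
    """SNK letter groupings: groups sharing a letter are not significantly
    different; letter 'a' goes to the interval containing the largest mean."""
    labels = sorted(means, key=lambda k: -means[k])
    m = np.array([means[k] for k in labels])
    n = np.array([ns[k] for k in labels], dtype=float)
    intervals = snk_marked_intervals(m, n, mse, df, alpha=alpha)
    letters = _letters_from_intervals(len(labels), intervals)
    return dict(zip(labels, letters))


# ---------------------------------------------------------------------------
# Table-1-style AUC summary with Z contrasts

def auc_contrasts(records: dict[tuple[str, str], AucRecord]) -> dict[str, dict[str, float]]:
    """Z tests on AUC effects from per-group (auc, se): maternal, diet, interaction.

    maternal = mean(obese) - mean(lean); diet = mean(HFD) - mean(control);
    interaction = (HFD effect in obese) - (HFD effect in lean).
    """
    need = set(GROUPS)
    if set(records) != need:
        raise DesignError(f"need AUC records for all four groups, got {set(records)}")
    a = {g: records[g].auc for g in GROUPS}
    v = {g: records[g].se_auc**2 for g in GROUPS}
    lc, lh = ("lean", "control"), ("lean", "HFD")
    oc, oh = ("obese", "control"), ("obese", "HFD")
    out = {}
    contrasts = {
        "maternal": ({oc: 0.5, oh: 0.5, lc: -0.5, lh: -0.5}),
        "diet": ({lh: 0.5, oh: 0.5, lc: -0.5, oc: -0.5}),
        "interaction": ({oh: 1.0, oc: -1.0, lh: -1.0, lc: 1.0}),
    }
    for name, w in contrasts.items():
        est = sum(w[g] * a[g] for g in GROUPS)
        se = np.sqrt(sum(w[g]**2 * v[g] for g in GROUPS))
        z = est / se if se > 0 else np.inf * np.sign(est or 1.0)
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        out[name] = dict(estimate=float(est), se=float(se), z=float(z), p=float(p))
    return out


def _z_letters(records: dict[tuple[str, str], AucRecord],
               alpha: float = 0.05) -> dict[str, str]:
    """Letter groupings of AUCs from pairwise Z tests (delta-method SEs)."""
    labels = sorted(records, key=lambda g: -records[g].auc)
    m = np.array([records[g].auc for g in labels])
    se = np.array([records[g].se_auc for g in labels])
    k = len(labels)
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            denom = np.hypot(se[i], se[j])
            if denom == 0:
                sig[i, j] = m[i] != m[j]
            else:
                z = (m[i] - m[j]) / denom
                sig[i, j] = 2.0 * stats.norm.sf(abs(z)) < alpha
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and not any(sig[a, b] for a in range(i, j + 2)
                                    for b in range(a + 1, j + 2)):
            j += 1
        intervals.append((i, j))
    letters = _letters_from_intervals(k, intervals)
    return {_group_label(*g): L for g, L in zip(labels, letters)}


def auc_table(ds: TimecourseDataset, genes: list[str] | None = None,
              closure: str = "periodic", alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene 24-h AUC summary across the four groups, Table-1 layout.

    Columns: gene, then auc/se per group, the three effect p-values from Z
    contrasts, and letter groupings when the interaction is significant.
    """
    genes = list(genes) if genes is not None else list(ds.genes)
    rows = []
    for gene in genes:
        curves = {(c.maternal, c.diet): c for c in group_means(ds, gene)}
        recs = {g: auc_with_error(curves[g], closure=closure) for g in curves}
        eff = auc_contrasts(recs)
        letters = (_z_letters(recs, alpha=alpha)
                   if eff["interaction"]["p"] < alpha else {})
        row = {"gene": gene}
        for g in GROUPS:
            lab = _group_label(*g)
            row[f"auc_{lab}"] = recs[g].auc
            row[f"se_{lab}"] = recs[g].se_auc
            row[f"letters_{lab}"] = letters.get(lab, "")
        for name in ("interaction", "maternal", "diet"):
            row[f"p_{name}"] = eff[name]["p"]
        rows.append(row)
    return pd.DataFrame(rows)
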