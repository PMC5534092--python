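"""Cohort statistics for per-subject decomposition tables.

Implements the analysis battery applied to the three study groups (LAD-MI,
RCA-MI, controls): group summaries as mean ± SE, classical one-way ANOVA with
Tukey–Kramer post-hoc pairwise comparisons (equal-variance form; group sizes
may differ), pooled-variance unpaired t-tests, Spearman rank correlation
reported alongside an ordinary least-squares line, and observer-variability
bias ± SD of paired re-measurements.

The Spearman p-value uses the exact permutation distribution for n <= 10 and
the classical t approximation above that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import LVDecompError, UndefinedCorrelationError

__all__ = [
    "GroupSummary",
    "PairwiseComparison",
    "ComparisonReport",
    "CorrelationReport",
    "VariabilityReport",
    "summarize_groups",
    "anova_tukey",
    "ttest_unpaired",
    "spearman_with_line",
    "observer_variability",
    "significance_marker",
]

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_marker(p: float) -> str:
    """'*' / '**' / '***' at the 0.05 / 0.01 / 0.001 thresholds, else ''."""
    for level, marker in SIGNIFICANCE_LEVELS:
        if p < level:
            return marker
    return ""


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    se: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float
    marker: str


@dataclass
class ComparisonReport:
    variable: str
    summaries: list[GroupSummary]
    anova_f: float
    anova_p: float
    pairwise: list[PairwiseComparison]


@dataclass(frozen=True)
class CorrelationReport:
    spearman_r: float
    spearman_p: float
    ols_slope: float
    ols_intercept: float
    n: int


@dataclass(frozen=True)
class VariabilityReport:
    bias: float
    sd: float
    n: int


def _group_arrays(table: pd.DataFrame, variable: str, group_col: str = "group"):
    if variable not in table.columns:
        raise LVDecompError(f"unknown variable {variable!r}")
    if group_col not in table.columns:
        raise LVDecompError(f"table has no {group_col!r} column")
    out = {}
    for g, sub in table.groupby(group_col, sort=True):
        vals = np.asarray(sub[variable], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[str(g)] = vals
    return out


def summarize_groups(
    table: pd.DataFrame, variable: str, group_col: str = "group"
) -> list[GroupSummary]:
    """Per-group arithmetic mean and SE (= sample SD / sqrt(n))."""
    groups = _group_arrays(table, variable, group_col)
    summaries = []
    for g, vals in groups.items():
        if len(vals) < 2:
            raise LVDecompError(f"group {g!r} needs >= 2 subjects, got {len(vals)}")
        summaries.append(
            GroupSummary(
                group=g,
                n=len(vals),
                mean=float(np.mean(vals)),
                se=float(np.std(vals, ddof=1) / np.sqrt(len(vals))),
            )
        )
    return summaries


def anova_tukey(
    table: pd.DataFrame, variable: str, group_col: str = "group"
) -> ComparisonReport:
    """Classical one-way ANOVA with Tukey–Kramer adjusted pairwise p-values.

    The Tukey–Kramer form of the studentized-range test accommodates unequal
    group sizes. Markers follow the 0.05/0.01/0.001 convention.
    """
    groups = _group_arrays(table, variable, group_col)
    if len(groups) < 3:
        raise LVDecompError(
            f"ANOVA/Tukey requires >= 3 groups, got {len(groups)}; "
            "use ttest_unpaired for two groups"
        )
    names = list(groups)
    samples = [groups[g] for g in names]
    if any(len(s) < 2 for s in samples):
        raise LVDecompError("each group needs >= 2 subjects")
    if np.ptp(np.concatenate(samples)) == 0:
        f_stat, f_p = 0.0, 1.0  # all observations identical
    else:
        f_stat, f_p = sps.f_oneway(*samples)
    tukey = sps.tukey_hsd(*samples)
    pairwise = []
    for i, j in itertools.combinations(range(len(names)), 2):
        p_adj = float(tukey.pvalue[i, j])
        pairwise.append(
            PairwiseComparison(
                group_a=names[i],
                group_b=names[j],
                mean_difference=float(np.mean(samples[i]) - np.mean(samples[j])),
                p_adjusted=p_adj,
                marker=significance_marker(p_adj),
            )
        )
    return ComparisonReport(
        variable=variable,
        summaries=summarize_groups(table, variable, group_col),
        anova_f=float(f_stat),
        anova_p=float(f_p),
        pairwise=pairwise,
    )


def ttest_unpaired(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided unpaired t-test with pooled (equal) variance.

    Degenerate identical zero-variance samples return (0, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise LVDecompError("each sample needs n >= 2")
    if np.std(x) == 0 and np.std(y) == 0 and np.mean(x) == np.mean(y):
        return 0.0, 1.0
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n, ties allowed).

    Enumerates all n! pairings of the (average) ranks in numpy chunks.
    """
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
    target = abs(rho_obs) * denom - 1e-12
    count = 0
    total = 0
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 200_000))
        if not chunk:
            break
        idx = np.array(chunk, dtype=np.intp)
        stat = np.abs(ry_c[idx] @ rx_c)
        count += int(np.sum(stat >= target))
        total += len(chunk)
    return count / total


def spearman_with_line(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Spearman rho (average-rank ties) with an OLS line fitted to the raw
    values, mirroring the convention of reporting a rank correlation next to a
    linear regression equation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise LVDecompError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise LVDecompError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in one variable")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _exact_spearman_p(rx, ry, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    fit = sps.linregress(x, y)
    return CorrelationReport(
        spearman_r=rho,
        spearman_p=float(p),
        ols_slope=float(fit.slope),
        ols_intercept=float(fit.intercept),
        n=n,
    )


def observer_variability(
    values_a: Sequence[float], values_b: Sequence[float]
) -> VariabilityReport:
    """Bias (mean of a − b) ± SD of the paired differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise LVDecompError("paired measurement sequences must have equal length")
    d = a - b
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return VariabilityReport(bias=float(np.mean(d)), sd=sd, n=len(d))
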