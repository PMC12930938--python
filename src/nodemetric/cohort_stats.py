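"""Descriptive statistics and group-comparison tests for cohort tables.

Continuous variables are summarized as median and quartiles (linear
interpolation between order statistics — the common statistical-software
default; the convention is configurable via ``quartile_method``) and
compared with the Mann-Whitney U test. Categorical variables are summarized
as counts/percentages and compared with Fisher's exact test (2x2 tables
with any expected count below 5) or Pearson's chi-square test otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "median_iqr",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "chi_square_test",
    "summarize_groups",
]


@dataclass
class GroupSummary:
    """One summary-table row: a variable compared across two groups."""

    metric: str
    kind: str  # "continuous" | "categorical"
    per_group: dict = field(default_factory=dict)
    p_value: float | None = None
    test_used: str | None = None
    flags: tuple[str, ...] = ()


def median_iqr(values, quartile_method: str = "linear") -> tuple[float, float, float]:
    """(median, q1, q3) of a non-empty sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr of empty input")
    med, q1, q3 = np.percentile(v, [50, 25, 75], method=quartile_method)
    return float(med), float(q1), float(q3)


def mann_whitney_u(group_a, group_b, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (for group_a) with two-sided p.

    ``method='auto'`` uses exact enumeration when the pooled sample has at
    most 12 observations and no ties, else the tie- and continuity-corrected
    normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sidedness by probability-mass summation (all tables at most as
    probable as the observed one). A zero margin makes the test degenerate:
    p = 1 is returned with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("fisher_exact_2x2 needs a 2x2 table of non-negative integers")
        t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin: Fisher test is degenerate, p = 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square statistic and p for an r x c count table.

    Uses (r-1)(c-1) degrees of freedom, no continuity correction. Emits a
    warning when any expected count falls below 5 (Fisher advised).
    """
    t = np.asarray(table, dtype=float)
    if t.sum() == 0:
        raise ValueError("chi-square of an all-zero table")
    stat, p, _, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        warnings.warn(
            "expected count below 5; Fisher's exact test is advised",
            stacklevel=2,
        )
    return float(stat), float(p)


def summarize_groups(
    frame: pd.DataFrame,
    group_col: str,
    continuous: list[str] = (),
    categorical: list[str] = (),
    quartile_method: str = "linear",
) -> list[GroupSummary]:
    """Two-group summary table (structure of a cohort-characteristics table).

    ``frame`` must contain exactly two group levels in ``group_col``.
    Continuous variables get per-group median (q1, q3) and a Mann-Whitney p;
    categorical variables get per-group counts/percentages and Fisher or
    chi-square p (Fisher for 2x2 tables with any expected count < 5).
    """
    levels = sorted(frame[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {levels}")
    out: list[GroupSummary] = []
    for var in continuous:
        per_group, samples = {}, []
        for lv in levels:
            vals = frame.loc[frame[group_col] == lv, var].dropna().to_numpy(float)
            per_group[lv] = median_iqr(vals, quartile_method) if vals.size else None
            samples.append(vals)
        flags = ()
        if samples[0].size and samples[1].size:
            _, p = mann_whitney_u(samples[0], samples[1])
            test = "mann_whitney"
        else:
            p, test, flags = None, None, ("insufficient-data",)
        out.append(GroupSummary(var, "continuous", per_group, p, test, flags))
    for var in categorical:
        sub = frame[[group_col, var]].dropna()
        ct = pd.crosstab(sub[var], sub[group_col])
        per_group = {
            lv: {
                str(cat): (int(c), 100.0 * c / max(ct[lv].sum(), 1))
                for cat, c in ct[lv].items()
            }
            for lv in levels
            if lv in ct.columns
        }
        table = ct.to_numpy()
        flags = ()
        if table.size == 0 or table.sum() == 0 or min(table.shape) < 2:
            p, test, flags = None, None, ("degenerate-table",)
        else:
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if table.shape == (2, 2) and (expected < 5).any():
                p, test = fisher_exact_2x2(table), "fisher"
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p = chi_square_test(table)
                test = "chi_square"
        out.append(GroupSummary(var, "categorical", per_group, p, test, flags))
    return out
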