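"""Descriptive cohort comparison of identified cases vs. non-cases, with the
study's test dispatch and the Breslow-Day odds-ratio homogeneity check.

Variables are compared between groups with the test named in a per-variable
spec (chi-square with Yates correction for 2x2, exact Fisher for sparse
R x C, Welch t, or Mann-Whitney U) — dispatch is configured, not
auto-detected, mirroring how registry tables annotate each row with its
test.  Stratified 2x2 associations (e.g. physical health x case status
across age groups) are checked for odds-ratio homogeneity with the
Breslow-Day test (optional Tarone adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableSpec",
    "default_variable_specs",
    "describe",
    "test_association",
    "breslow_day",
]

TESTS = ("chi-square", "fisher", "t-test", "mann-whitney")


@dataclass(frozen=True)
class VariableSpec:
    """How one variable is summarized and tested."""

    name: str
    kind: str  # "categorical" | "continuous"
    test: str  # one of TESTS

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"kind must be categorical/continuous, got {self.kind!r}")
        if self.test not in TESTS:
            raise ValueError(f"test must be one of {TESTS}, got {self.test!r}")
        if self.kind == "continuous" and self.test in ("chi-square", "fisher"):
            raise ValueError(f"{self.test} requires a categorical variable")
        if self.kind == "categorical" and self.test in ("t-test", "mann-whitney"):
            raise ValueError(f"{self.test} requires a continuous variable")


def default_variable_specs() -> list[VariableSpec]:
    """The demographic-table dispatch used for case/non-case comparison."""
    return [
        VariableSpec("sex", "categorical", "chi-square"),
        VariableSpec("age", "continuous", "mann-whitney"),
        VariableSpec("race", "categorical", "fisher"),
        VariableSpec("education_years", "continuous", "t-test"),
        VariableSpec("marital_status", "categorical", "fisher"),
        VariableSpec("physical_health_flag", "categorical", "chi-square"),
        VariableSpec("mental_health_flag", "categorical", "chi-square"),
        VariableSpec("crisis_flag", "categorical", "chi-square"),
        VariableSpec("rucc", "continuous", "t-test"),
    ]


_FISHER_ENUM_LIMIT = 200_000


def _fisher_rxc(table: np.ndarray, rng=None) -> float:
    """Exact R x C Fisher p-value by enumeration over tables with the
    observed margins; seeded Monte-Carlo approximation (sampling from the
    fixed-margin `random_table` null, as R's ``simulate.p.value`` does) when
    the enumeration space exceeds ~2e5 tables."""
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    space = np.prod([float(min(r, col_sums[0]) + 1) for r in row_sums])
    for c in col_sums[1:-1]:
        space *= float(min(row_sums.max(), c) + 1)
    if space > _FISHER_ENUM_LIMIT:
        method = stats.MonteCarloMethod(
            n_resamples=19_999, rng=np.random.default_rng(rng if rng is not None else 0)
        )
        return float(stats.fisher_exact(table, method=method).pvalue)

    from math import lgamma

    log_norm = sum(lgamma(r + 1) for r in row_sums) + sum(
        lgamma(c + 1) for c in col_sums
    ) - lgamma(table.sum() + 1)

    def log_pmf(t: np.ndarray) -> float:
        return log_norm - sum(lgamma(x + 1) for x in t.ravel())

    lp_obs = log_pmf(table)
    n_rows, n_cols = table.shape
    total = 0.0

    def recurse(partial: list[list[int]], row: int) -> None:
        nonlocal total
        if row == n_rows - 1:
            last = col_sums - np.sum(partial, axis=0) if partial else col_sums
            if (last >= 0).all() and last.sum() == row_sums[-1]:
                t = np.array(partial + [last.tolist()])
                lp = log_pmf(t)
                if lp <= lp_obs + 1e-9:
                    total += np.exp(lp)
            return

        def cells(remaining: int, col: int, current: list[int]) -> None:
            free = col_sums - (np.sum(partial, axis=0) if partial else 0)
            if col == n_cols - 1:
                if remaining <= free[col]:
                    recurse(partial + [current + [remaining]], row + 1)
                return
            for x in range(min(remaining, int(free[col])) + 1):
                cells(remaining - x, col + 1, current + [x])

        cells(int(row_sums[row]), 0, [])

    recurse([], 0)
    return float(min(total, 1.0))


def _contingency(df: pd.DataFrame, var: str, group: str) -> pd.DataFrame:
    """Levels x groups count table; missing/unknown levels are retained as
    explicit categories, never dropped."""
    col = df[var]
    if col.isna().any():
        col = col.astype(object).where(col.notna(), "Unknown or missing")
    table = pd.crosstab(col, df[group])
    return table


def test_association(
    table_or_samples,
    test: str,
    *,
    yates: bool = True,
    rng: np.random.Generator | int | None = None,
):
    """Dispatch a two-group association test; returns (statistic, p-value).

    ``chi-square``: contingency table; Yates continuity correction applied
    to 2x2 by default.  ``fisher``: exact R x C test (scipy's network
    algorithm).  ``t-test``: Welch two-sample t on a (sample1, sample2)
    pair.  ``mann-whitney``: two-sided U test (exact for small samples,
    normal approximation otherwise, scipy's default policy).
    """
    if test == "chi-square":
        table = np.asarray(table_or_samples, dtype=float)
        if table.ndim != 2 or min(table.shape) < 2:
            raise ValueError("chi-square requires an R x C table with R, C >= 2")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("chi-square table has a zero margin")
        correct = yates and table.shape == (2, 2)
        res = stats.chi2_contingency(table, correction=correct)
        return float(res[0]), float(res[1])
    if test == "fisher":
        table = np.asarray(table_or_samples, dtype=int)
        if table.ndim != 2 or min(table.shape) < 2:
            raise ValueError("fisher requires an R x C table with R, C >= 2")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("fisher table has a zero margin")
        if table.shape == (2, 2):
            res = stats.fisher_exact(table)
            return float(res.statistic), float(res.pvalue)
        p = _fisher_rxc(table, rng)
        return float("nan"), p
    if test == "t-test":
        a, b = (np.asarray(s, dtype=float) for s in table_or_samples)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test requires >= 2 observations per group")
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "mann-whitney":
        a, b = (np.asarray(s, dtype=float) for s in table_or_samples)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("mann-whitney requires non-empty samples")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def describe(
    df: pd.DataFrame,
    group: str,
    specs: Sequence[VariableSpec] | None = None,
    *,
    yates: bool = True,
) -> pd.DataFrame:
    """Comparison table: per-variable counts/percentages (categorical,
    column-wise within group) or mean/SD (continuous) per group and overall,
    with the configured test's statistic and p-value on the first row of
    each variable block."""
    specs = list(specs) if specs is not None else default_variable_specs()
    groups = sorted(df[group].dropna().unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"group column {group!r} must have exactly 2 levels")
    for g in groups:
        if (df[group] == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")

    rows = []
    for spec in specs:
        if spec.kind == "categorical":
            table = _contingency(df, spec.name, group)
            table = table.reindex(columns=groups, fill_value=0)
            stat, p = test_association(table.values, spec.test, yates=yates)
            totals = table.sum(axis=0)
            overall = table.sum(axis=1)
            for j, level in enumerate(table.index):
                row = {
                    "variable": spec.name,
                    "level": str(level),
                    "test": spec.test,
                    "statistic": stat if j == 0 else np.nan,
                    "p_value": p if j == 0 else np.nan,
                }
                for g in groups:
                    n = int(table.loc[level, g])
                    row[f"{g}_n"] = n
                    row[f"{g}_pct"] = 100.0 * n / totals[g] if totals[g] else np.nan
                row["overall_n"] = int(overall[level])
                row["overall_pct"] = 100.0 * overall[level] / overall.sum()
                rows.append(row)
        else:
            samples = [
                df.loc[df[group] == g, spec.name].dropna().astype(float) for g in groups
            ]
            stat, p = test_association(samples, spec.test)
            row = {
                "variable": spec.name,
                "level": "mean (SD)",
                "test": spec.test,
                "statistic": stat,
                "p_value": p,
            }
            for g, s in zip(groups, samples):
                row[f"{g}_mean"] = float(s.mean())
                row[f"{g}_sd"] = float(s.std(ddof=1))
            pooled = df[spec.name].dropna().astype(float)
            row["overall_mean"] = float(pooled.mean())
            row["overall_sd"] = float(pooled.std(ddof=1))
            rows.append(row)
    return pd.DataFrame(rows)


def breslow_day(
    strata: Sequence[np.ndarray] | np.ndarray,
    *,
    tarone: bool = False,
) -> tuple[float, float]:
    """Breslow-Day homogeneity test of odds ratios across 2x2 strata.

    The statistic sums, over strata, the squared deviation of the exposed
    case cell from its expectation under the Mantel-Haenszel common odds
    ratio, scaled by the asymptotic variance; chi-square with K-1 degrees of
    freedom.  ``tarone=True`` applies the Tarone correction.  Returns
    (statistic, p-value).
    """
    tables = [np.asarray(t, dtype=float) for t in strata]
    if len(tables) < 2:
        raise ValueError("Breslow-Day requires at least 2 strata")
    for k, t in enumerate(tables):
        if t.shape != (2, 2):
            raise ValueError(f"stratum {k} is not a 2x2 table")
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            raise ValueError(
                f"stratum {k} has a zero margin; collapse or drop degenerate strata"
            )

    from statsmodels.stats.contingency_tables import StratifiedTable

    # statsmodels expects a 2 x 2 x K array
    arr = np.stack(tables, axis=-1)
    res = StratifiedTable(arr).test_equal_odds(adjust=tarone)
    return float(res.statistic), float(res.pvalue)
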