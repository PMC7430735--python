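"""Descriptive stage: outcome distribution, zero share, overdispersion,
and category-wise death percentages with Pearson chi-square tests.

The association test cross-tabulates each categorical covariate against the
binary indicator "mother experienced at least one under-five death": an
r x 2 table of (deaths, no-deaths) counts per category, tested with the
standard Pearson statistic (df = r - 1; no continuity correction by
default, optional Yates flag for 2 x 2 tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (presentation rounding for percents)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class OutcomeSummary:
    """Distribution of per-mother death counts."""

    n: int
    n_zero: int
    percent_zero: float
    mean: float
    variance: float
    histogram: dict

    @property
    def overdispersed(self) -> bool:
        return self.variance > self.mean


def summarize_outcome(y) -> OutcomeSummary:
    """Exact counts, zero share, sample mean/variance (denominator n-1)."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty outcome vector")
    n = int(y.size)
    n_zero = int(np.sum(y == 0))
    var = float(np.var(y, ddof=1)) if n > 1 else 0.0
    vals, counts = np.unique(y, return_counts=True)
    return OutcomeSummary(
        n=n,
        n_zero=n_zero,
        percent_zero=100.0 * n_zero / n,
        mean=float(np.mean(y)),
        variance=var,
        histogram={int(v): int(c) for v, c in zip(vals, counts)},
    )


@dataclass
class ContingencyTable:
    """Category x (deaths, no-deaths) counts for one covariate.

    rows: (category label, mothers with >=1 death, total mothers).  The
    percent column is 100 * deaths / total; the chi-square test is Pearson
    on the r x 2 (deaths, no-deaths) layout.
    """

    variable: str
    rows: list  # of (label, deaths, total)
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None

    def __post_init__(self):
        for label, deaths, total in self.rows:
            if deaths < 0 or total < 0 or deaths > total:
                raise ValueError(
                    f"{self.variable}/{label}: need 0 <= deaths <= total, "
                    f"got {deaths}/{total}"
                )

    @property
    def labels(self) -> list:
        return [r[0] for r in self.rows]

    def percents(self, decimals: int = 1) -> list:
        """Presentation percents, rounded half away from zero."""
        out = []
        for _, deaths, total in self.rows:
            if total == 0:
                out.append(float("nan"))
            else:
                out.append(round_half_up(100.0 * deaths / total, decimals))
        return out

    def counts_matrix(self) -> np.ndarray:
        return np.array([[d, t - d] for _, d, t in self.rows], dtype=float)


def percent_table(table: ContingencyTable, decimals: int = 1) -> pd.DataFrame:
    """Table with the percent-of-deaths column filled per category."""
    if any(t == 0 for _, _, t in table.rows):
        raise ValueError(f"{table.variable}: zero total in a category; "
                         "percent undefined")
    return pd.DataFrame(
        {
            "variable": table.variable,
            "category": table.labels,
            "deaths": [d for _, d, _ in table.rows],
            "total": [t for _, _, t in table.rows],
            "percent": table.percents(decimals),
        }
    )


def chi_square(counts, yates: bool = False):
    """Pearson chi-square for an r x 2 (deaths, no-deaths) table.

    Returns (chi2, df, p_value) with df = r - 1.  All expected cells must
    be positive; merge sparse categories otherwise.  ``yates`` applies the
    continuity correction (2 x 2 tables only).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
        raise ValueError("expected an r x 2 count table with r >= 2")
    expected = stats.contingency.expected_freq(counts)
    if np.any(expected <= 0):
        raise ValueError("a cell has zero expected count; merge categories "
                         "before testing")
    if yates and counts.shape[0] != 2:
        raise ValueError("Yates correction applies to 2 x 2 tables only")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=yates)
    return float(chi2), int(df), float(p)


def association_test(table: ContingencyTable, yates: bool = False) -> ContingencyTable:
    """Return a copy of the table with the Pearson test results filled in."""
    chi2, df, p = chi_square(table.counts_matrix(), yates=yates)
    return ContingencyTable(table.variable, list(table.rows), chi2, df, p)


def crosstab_from_data(df: pd.DataFrame, variable: str,
                       outcome: str = "y") -> ContingencyTable:
    """Build a (deaths, total) table for one covariate from mother-level data."""
    dead = df[outcome] > 0
    g = df.groupby(variable, observed=True, sort=False)
    rows = [(str(label), int(dead[idx].sum()), int(len(idx)))
            for label, idx in g.groups.items()]
    return ContingencyTable(variable, rows)


def describe(df: pd.DataFrame, covariates, outcome: str = "y"):
    """OutcomeSummary plus tested contingency tables for the given covariates."""
    summary = summarize_outcome(df[outcome].to_numpy())
    tables = [association_test(crosstab_from_data(df, v, outcome))
              for v in covariates]
    return summary, tables
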