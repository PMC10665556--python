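"""Baseline (Table-1-style) cohort comparisons.

Pearson chi-squared tests (df=1, no continuity correction) for
dichotomous traits from 2x2 counts, and two-sample t-tests recomputed
from printed summary statistics (mean, SD, n) for continuous traits.
Fisher's exact test is provided as a utility, not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TwoByTwo:
    """2x2 count table: rows = groups, columns = trait yes/no."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("group1", "group2")
    col_labels: tuple = ("yes", "no")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class SummaryPair:
    """Two-group summary statistics for a continuous trait."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def __post_init__(self) -> None:
        if self.sd_a < 0 or self.sd_b < 0:
            raise ValueError("SD must be non-negative")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("need n >= 2 per group")


def chisq_2x2(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-squared, df=1, no Yates correction, two-sided p."""
    tab = t.table
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    res = stats.chi2_contingency(tab, correction=False)
    return float(res.statistic), float(res.pvalue)


def fisher_2x2(t: TwoByTwo) -> tuple[float, float]:
    """Fisher's exact test (utility; not the default for Table-1 traits)."""
    odds, p = stats.fisher_exact(t.table)
    return float(odds), float(p)


def t_from_summaries(s: SummaryPair, mode: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test from summary statistics.

    ``mode="welch"`` (default) or ``"pooled"``. Degenerate input with
    zero SD in both groups and equal means returns (0, 1).
    """
    if s.sd_a == 0 and s.sd_b == 0:
        if s.mean_a == s.mean_b:
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    if mode not in ("welch", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    t, p = stats.ttest_ind_from_stats(
        s.mean_a, s.sd_a, s.n_a, s.mean_b, s.sd_b, s.n_b,
        equal_var=(mode == "pooled"),
    )
    return float(t), float(p)


def table1(rows: pd.DataFrame, mode: str = "welch") -> pd.DataFrame:
    """Run a batch of baseline comparisons from a tidy input table.

    Each row describes one comparison. Columns: ``label``, ``kind``
    ("dichotomous" or "continuous"); for dichotomous rows ``a b c d``;
    for continuous rows ``mean_a sd_a n_a mean_b sd_b n_b``.
    """
    out = []
    for r in rows.itertuples(index=False):
        if r.kind == "dichotomous":
            stat, p = chisq_2x2(TwoByTwo(int(r.a), int(r.b), int(r.c), int(r.d)))
            method = "chi2"
        elif r.kind == "continuous":
            stat, p = t_from_summaries(
                SummaryPair(r.mean_a, r.sd_a, int(r.n_a), r.mean_b, r.sd_b, int(r.n_b)),
                mode=mode,
            )
            method = f"t_{mode}"
        else:
            raise ValueError(f"unknown row kind {r.kind!r}")
        out.append((r.label, method, stat, p))
    return pd.DataFrame(out, columns=["label", "method", "statistic", "p"])
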