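"""Between-group test battery for cohort baseline characteristics.

The cohort description compares the patient (CHD) and control (HC) groups
with four procedures, each pinned to the kind of variable it handles:

* Fisher's exact test on a 2x2 contingency table (binary characteristics);
* Welch's unequal-variance t-test, computable from mean/SD/n summaries;
* a two-sample proportion test, i.e. the 2x2 chi-squared with Yates
  continuity correction clipped at zero per cell (the classic textbook /
  R ``prop.test`` form);
* Pearson's chi-squared on r x c tables for multi-category characteristics,
  with zero-total categories dropped first (an all-zero category would make
  expected counts 0/0).

P-values are kept at full precision internally; report writers round to
two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyTable", "SummaryStats", "fisher_exact_2x2",
           "welch_from_summary", "prop_test", "chisq_test"]

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise ValueError("negative count in contingency table")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("contingency table counts must be integers")
            self.counts = np.round(self.counts).astype(int)


@dataclass
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def _as_2x2(table) -> np.ndarray:
    t = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    return np.round(t).astype(int)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins whose point probability does not
    exceed the observed one (mainstream-package convention)."""
    t = _as_2x2(table)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def welch_from_summary(a: SummaryStats, b: SummaryStats) -> tuple[float, float, float]:
    """Welch's t-test from per-group mean/SD/n.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both group variances are zero")
    res = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                     equal_var=False)
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def prop_test(x1: int, n1: int, x2: int, n2: int,
              continuity: bool = True) -> float:
    """Two-sample proportion test: chi-squared on the implied 2x2.

    With ``continuity=True`` (default) the Yates correction is applied per
    cell as max(0, |O - E| - 0.5), so proportions closer than the
    correction yield a statistic of exactly 0 and p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"successes {x} outside [0, {n}]")
    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    if np.any(expected == 0):
        return 1.0  # degenerate margin: no information
    dev = np.abs(obs - expected)
    if continuity:
        dev = np.maximum(0.0, dev - 0.5)
    stat = float((dev ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, df=1))


def chisq_test(table, drop_zero_categories: bool = True) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) on an r x c table.

    Rows/columns with zero total are dropped first when
    ``drop_zero_categories`` (they would give undefined expected counts).
    Cells with expected count < 5 trigger a logged warning, not an error.
    Returns (statistic, df, p).
    """
    t = (table.counts if isinstance(table, ContingencyTable)
         else np.asarray(table)).astype(float)
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    if drop_zero_categories:
        t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("fewer than 2 non-degenerate rows or columns")
    stat, p, df, expected = stats.chi2_contingency(t, correction=False)
    low = (expected < 5).sum()
    if low:
        logger.warning("%d cell(s) with expected count < 5; chi-squared "
                       "approximation may be poor", low)
    return float(stat), int(df), float(p)
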