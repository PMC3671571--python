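"""Statistical comparisons: per-frequency rank tests with FDR, proportions.

Group comparisons are two-sided Mann-Whitney rank-sum tests at each
stimulation frequency, corrected with the Benjamini-Hochberg-Yekutieli (BY)
false-discovery-rate procedure; the number of comparisons is held at the full
grid size (13 by default) even when some frequencies are untestable.
Categorical distributions are compared with the chi-square test of
independence, replaced by Fisher's exact test for 2x2 tables with small
expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestReport",
    "fdr_adjust",
    "mw_per_frequency",
    "proportion_test",
]

ALPHA = 0.05


@dataclass
class TestReport:
    """Per-frequency test outcome with raw and FDR-adjusted p-values."""

    comparison: str
    method: str
    frequencies_hz: np.ndarray
    statistic: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    alpha: float = ALPHA

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(self.p_adj), self.p_adj < self.alpha, False)

    @property
    def untestable(self) -> np.ndarray:
        return ~np.isfinite(self.p_raw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "comparison": self.comparison,
                "method": self.method,
                "frequency_hz": self.frequencies_hz,
                "statistic": self.statistic,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "significant": self.significant,
                "untestable": self.untestable,
            }
        )


def fdr_adjust(p_values, m: int | None = None, dependent: bool = True) -> np.ndarray:
    """Benjamini-Hochberg(-Yekutieli) step-up adjusted p-values.

    ``m`` is the number of comparisons in the family, which may exceed the
    number of p-values actually supplied (untestable comparisons still count
    toward the family).  With ``dependent=True`` the Yekutieli correction
    factor ``sum(1/i, i=1..m)`` is applied.  NaN inputs are passed through as
    NaN; adjusted values are monotone in the input ranks and clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = int(finite.sum())
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"family size m={m} smaller than the {n} supplied p-values")
    out = np.full(p.shape, np.nan)
    if n == 0:
        return out
    c = float(np.sum(1.0 / np.arange(1, m + 1))) if dependent else 1.0
    idx = np.flatnonzero(finite)
    order = idx[np.argsort(p[idx], kind="stable")]
    ranks = np.arange(1, n + 1)
    adj = m * c * p[order] / ranks
    adj = np.minimum.accumulate(adj[::-1])[::-1]  # step-up monotonisation
    out[order] = np.minimum(adj, 1.0)
    return out


def mw_per_frequency(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    comparison: str = "",
    m: int | None = None,
    alpha: float = ALPHA,
    dependent: bool = True,
) -> TestReport:
    """Two-sided Mann-Whitney test of one metric at every frequency.

    ``group_a``/``group_b`` are tables of metric values with one column per
    frequency (rows = neurons, NaN = undefined, excluded pairwise).
    Frequencies with fewer than two defined values in either group are marked
    untestable but still count toward the FDR family size ``m`` (defaults to
    the number of columns).
    """
    cols = list(group_a.columns)
    if list(group_b.columns) != cols:
        raise ValueError("groups must share the same frequency columns")
    if m is None:
        m = len(cols)
    stat = np.full(len(cols), np.nan)
    p_raw = np.full(len(cols), np.nan)
    for i, col in enumerate(cols):
        x = group_a[col].dropna().to_numpy()
        y = group_b[col].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        pooled = np.concatenate([x, y])
        # exact null distribution for small tie-free samples, else the
        # tie-corrected normal approximation
        method = (
            "exact"
            if len(np.unique(pooled)) == len(pooled) and max(len(x), len(y)) <= 25
            else "asymptotic"
        )
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat[i], p_raw[i] = res.statistic, res.pvalue
    p_adj = fdr_adjust(p_raw, m=m, dependent=dependent)
    return TestReport(
        comparison=comparison,
        method="MW",
        frequencies_hz=np.asarray(cols, dtype=float),
        statistic=stat,
        p_raw=p_raw,
        p_adj=p_adj,
        alpha=alpha,
    )


def proportion_test(table, comparison: str = "", alpha: float = ALPHA) -> TestReport:
    """Independence test for a contingency table of category counts.

    Chi-square test of independence; for 2x2 tables with any expected count
    below 5, Fisher's exact test (two-sided) is used instead.  Degenerate
    tables (a zero row or column margin) are untestable.
    """
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.number):
        raise ValueError("table must be a 2-D array of nonnegative counts")
    if np.any(t != np.floor(t)):
        raise ValueError("table entries must be integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if t.shape == (2, 2) and expected.min() < 5:
        stat, p = sps.fisher_exact(t, alternative="two-sided")
        method = "fisher"
    else:
        stat, p, _, _ = sps.chi2_contingency(t, correction=False)
        method = "chi2"
    return TestReport(
        comparison=comparison,
        method=method,
        frequencies_hz=np.array([np.nan]),
        statistic=np.array([float(stat)]),
        p_raw=np.array([float(p)]),
        p_adj=np.array([float(p)]),
        alpha=alpha,
    )
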