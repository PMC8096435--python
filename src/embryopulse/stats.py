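"""The statistical toolbox used throughout the analyses.

Unpaired two-tailed Welch's t test, Mann-Whitney U, Pearson's chi-square
with Yates's continuity correction, and Pearson correlation, plus the group
summary (mean, SD, SEM, median, quartiles) behind the boxplots. The
reporting convention is p < 10⁻² for statistical significance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SIGNIFICANCE_P = 1e-2


@dataclass
class TestResult:
    statistic: float
    p_value: float
    name: str

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_P


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    return x


def welch_t(x, y) -> TestResult:
    """Unpaired two-tailed Welch's t test (Satterthwaite df)."""
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(x, y, equal_var=False)
    if np.isnan(p):  # both samples constant and equal
        t, p = 0.0, 1.0
    return TestResult(float(t), float(p), "welch_t")


def mann_whitney(x, y, exact_max_n: int = 8) -> TestResult:
    """Mann-Whitney U from rank sums with midrank ties.

    The U statistic is reported for the first sample (x entirely below y
    gives U = 0). The p value is exact when min(n) <= ``exact_max_n`` and
    there are no ties, and a tie-corrected normal approximation with
    continuity correction otherwise.
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each sample needs at least one observation")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= exact_max_n
                         and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    # U is reported for the first sample (scipy's convention)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "mann_whitney")


def chi2_yates(table) -> TestResult:
    """Pearson's chi-square on a 2×2 table with Yates's correction.

    Σ (|O − E| − 0.5)² / E with the correction floored so that
    |O − E| − 0.5 never goes below zero; p from χ² with one df.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("need a 2×2 contingency table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or np.any(table < 0):
            raise ValueError("counts must be nonnegative integers")
    table = table.astype(float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0 or np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate table: empty row or column")
    expected = row * col / total
    dev = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    stat = float((dev ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(stat, p, "chi2_yates")


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with a t-based two-tailed p value."""
    x, y = _clean(x), _clean(y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant samples")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson_r")


def group_summary(values, group_labels=None) -> pd.DataFrame:
    """Mean, SD, SEM, median and quartiles per group."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float)})
    df["group"] = "all" if group_labels is None else np.asarray(group_labels)
    rows = []
    for g, sub in df.groupby("group", sort=True):
        v = sub.value.to_numpy()
        n = len(v)
        sd = v.std(ddof=1) if n > 1 else np.nan
        rows.append(
            {
                "group": g,
                "n": n,
                "mean": v.mean(),
                "sd": sd,
                "sem": sd / np.sqrt(n) if n > 1 else np.nan,
                "median": np.median(v),
                "q1": np.percentile(v, 25),
                "q3": np.percentile(v, 75),
            }
        )
    return pd.DataFrame(rows)
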