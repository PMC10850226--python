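"""Baseline characteristics and two-group test selection.

Continuous variables are summarised as mean (SD) when a Shapiro-Wilk test
at alpha = 0.05 does not reject normality and as median (Q1, Q3)
otherwise.  Categorical comparisons use the chi-square test when every
expected cell count is >= 5 and Fisher's exact test otherwise; continuous
comparisons use Welch's unequal-variance t-test when both groups look
normal and the Wilcoxon rank-sum test otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContinuousSummary",
    "TestResult",
    "summarize_continuous",
    "select_categorical_test",
    "select_continuous_test",
    "format_count_percent",
    "baseline_table",
    "SHAPIRO_ALPHA",
]

SHAPIRO_ALPHA = 0.05


@dataclass
class ContinuousSummary:
    route: str  # "normal" | "nonnormal"
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float

    def formatted(self, digits: int = 1) -> str:
        if self.route == "normal":
            return f"{self.mean:.{digits}f} ± {self.sd:.{digits}f}"
        return f"{self.median:.{digits}f} ({self.q1:.{digits}f}, {self.q3:.{digits}f})"


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False  # constant: Shapiro undefined, route nonnormal
    return stats.shapiro(x).pvalue >= SHAPIRO_ALPHA


def summarize_continuous(x) -> ContinuousSummary:
    """Summarise one continuous variable, choosing the display route by a
    Shapiro-Wilk normality check.  Quantiles use linear interpolation
    (type 7).  Needs >= 3 non-missing values."""
    arr = np.asarray(x, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise ValueError("need at least 3 non-missing values")
    route = "normal" if _is_normal(arr) else "nonnormal"
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return ContinuousSummary(
        route=route,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def select_categorical_test(table) -> TestResult:
    """Chi-square (no continuity correction) when all expected counts >= 5,
    Fisher's exact test otherwise (2x2 only; collapse larger tables)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("need a two-way contingency table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if (expected >= 5).all():
        stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
        return TestResult("chi_square", float(stat), float(p))
    if tab.shape != (2, 2):
        raise ValueError(
            "expected counts below 5 in a table larger than 2x2; collapse "
            "categories before applying Fisher's exact test"
        )
    res = stats.fisher_exact(tab.astype(int), alternative="two-sided")
    return TestResult("fisher", float(res[0]), float(res[1]))


def select_continuous_test(x, y) -> TestResult:
    """Welch's t-test when both groups look normal (Shapiro-Wilk), else the
    Wilcoxon rank-sum test with the tie-corrected normal approximation."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("both groups need at least 3 values")
    if _is_normal(a) and _is_normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        return TestResult("welch_t", float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue))


def format_count_percent(count: int, total: int, digits: int = 1) -> str:
    """``"54 (18.5)"`` style cell for categorical rows."""
    return f"{count} ({100.0 * count / total:.{digits}f})"


def baseline_table(df: pd.DataFrame, variables: dict[str, str] | None = None) -> pd.DataFrame:
    """Baseline characteristics table.

    ``variables`` maps column name to kind (``"categorical"`` or
    ``"continuous"``); by default every object/category column is treated
    as categorical and every numeric column as continuous.  Returns a
    two-column frame (characteristic, value) mirroring the usual Table-1
    layout; continuous rows state which display route was used.
    """
    if variables is None:
        variables = {
            c: ("categorical" if df[c].dtype == object else "continuous")
            for c in df.columns
        }
    rows = []
    total = len(df)
    for col, kind in variables.items():
        if kind == "categorical":
            counts = df[col].value_counts(dropna=True)
            rows.append((f"{col}, N (%)", ""))
            for level, cnt in counts.items():
                rows.append((f"  {level}", format_count_percent(int(cnt), total)))
        else:
            s = summarize_continuous(df[col].to_numpy(dtype=float))
            label = "mean ± SD" if s.route == "normal" else "median (Q1, Q3)"
            rows.append((f"{col}, {label}", s.formatted(2)))
    return pd.DataFrame(rows, columns=["characteristic", "value"])
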