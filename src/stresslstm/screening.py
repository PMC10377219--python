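"""Statistical feature screening for the stress cohort.

Each of the eleven candidate variables is tested for association with the
binary stress label: continuous variables with a two-sided Welch
two-sample t-test, binary variables with an uncorrected Pearson
chi-square test on the 2x2 contingency table (df = 1).  A variable is
selected when its p-value falls below the significance level (default
alpha = 0.05).  On the reference cohort this reproduces the published
nine-variable selection: gender, age, height, weight, sleep duration,
pulse rate, SBP, drinking and smoking, with DBP and BMI excluded.

No continuity correction is applied and no multiple-testing adjustment
is made: the uncorrected chi-square is what reproduces the published
table p-values (with Yates' correction the drinking table would give
p ~= 0.005 instead of the printed 0.004).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    BINARY_LEVELS,
    BINARY_VARS,
    FEATURES,
    LABEL,
    LABEL_LEVELS,
    UNITS,
)

__all__ = [
    "DegenerateStatisticError",
    "TestResult",
    "ScreeningResult",
    "ScreeningReport",
    "two_sample_t_test",
    "chi_square_test",
    "contingency_table",
    "group_summary",
    "screen_features",
    "format_summary",
]


class DegenerateStatisticError(ValueError):
    """A sample or table is too degenerate for the requested test."""


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


def two_sample_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Welch (unequal-variance) two-sample t-test.

    Both samples must contain at least two values and have positive
    variance.  Swapping the samples negates the statistic and leaves the
    p-value unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, s in (("first", a), ("second", b)):
        if s.ndim != 1 or s.size < 2:
            raise DegenerateStatisticError(
                f"{name} sample needs at least 2 values, got {s.size}"
            )
        if not np.all(np.isfinite(s)):
            raise DegenerateStatisticError(f"{name} sample contains non-finite values")
        if np.var(s, ddof=1) <= 0.0:
            raise DegenerateStatisticError(f"{name} sample has zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue))


def chi_square_test(table: Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table, df = 1.

    No continuity correction is applied.  The table must have strictly
    positive row and column margins.  The statistic is invariant under
    transposition and simultaneous row/column swaps.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DegenerateStatisticError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise DegenerateStatisticError("table entries must be nonnegative integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise DegenerateStatisticError("table total must be positive")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateStatisticError("table has a zero row or column margin")
    res = stats.chi2_contingency(t, correction=False)
    return TestResult(float(res.statistic), float(res.pvalue))


def contingency_table(cohort: pd.DataFrame, var: str) -> np.ndarray:
    """2x2 counts for a binary variable: rows = levels, cols = (low, high)."""
    first, second = BINARY_LEVELS[var]
    counts = np.zeros((2, 2), dtype=np.int64)
    for j, group in enumerate(LABEL_LEVELS):
        sub = cohort.loc[cohort[LABEL] == group, var]
        counts[0, j] = int((sub == first).sum())
        counts[1, j] = int((sub == second).sum())
    return counts


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the association test for one candidate variable."""

    name: str
    kind: str  # "t" or "chi-square"
    statistic: float
    pvalue: float
    selected: bool


@dataclass(frozen=True)
class ScreeningReport:
    """Per-variable screening outcomes, in canonical schema order."""

    results: tuple[ScreeningResult, ...]
    alpha: float

    @property
    def selected_features(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.results if r.selected)

    def __getitem__(self, name: str) -> ScreeningResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "selected": list(self.selected_features),
            "results": [
                {
                    "name": r.name,
                    "test": r.kind,
                    "statistic": r.statistic,
                    "pvalue": r.pvalue,
                    "selected": r.selected,
                }
                for r in self.results
            ],
        }


def _split_groups(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    present = set(cohort[LABEL].unique())
    if not set(LABEL_LEVELS) <= present:
        raise ValueError(
            f"cohort must contain both stress groups; found {sorted(present)}"
        )
    return (
        cohort[cohort[LABEL] == LABEL_LEVELS[0]],
        cohort[cohort[LABEL] == LABEL_LEVELS[1]],
    )


def screen_features(cohort: pd.DataFrame, alpha: float = 0.05) -> ScreeningReport:
    """Test all eleven candidate variables against the stress label.

    Continuous variables get the Welch t-test, binary variables the
    uncorrected chi-square test; ``selected`` means ``p < alpha``.
    Degeneracy errors are re-raised with the offending variable's name.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    low, high = _split_groups(cohort)
    results = []
    for var in FEATURES:
        try:
            if var in BINARY_VARS:
                stat, p = chi_square_test(contingency_table(cohort, var))
                kind = "chi-square"
            else:
                stat, p = two_sample_t_test(low[var].to_numpy(), high[var].to_numpy())
                kind = "t"
        except DegenerateStatisticError as exc:
            raise DegenerateStatisticError(f"variable {var!r}: {exc}") from exc
        results.append(ScreeningResult(var, kind, stat, p, bool(p < alpha)))
    return ScreeningReport(tuple(results), alpha)


def group_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group summary in the reference-table layout.

    One row per continuous variable (group means) and per binary-variable
    level (group counts), with each variable's test p-value attached to
    its first row.
    """
    low, high = _split_groups(cohort)
    report = screen_features(cohort)
    rows = []
    for var in FEATURES:
        p = report[var].pvalue
        if var in BINARY_VARS:
            table = contingency_table(cohort, var)
            rows.append({"variable": var, "level": "", "low": np.nan, "high": np.nan, "pvalue": p})
            for i, level in enumerate(BINARY_LEVELS[var]):
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "low": table[i, 0],
                        "high": table[i, 1],
                        "pvalue": np.nan,
                    }
                )
        else:
            rows.append(
                {
                    "variable": var,
                    "level": "mean",
                    "low": float(low[var].mean()),
                    "high": float(high[var].mean()),
                    "pvalue": p,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "level", "low", "high", "pvalue"])


def format_summary(summary: pd.DataFrame) -> str:
    """Plain-text rendering of :func:`group_summary`.

    p-values are printed in fixed-point with three decimals (so a p-value
    of 6.6e-6 prints as 0.000); full precision is kept in the DataFrame.
    """
    lines = [f"{'Variable':<28}{'Low':>10}{'High':>10}{'p-value':>10}"]
    for _, row in summary.iterrows():
        name = row["variable"] if row["level"] in ("", "mean") else f"  {row['level']}"
        if row["level"] == "mean":
            unit = UNITS.get(row["variable"], "")
            name = f"Avg. {row['variable']}" + (f" ({unit})" if unit else "")
        if np.isnan(row["low"]):
            low = high = ""
        elif row["level"] in BINARY_LEVELS.get(row["variable"], ()):
            low, high = f"{int(row['low'])}", f"{int(row['high'])}"
        else:
            low, high = f"{row['low']:.2f}", f"{row['high']:.2f}"
        p = "" if np.isnan(row["pvalue"]) else f"{row['pvalue']:.3f}"
        lines.append(f"{name:<28}{low:>10}{high:>10}{p:>10}")
    return "\n".join(lines)
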