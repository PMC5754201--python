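"""Condition-level statistics: unpaired Student's test, mean±SEM bars,
five-number whisker summaries and significance-star labels.

The default star convention is deliberately unconventional — ``***`` for
p < 0.05 and ``*`` for p < 0.1 — matching the source study's reporting;
the standard ``*/**/***`` scheme is available as
:data:`STANDARD_CONVENTION`. The default test is the classical
equal-variance (pooled) two-sample t with ``df = n_a + n_b - 2``;
Welch's correction is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "DEFAULT_CONVENTION",
    "STANDARD_CONVENTION",
    "TTestResult",
    "GroupSummary",
    "ComparisonResult",
    "unpaired_t_test",
    "t_test_from_stats",
    "group_summary",
    "significance_stars",
    "compare_conditions",
    "bar_sem_plot",
    "whisker_plot",
]

#: (p-threshold, label) pairs in increasing threshold order; the label of
#: the smallest threshold exceeding p wins, else "ns".
DEFAULT_CONVENTION: tuple[tuple[float, str], ...] = ((0.05, "***"), (0.1, "*"))
STANDARD_CONVENTION: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


class TTestResult(NamedTuple):
    t_statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class GroupSummary:
    """Mean±SEM bar summary and five-number whisker summary for one condition."""

    condition: str
    n: int
    mean: float
    sem: float | None  # undefined (None) for n = 1
    five_number: tuple[float, float, float, float, float]

    def as_dict(self) -> dict:
        lo, q1, med, q3, hi = self.five_number
        return {
            "condition": self.condition,
            "n": self.n,
            "mean": self.mean,
            "sem": self.sem,
            "min": lo,
            "q1": q1,
            "median": med,
            "q3": q3,
            "max": hi,
        }


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    condition_a: str
    condition_b: str
    summary_a: GroupSummary
    summary_b: GroupSummary
    t_statistic: float
    p_value: float
    stars: str
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "group_a": self.summary_a.as_dict(),
            "group_b": self.summary_b.as_dict(),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "stars": self.stars,
            "degenerate": self.degenerate,
        }


def _check_sample(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"sample {name} needs n >= 2 one-dimensional values")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"sample {name} contains non-finite values")
    return x


def unpaired_t_test(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sided unpaired two-sample t-test (pooled variance by default).

    Zero pooled variance with equal means yields ``t = 0, p = 1``; with
    unequal means the result is flagged degenerate with ``p = 0``.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, degenerate=False)
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()), 0.0, True)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue))


def t_test_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TTestResult:
    """Pooled t-test from group means and standard deviations.

    The summary-statistics variant of the same test, for when only a
    sample's average and standard deviation are available.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need n >= 2")
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            return TTestResult(0.0, 1.0)
        return TTestResult(math.copysign(math.inf, mean_a - mean_b), 0.0, True)
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True)
    return TTestResult(float(res.statistic), float(res.pvalue))


def group_summary(values, condition: str = "") -> GroupSummary:
    """Mean, SEM (sample sd / sqrt(n); None for n = 1) and five-number summary.

    Quartiles use linear interpolation between order statistics.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("need a non-empty 1D sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    n = x.size
    sem = float(x.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
    lo, q1, med, q3, hi = np.percentile(x, [0, 25, 50, 75, 100])
    return GroupSummary(
        condition=condition,
        n=n,
        mean=float(x.mean()),
        sem=sem,
        five_number=(float(lo), float(q1), float(med), float(q3), float(hi)),
    )


def significance_stars(
    p: float, convention: Sequence[tuple[float, str]] = DEFAULT_CONVENTION
) -> str:
    """Map a p-value to a star label under the given convention.

    Default: ``p < 0.05 -> "***"``, ``0.05 <= p < 0.1 -> "*"``, else ``"ns"``.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1]; got {p}")
    for threshold, stars in sorted(convention):
        if p < threshold:
            return stars
    return "ns"


def compare_conditions(
    table,
    metric: str,
    cond_a: str,
    cond_b: str,
    convention: Sequence[tuple[float, str]] = DEFAULT_CONVENTION,
    equal_var: bool = True,
    condition_col: str = "condition",
) -> ComparisonResult:
    """Compare one metric between two conditions of a tidy per-specimen table.

    *table* is a DataFrame with one row per specimen, a condition column
    and a numeric column named *metric*.
    """
    if metric not in table.columns:
        raise KeyError(f"unknown metric {metric!r}; columns: {list(table.columns)}")
    samples = {}
    for cond in (cond_a, cond_b):
        vals = table.loc[table[condition_col] == cond, metric].dropna().to_numpy(float)
        if vals.size < 2:
            raise ValueError(
                f"condition {cond!r} has n = {vals.size} < 2 for metric {metric!r}"
            )
        samples[cond] = vals
    res = unpaired_t_test(samples[cond_a], samples[cond_b], equal_var=equal_var)
    return ComparisonResult(
        metric=metric,
        condition_a=cond_a,
        condition_b=cond_b,
        summary_a=group_summary(samples[cond_a], cond_a),
        summary_b=group_summary(samples[cond_b], cond_b),
        t_statistic=res.t_statistic,
        p_value=res.p_value,
        stars=significance_stars(res.p_value, convention),
        degenerate=res.degenerate,
    )


def _agg_backend():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def bar_sem_plot(
    summaries: Sequence[GroupSummary], metric: str, path: str | Path
) -> Path:
    """Bar graph of group means with SEM error bars."""
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(4, 4))
    xs = np.arange(len(summaries))
    means = [s.mean for s in summaries]
    sems = [0.0 if s.sem is None else s.sem for s in summaries]
    ax.bar(xs, means, yerr=sems, capsize=4, color="0.7", edgecolor="k")
    ax.set_xticks(xs)
    ax.set_xticklabels([f"{s.condition}\n(n={s.n})" for s in summaries])
    ax.set_ylabel(metric)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def whisker_plot(
    summaries: Sequence[GroupSummary], metric: str, path: str | Path
) -> Path:
    """Whisker plot drawn from the five-number summaries (min, Q1, median, Q3, max)."""
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(4, 4))
    boxes = []
    for s in summaries:
        lo, q1, med, q3, hi = s.five_number
        boxes.append(
            {
                "label": f"{s.condition} (n={s.n})",
                "whislo": lo,
                "q1": q1,
                "med": med,
                "q3": q3,
                "whishi": hi,
                "fliers": [],
            }
        )
    ax.bxp(boxes, showfliers=False)
    ax.set_ylabel(metric)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
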