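"""Summary statistics and the significance tests used for figure legends.

Everything here reduces to the unpaired equal-variance (pooled) Student
t-test and mean +/- SD / SEM reporting, plus small conveniences: running
the test directly from printed summary statistics, percent reduction of a
group mean, and a pairwise comparison table for FRET-efficiency groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "TTestResult",
    "summarize",
    "ttest_unpaired",
    "ttest_from_summary",
    "percent_reduction",
    "fret_group_report",
]


@dataclass(frozen=True)
class SummaryStats:
    """Sample size, mean, SD (n-1 denominator) and SEM of one group."""

    n: int
    mean: float
    sd: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class TTestResult:
    """Unpaired equal-variance t-test outcome (two-tailed)."""

    t: float
    df: int
    p: float
    group_a: SummaryStats
    group_b: SummaryStats


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, SD and SEM of a sample; SD/SEM are NaN (flagged) for n=1."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if x.size == 1:
        logger.warning("n=1 sample: SD and SEM are undefined")
        return SummaryStats(n=1, mean=float(x[0]), sd=float("nan"),
                            sem=float("nan"))
    sd = float(x.std(ddof=1))
    return SummaryStats(n=int(x.size), mean=float(x.mean()), sd=sd,
                        sem=sd / float(np.sqrt(x.size)))


def ttest_from_summary(a: SummaryStats, b: SummaryStats) -> TTestResult:
    """Pooled-variance t-test computed from summary statistics alone.

    Identical to the raw-sample test; lets printed figure-legend values
    (mean +/- SD, n) be checked directly.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if a.sd < 0 or b.sd < 0:
        raise ValueError("standard deviations must be >= 0")
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
    if pooled_var == 0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=df, p=1.0, group_a=a, group_b=b)
        logger.warning("zero pooled variance with unequal means: p -> 0")
        return TTestResult(t=float(np.inf) if a.mean > b.mean
                           else float(-np.inf), df=df, p=0.0,
                           group_a=a, group_b=b)
    se = float(np.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n)))
    t = (a.mean - b.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=min(p, 1.0), group_a=a, group_b=b)


def ttest_unpaired(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Unpaired Student t-test assuming equal variance, from raw samples."""
    sa, sb = summarize(a), summarize(b)
    return ttest_from_summary(sa, sb)


def percent_reduction(control: SummaryStats, treated: SummaryStats) -> float:
    """Percent reduction of the treated group mean relative to control."""
    if control.mean == 0:
        raise ValueError("percent reduction undefined for zero control mean")
    return 100.0 * (1.0 - treated.mean / control.mean)


def fret_group_report(groups: Mapping[str, Sequence[float]]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean +/- SEM and all pairwise equal-variance t-tests.

    Groups with n < 2 are excluded from testing with a warning.  The
    pairwise p-values are reported raw (uncorrected for multiple
    comparisons), as is conventional for figure-legend stars; the table
    carries a ``correction`` column stating so.
    """
    if len(groups) < 1:
        raise ValueError("need at least one group")
    summaries = []
    usable: dict[str, SummaryStats] = {}
    for name, values in groups.items():
        s = summarize(values)
        summaries.append({"group": name, "n": s.n, "mean": s.mean,
                          "sd": s.sd, "sem": s.sem})
        if s.n >= 2:
            usable[name] = s
        else:
            logger.warning("group %r has n<2: excluded from testing", name)
    summary_df = pd.DataFrame(summaries)
    rows = []
    names = list(usable)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            res = ttest_from_summary(usable[na], usable[nb])
            rows.append({"group_a": na, "group_b": nb, "t": res.t,
                         "df": res.df, "p": res.p, "correction": "none"})
    tests_df = pd.DataFrame(
        rows, columns=["group_a", "group_b", "t", "df", "p", "correction"])
    return summary_df, tests_df
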