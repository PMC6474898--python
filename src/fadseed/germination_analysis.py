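"""Germination curves and nonparametric comparisons.

Germination is summarised per seed category by the inverse Kaplan-Meier
curve (1 minus the product-limit survival estimate: the cumulative fraction
germinated over days, with non-germinators right-censored), and categories
are compared by a Wilcoxon rank-sum test and by the log-rank test.

The rank-sum test here is the shared implementation for the whole package:
midrank tie handling, exact p by full enumeration of group assignments for
small samples, tie-corrected normal approximation with continuity
correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

#: Combined sample size at or below which the exact enumeration is used.
EXACT_THRESHOLD = 12


@dataclass
class TestResult:
    """Outcome of a two-sample hypothesis test."""

    name: str
    statistic: float
    p_value: float
    df: Optional[int] = None
    n_per_group: tuple[int, int] = (0, 0)
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class KMCurve:
    """Inverse Kaplan-Meier curve: cumulative germinated proportion by day.

    ``days`` are the ordered observed event days; ``cum_germinated`` is
    1 - S(t) at each day (non-decreasing, in [0, 1]); ``at_risk`` counts
    seeds still under observation just before each day (non-increasing).
    """

    category: str
    days: np.ndarray
    cum_germinated: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cum_germinated) < -1e-12):
            raise ValueError("cumulative germination must be non-decreasing")
        if np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at-risk counts must be non-increasing")


def inverse_km(records: pd.DataFrame) -> dict[str, KMCurve]:
    """Product-limit estimate of cumulative germination, per category.

    ``records`` needs columns ``category``, ``day`` and boolean
    ``germinated`` (False = right-censored at ``day``).  With no censoring
    the curve equals the empirical cumulative fraction germinated.
    """
    if records.empty:
        raise ValueError("no germination records")
    curves: dict[str, KMCurve] = {}
    for cat, grp in records.groupby("category", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["day"], event_observed=grp["germinated"].astype(bool))
        tbl = kmf.event_table
        event_days = tbl.index[tbl["observed"] > 0].to_numpy(dtype=float)
        if event_days.size:
            surv = (
                kmf.survival_function_at_times(event_days).to_numpy(dtype=float)
            )
            cum = 1.0 - surv
            at_risk = tbl.loc[event_days, "at_risk"].to_numpy(dtype=float)
        else:
            cum = np.array([])
            at_risk = np.array([])
        curves[str(cat)] = KMCurve(
            category=str(cat), days=event_days, cum_germinated=cum, at_risk=at_risk
        )
    return curves


def _rank_sum_statistic(ranks_a: np.ndarray, n1: int) -> float:
    """Mann-Whitney U of the first sample from its midranks."""
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2.0)


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    exact_threshold: int = EXACT_THRESHOLD,
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    The statistic W is the Mann-Whitney U of the first sample (rank sum of
    ``a`` minus its minimum).  For combined n at or below
    ``exact_threshold`` the p-value is exact, by full enumeration of the
    C(n, n1) assignments of the pooled midranks to the first group
    (two-sided: twice the smaller tail including the observed point, capped
    at 1).  Larger samples use the normal approximation with tie-corrected
    variance and a 0.5 continuity correction.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = _rank_sum_statistic(ranks[:n1], n1)

    if n <= exact_threshold:
        total = 0
        le = ge = 0
        for idx in combinations(range(n), n1):
            u = _rank_sum_statistic(ranks[list(idx)], n1)
            total += 1
            le += u <= w + 1e-9
            ge += u >= w - 1e-9
        p_less, p_greater = le / total, ge / total
        method = "exact enumeration"
    else:
        mu = n1 * n2 / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:  # all values tied
            p_less = p_greater = 1.0
        else:
            sd = np.sqrt(var)
            p_less = stats.norm.cdf((w - mu + 0.5) / sd)
            p_greater = stats.norm.sf((w - mu - 0.5) / sd)
        method = "normal approximation"

    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_less, p_greater))
    elif alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(
        name="wilcoxon_rank_sum",
        statistic=w,
        p_value=float(p),
        n_per_group=(n1, n2),
        method=method,
    )


def logrank_test(records: pd.DataFrame) -> TestResult:
    """Two-group log-rank test of the germination-time distributions.

    Standard observed-minus-expected chi-square with 1 degree of freedom;
    censoring enters through the at-risk sets.  Requires exactly two
    categories and at least one event overall.
    """
    cats = sorted(records["category"].unique())
    if len(cats) != 2:
        raise ValueError(f"log-rank test needs exactly 2 categories, got {cats}")
    if not records["germinated"].astype(bool).any():
        raise ValueError("no germination events: log-rank test undefined")
    ga = records[records["category"] == cats[0]]
    gb = records[records["category"] == cats[1]]
    res = _ll_logrank(
        ga["day"],
        gb["day"],
        event_observed_A=ga["germinated"].astype(bool),
        event_observed_B=gb["germinated"].astype(bool),
    )
    return TestResult(
        name="logrank",
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=1,
        n_per_group=(len(ga), len(gb)),
        method="chi-square",
    )


def germination_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-category germinated fraction and counts (censored = not germinated)."""
    if records.empty:
        raise ValueError("no germination records")
    grouped = records.groupby("category", sort=True)["germinated"]
    out = pd.DataFrame(
        {
            "n": grouped.size(),
            "n_germinated": grouped.sum().astype(int),
        }
    )
    out["fraction_germinated"] = out["n_germinated"] / out["n"]
    return out.reset_index()
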