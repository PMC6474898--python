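"""Fitness-phenotype association models.

Plant-level association between the fitness proxy (total flowers) and mean
seed spot cover is an ordinary least-squares regression; seed-level
associations use a linear mixed model with a per-plant random intercept
(REML).  Group comparisons between light regimes delegate to the shared
Wilcoxon rank-sum implementation.

Two-sided p-values throughout; no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from fadseed.germination_analysis import TestResult, rank_sum_test


@dataclass
class RegressionFit:
    """Ordinary least-squares fit of y on x (with intercept)."""

    slope: float
    intercept: float
    slope_se: float
    t: float
    p_value: float
    r_squared: float
    n: int


@dataclass
class MixedFit:
    """Random-intercept linear mixed model fit (REML by default)."""

    slope: float
    intercept: float
    group_variance: float
    residual_variance: float
    t: float
    group_name: str
    n_obs: int
    n_groups: int
    method: str = "REML"


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """OLS of y on x; t and p for the slope use n-2 degrees of freedom.

    Raises
    ------
    ValueError
        If lengths differ, n < 3, or x is constant.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant: slope undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.OLS(yv, sm.add_constant(xv)).fit()
        r2 = float(res.rsquared)
        t = float(res.tvalues[1])
        p = float(res.pvalues[1])
    if not np.isfinite(r2):  # constant y: no variance to explain
        r2 = 0.0
    if not np.isfinite(t):
        t, p = 0.0, 1.0
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        t=t,
        p_value=p,
        r_squared=r2,
        n=int(xv.size),
    )


def fit_mixed_linear(
    y: Sequence[float],
    x: Sequence[float],
    groups: Sequence,
    reml: bool = True,
) -> MixedFit:
    """Linear mixed model of y on x with a random intercept per group.

    When the grouping is degenerate — a single group, or data the pooled
    OLS fits perfectly (zero residual) — the fixed slope reduces to the
    pooled OLS slope; the single-group case additionally emits a warning.
    """
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    gv = np.asarray(groups)
    if not (yv.size == xv.size == gv.size):
        raise ValueError("y, x and groups must have equal length")
    uniq = np.unique(gv)
    ols = fit_linear(xv, yv)
    resid_ss = float(
        np.sum((yv - ols.intercept - ols.slope * xv) ** 2)
    )

    if uniq.size < 2:
        warnings.warn(
            "single group: mixed model falls back to pooled OLS", stacklevel=2
        )
        return _mixedfit_from_ols(ols, resid_ss, n_groups=int(uniq.size))
    if resid_ss < 1e-10 * max(1.0, float(np.sum(yv**2))):
        # exact linear data: REML is degenerate, the documented reduction applies
        return _mixedfit_from_ols(ols, resid_ss, n_groups=int(uniq.size))

    exog = sm.add_constant(xv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(yv, exog, groups=gv)
        res = model.fit(reml=reml)
    return MixedFit(
        slope=float(res.fe_params[1]),
        intercept=float(res.fe_params[0]),
        group_variance=float(np.asarray(res.cov_re).ravel()[0]),
        residual_variance=float(res.scale),
        t=float(res.tvalues[1]),
        group_name="group",
        n_obs=int(yv.size),
        n_groups=int(uniq.size),
        method="REML" if reml else "ML",
    )


def _mixedfit_from_ols(ols: RegressionFit, resid_ss: float, n_groups: int) -> MixedFit:
    return MixedFit(
        slope=ols.slope,
        intercept=ols.intercept,
        group_variance=0.0,
        residual_variance=resid_ss / max(1, ols.n - 2),
        t=ols.t,
        group_name="group",
        n_obs=ols.n,
        n_groups=n_groups,
        method="OLS reduction",
    )


def compare_groups(
    a: Sequence[float], b: Sequence[float]
) -> TestResult:
    """Rank-sum comparison of a measurement between two regimes.

    Delegates to the shared Wilcoxon rank-sum implementation (single
    implementation package-wide).
    """
    return rank_sum_test(a, b)
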