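"""Ant seed-preference assays: paired trials and checkerboard grids.

Two assay designs quantify whether foraging ants prefer unspotted seeds:

* **paired trials** — one unspotted and one spotted seed are presented
  together; the first removed is recorded.  Analysed by the per-category
  removal fraction with an exact binomial sign test against 0.5, and by an
  intercept-only logistic mixed model with a random intercept per time
  point (sessions merged);
* **grid assay** — the two categories alternate on an even-sided
  checkerboard; the complete removal order is logged.  Analysed by a
  rank-sum test on removal ranks, a running state account, and a
  hypergeometric null for category-blind removal.

The odds ratio convention follows the binary outcome "the spotted seed was
removed": OR = spotted removals / unspotted removals, so OR < 1 means a
preference for unspotted seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from fadseed.germination_analysis import TestResult, rank_sum_test

CATEGORIES = ("unspotted", "spotted")


class SeparationError(ValueError):
    """All removals fall in one category: the logistic MLE diverges."""


@dataclass
class PreferenceResult:
    """Summary of a preference analysis.

    ``fractions`` sum to 1 across categories; ``odds_ratio`` is the odds
    of the spotted seed being the one removed (< 1: unspotted preferred).
    """

    removals: dict[str, int]
    fractions: dict[str, float]
    odds_ratio: float
    statistic: float
    p_value: float
    method: str
    random_intercept_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class GridAssay:
    """Checkerboard layout plus the ordered removal log.

    ``layout``: one row per occupied cell (``row``, ``col``,
    ``category``), forming a proper 2-coloring (4-neighbors always differ).
    ``events``: ordered removals (``event_index`` strictly increasing,
    ``time``, ``row``, ``col``); each cell is removed at most once.  Tied
    time stamps are ordered by event index (video frame order).
    """

    layout: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        lay = self.layout
        cellcat = {(r, c): cat for r, c, cat in lay[["row", "col", "category"]].itertuples(index=False)}
        if len(cellcat) != len(lay):
            raise ValueError("duplicate cells in layout")
        for (r, c), cat in cellcat.items():
            for rr, cc in ((r + 1, c), (r, c + 1)):
                if (rr, cc) in cellcat and cellcat[(rr, cc)] == cat:
                    raise ValueError(
                        f"layout is not a proper 2-coloring at cell ({r}, {c})"
                    )
        ev = self.events
        if len(ev):
            idx = ev["event_index"].to_numpy()
            if np.any(np.diff(idx) <= 0):
                raise ValueError("event indices must be strictly increasing")
            cells = list(ev[["row", "col"]].itertuples(index=False, name=None))
            if len(set(cells)) != len(cells):
                raise ValueError("a cell is removed more than once")
            missing = [cell for cell in cells if cell not in cellcat]
            if missing:
                raise ValueError(f"events reference empty cells: {missing}")

    def event_categories(self) -> pd.Series:
        """Category of each removal, in event order, from the layout."""
        cellcat = {
            (r, c): cat
            for r, c, cat in self.layout[["row", "col", "category"]].itertuples(index=False)
        }
        return self.events.apply(lambda e: cellcat[(e["row"], e["col"])], axis=1)


# --------------------------------------------------------------------------
# paired trials
# --------------------------------------------------------------------------

def _removal_counts(trials: pd.DataFrame) -> dict[str, int]:
    counts = trials["removed_category"].value_counts().to_dict()
    bad = set(counts) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown removal categories: {sorted(bad)}")
    return {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}


def trial_preference(trials: pd.DataFrame) -> PreferenceResult:
    """Removal fraction per category with an exact binomial sign test.

    The fraction of trials in which each category was removed, the raw
    odds ratio (spotted / unspotted removals), and a two-sided exact
    binomial test of the removal probability against 0.5.
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    counts = _removal_counts(trials)
    n = len(trials)
    n_un, n_sp = counts["unspotted"], counts["spotted"]
    test = stats.binomtest(n_un, n, p=0.5, alternative="two-sided")
    odds = (n_sp / n_un) if n_un > 0 else np.inf
    if n_sp == 0:
        odds = 1e-12  # degenerate: keep OR positive, p-value carries the evidence
    return PreferenceResult(
        removals=counts,
        fractions={cat: counts[cat] / n for cat in CATEGORIES},
        odds_ratio=float(odds),
        statistic=float(n_un),
        p_value=float(test.pvalue),
        method="exact binomial sign test",
    )


def _glmm_negloglik(
    theta: np.ndarray, k: np.ndarray, m: np.ndarray, nodes: np.ndarray, wts: np.ndarray
) -> float:
    """Negative marginal log-likelihood of the intercept-only logistic GLMM.

    Per time point j with k_j spotted removals out of m_j trials,
    the random intercept u_j ~ N(0, sigma^2) is integrated out by
    Gauss-Hermite quadrature.
    """
    beta, log_sigma = theta
    sigma = np.exp(log_sigma)
    eta = beta + np.sqrt(2.0) * sigma * nodes  # (Q,)
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    # (groups, Q) binomial log-kernels
    ll = k[:, None] * log_p[None, :] + (m - k)[:, None] * log_q[None, :]
    group_ll = logsumexp(ll + np.log(wts / np.sqrt(np.pi))[None, :], axis=1)
    return -float(group_ll.sum())


def trial_mixed_logistic(
    trials: pd.DataFrame,
    time_col: str = "time",
    bins: Optional[int] = None,
    n_quadrature: int = 25,
) -> PreferenceResult:
    """Intercept-only logistic mixed model for the paired-trial assay.

    Models the binary outcome "the spotted seed was removed" with a fixed
    intercept and a Gaussian random intercept per time point (each distinct
    value of ``time_col``, or ``bins`` equal-width bins of it).  Maximum
    likelihood via Gauss-Hermite quadrature.  OR = exp(fixed intercept);
    when the between-time variance is estimated at 0 this reduces to the
    raw odds ratio.

    Raises
    ------
    SeparationError
        If every removal is of one category (the MLE diverges).
    ValueError
        With fewer than two time points.
    """
    counts = _removal_counts(trials)
    if counts["unspotted"] == 0 or counts["spotted"] == 0:
        raise SeparationError(
            "all removals are of one category: odds ratio is not estimable"
        )
    t = trials[time_col]
    grouping = pd.cut(t, bins) if bins is not None else t
    y = (trials["removed_category"] == "spotted").astype(int)
    per_group = y.groupby(grouping, observed=True).agg(["sum", "size"])
    if len(per_group) < 2:
        raise ValueError("need at least 2 time points for a random intercept")
    k = per_group["sum"].to_numpy(dtype=float)
    m = per_group["size"].to_numpy(dtype=float)

    nodes, wts = np.polynomial.hermite.hermgauss(n_quadrature)
    raw_logit = float(np.log(counts["spotted"] / counts["unspotted"]))
    best = None
    for s0 in (-3.0, -1.0, 0.0):  # multistart over the variance scale
        res = optimize.minimize(
            _glmm_negloglik,
            x0=np.array([raw_logit, s0]),
            args=(k, m, nodes, wts),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    beta, log_sigma = best.x
    sigma = float(np.exp(log_sigma))

    # Wald z from the profile curvature in beta (central differences)
    h = 1e-4
    f0 = _glmm_negloglik(np.array([beta, log_sigma]), k, m, nodes, wts)
    fp = _glmm_negloglik(np.array([beta + h, log_sigma]), k, m, nodes, wts)
    fm = _glmm_negloglik(np.array([beta - h, log_sigma]), k, m, nodes, wts)
    curv = (fp - 2 * f0 + fm) / h**2
    se = 1.0 / np.sqrt(curv) if curv > 0 else np.nan
    z = beta / se if np.isfinite(se) and se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0

    n = len(trials)
    return PreferenceResult(
        removals=counts,
        fractions={cat: counts[cat] / n for cat in CATEGORIES},
        odds_ratio=float(np.exp(beta)),
        statistic=float(z) if np.isfinite(z) else 0.0,
        p_value=p,
        method="logistic mixed model (ML, Gauss-Hermite)",
        random_intercept_sd=sigma,
    )


# --------------------------------------------------------------------------
# grid assay
# --------------------------------------------------------------------------

def grid_state(assay: GridAssay, k: int) -> pd.DataFrame:
    """Removed/remaining counts per category after the first ``k`` removals.

    Conservation holds per category: removed + remaining = initial.
    """
    n_cells = len(assay.layout)
    if not 0 <= k <= n_cells:
        raise ValueError(f"k must lie in [0, {n_cells}]")
    if k > len(assay.events):
        raise ValueError(f"log holds only {len(assay.events)} events")
    initial = assay.layout["category"].value_counts()
    removed = (
        assay.event_categories().iloc[:k].value_counts()
        if k
        else pd.Series(dtype=int)
    )
    rows = []
    for cat in sorted(initial.index):
        ini = int(initial[cat])
        rem = int(removed.get(cat, 0))
        rows.append(
            {
                "category": cat,
                "initial": ini,
                "removed": rem,
                "remaining": ini - rem,
            }
        )
    return pd.DataFrame(rows)


def grid_rank_test(assay: GridAssay) -> TestResult:
    """Rank-sum comparison of removal order between the two categories.

    Removal rank 1 is the first seed taken; ranks are split by category
    and compared with the shared Wilcoxon rank-sum implementation
    (unspotted ranks first).  Seeds never removed are not ranked; a
    category with no removals at all raises, with guidance.
    """
    cats = assay.event_categories().to_numpy()
    ranks = np.arange(1, len(cats) + 1, dtype=float)
    a = ranks[cats == "unspotted"]
    b = ranks[cats == "spotted"]
    if a.size == 0 or b.size == 0:
        raise ValueError(
            "a category was never removed; the rank test needs removals from "
            "both (treating unremoved seeds as censored is not supported)"
        )
    return rank_sum_test(a, b)


def random_removal_null(
    observed_focal: int, n_draws: int, focal_total: int, grand_total: int
) -> float:
    """Upper-tail probability of the focal count under category-blind removal.

    P(X >= observed) where X ~ Hypergeometric(N=grand_total,
    K=focal_total, n=n_draws): the chance that blind removal of
    ``n_draws`` seeds takes at least ``observed_focal`` of the focal
    category.
    """
    if not 0 <= focal_total <= grand_total:
        raise ValueError("focal_total must lie in [0, grand_total]")
    if not 0 <= n_draws <= grand_total:
        raise ValueError("n_draws must lie in [0, grand_total]")
    if not 0 <= observed_focal <= n_draws:
        raise ValueError("observed count must lie in [0, n_draws]")
    if observed_focal > focal_total:
        return 0.0
    return float(stats.hypergeom.sf(observed_focal - 1, grand_total, focal_total, n_draws))
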