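"""Plant-level phenotyping: fitness proxy, seed categories, aggregation.

The fitness proxy of a plant is its total flower count with the top whorl
omitted (the last whorl develops only partially and would be
over-represented).  Seeds are classified into "unspotted" (bottom 15% of
the spot-cover distribution) and "spotted" (top 15%) by rank, with
floor() tail sizes so the tails never overlap.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def plant_fitness(whorl_counts: Sequence[int]) -> int:
    """Total flowers of a plant, omitting the top (last) whorl.

    The whorl list is ordered base to top.  A single-whorl plant returns 0:
    only the omitted whorl exists (flagged in the log rather than raised).
    """
    if len(whorl_counts) == 0:
        raise ValueError("whorl count list must be non-empty")
    counts = [int(c) for c in whorl_counts]
    if any(c < 0 for c in counts):
        raise ValueError("flower counts must be non-negative")
    if len(counts) == 1:
        logger.info("single-whorl plant: fitness proxy is 0 by the omission rule")
    return int(sum(counts[:-1]))


def categorize_seeds(
    covers: Sequence[float],
    low_quantile: float = 0.15,
    high_quantile: float = 0.85,
) -> list[str]:
    """Rank-based classification into unspotted / mid / spotted.

    Exactly ``floor(low_quantile * n)`` lowest-ranked covers are labelled
    ``"unspotted"`` and ``floor((1 - high_quantile) * n)`` highest-ranked
    ``"spotted"``; everything else is ``"mid"``.  Ranking is by value with
    stable tie-breaking in input order; a tie spanning a cut is logged.

    Raises
    ------
    ValueError
        For fewer than 7 values (a tail would be empty) or a degenerate
        all-equal distribution.
    """
    values = np.asarray(covers, dtype=float)
    n = values.size
    if n < 7:
        raise ValueError("need at least 7 cover values so both tails are non-empty")
    if np.ptp(values) == 0:
        raise ValueError("degenerate distribution: all cover values identical")
    k_low = math.floor(low_quantile * n)
    k_high = math.floor((1.0 - high_quantile) * n)

    order = np.argsort(values, kind="stable")
    labels = np.full(n, "mid", dtype=object)
    labels[order[:k_low]] = "unspotted"
    labels[order[n - k_high :]] = "spotted"

    for cut, name in ((k_low, "low"), (n - k_high, "high")):
        if 0 < cut < n and values[order[cut - 1]] == values[order[cut]]:
            logger.info(
                "tie spans the %s cut (value %.6g); broken by stable input order",
                name,
                values[order[cut]],
            )
    return list(labels)


def aggregate_plants(
    seeds: pd.DataFrame, plant_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Aggregate per-seed measurements to the plant level.

    Expects seed rows with ``plant_id``, ``spot_cover_pct`` and (optionally)
    ``elaiosome_area_px``.  Returns one row per plant with the mean cover,
    the unbiased (n-1) cover variance — missing, not 0, for single-seed
    plants — the mean elaiosome area and the seed count.  Plants listed in
    ``plant_ids`` but absent from the seed table are excluded with a
    warning.
    """
    if "plant_id" not in seeds.columns:
        raise ValueError("seed table must carry a plant_id column")
    grouped = seeds.groupby("plant_id", sort=True)
    out = pd.DataFrame(
        {
            "mean_cover": grouped["spot_cover_pct"].mean(),
            "cover_variance": grouped["spot_cover_pct"].var(ddof=1),
            "n_seeds": grouped["spot_cover_pct"].size(),
        }
    )
    if "elaiosome_area_px" in seeds.columns:
        out["mean_elaiosome_area"] = grouped["elaiosome_area_px"].mean()
    if plant_ids is not None:
        missing = sorted(set(plant_ids) - set(out.index))
        if missing:
            warnings.warn(
                f"plants with zero seeds excluded: {', '.join(missing)}",
                stacklevel=2,
            )
    return out.reset_index()
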