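"""Synthetic reconstructions of the published assay logs.

The original removal logs were not deposited; only summary totals are in
print.  These builders produce deterministic, synthetic logs consistent
with those totals — the per-trial order is an even interleaving, not the
historical sequence — so the desk-reproducible summary statistics can be
recomputed from a concrete table.
"""

from __future__ import annotations

import pandas as pd

from fadseed.ant_preference import GridAssay
from fadseed.synthetic_data import checkerboard_layout

#: Published paired-trial totals: removals per category over 212 trials.
TRIAL_TOTALS = {"unspotted": 129, "spotted": 83}

#: Session sizes of the three experiment days (sums to 212).
TRIAL_SESSIONS = {"day_1": 30, "day_2": 15, "day_3": 167}

#: Grid-assay state after half the seeds were removed: seeds remaining.
GRID_HALF_REMAINING = {"unspotted": 8, "spotted": 24}


def _interleave(n_a: int, n_b: int, a: str, b: str) -> list[str]:
    """Deterministic even interleaving of n_a copies of a with n_b of b."""
    out, err = [], 0
    for _ in range(n_a + n_b):
        err += n_a
        if err * 2 >= n_a + n_b:
            out.append(a)
            err -= n_a + n_b
        else:
            out.append(b)
    # rounding can leave the tally off by the final element; patch the tail
    while out.count(a) > n_a:
        out[out.index(a)] = b
    while out.count(a) < n_a:
        out[out.index(b)] = a
    return out


def paired_trial_log() -> pd.DataFrame:
    """Synthetic 212-trial log matching the published per-category totals.

    129 unspotted and 83 spotted removals, evenly interleaved and split
    into the three published session sizes.
    """
    seq = _interleave(
        TRIAL_TOTALS["unspotted"], TRIAL_TOTALS["spotted"], "unspotted", "spotted"
    )
    rows, t = [], 0
    for session, size in TRIAL_SESSIONS.items():
        for _ in range(size):
            rows.append(
                {
                    "trial_id": t,
                    "session": session,
                    "time": t,
                    "removed_category": seq[t],
                }
            )
            t += 1
    return pd.DataFrame(rows)


def grid_assay_log() -> GridAssay:
    """Synthetic 8x8 checkerboard log matching the published half-removal state.

    The first 32 removals take 24 unspotted and 8 spotted seeds (so 8
    unspotted and 24 spotted remain at the half-removal mark); the
    remaining 32 events clear the board.  Within each phase the category
    sequence is an even interleaving and cells are taken in scan order.
    """
    layout = checkerboard_layout(8)
    cells = {
        cat: list(
            layout[layout.category == cat][["row", "col"]].itertuples(
                index=False, name=None
            )
        )
        for cat in ("unspotted", "spotted")
    }
    first = _interleave(24, 8, "unspotted", "spotted")
    second = _interleave(8, 24, "unspotted", "spotted")
    events = []
    for i, cat in enumerate(first + second, start=1):
        r, c = cells[cat].pop(0)
        events.append(
            {"event_index": i, "time": float(i), "row": r, "col": c, "category": cat}
        )
    return GridAssay(layout=layout, events=pd.DataFrame(events))
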