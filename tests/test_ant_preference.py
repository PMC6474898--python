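"""Paired-trial and grid ant-preference analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from fadseed import fixtures
from fadseed.ant_preference import (
    GridAssay,
    SeparationError,
    grid_rank_test,
    grid_state,
    random_removal_null,
    trial_mixed_logistic,
    trial_preference,
)
from fadseed.germination_analysis import rank_sum_test
from fadseed.synthetic_data import AssayGenParams, checkerboard_layout, generate_grid


def _trials(n_un, n_sp, times=None):
    cats = ["unspotted"] * n_un + ["spotted"] * n_sp
    n = len(cats)
    return pd.DataFrame(
        {
            "trial_id": range(n),
            "session": ["s"] * n,
            "time": times if times is not None else range(n),
            "removed_category": cats,
        }
    )


class TestTrialPreference:
    def test_published_totals_give_60_8_percent(self):
        res = trial_preference(fixtures.paired_trial_log())
        assert res.fractions["unspotted"] * 100 == pytest.approx(60.8, abs=0.05)
        assert res.removals == {"unspotted": 129, "spotted": 83}

    def test_balanced_removals_are_null(self):
        res = trial_preference(_trials(10, 10))
        assert res.fractions["unspotted"] == 0.5
        assert res.p_value == pytest.approx(1.0)

    def test_total_preference_exact_binomial_p(self):
        res = trial_preference(_trials(10, 0))
        assert res.p_value == pytest.approx(2 * 0.5**10)

    def test_category_swap_symmetry(self):
        t = _trials(14, 6)
        swapped = t.assign(
            removed_category=t["removed_category"].map(
                {"unspotted": "spotted", "spotted": "unspotted"}
            )
        )
        a, b = trial_preference(t), trial_preference(swapped)
        assert a.fractions["unspotted"] == pytest.approx(1 - b.fractions["unspotted"])
        assert a.odds_ratio == pytest.approx(1 / b.odds_ratio)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            trial_preference(_trials(0, 0))

    def test_sign_test_null_calibration(self, rng):
        """Type-I error of the sign test at alpha 0.05 over null replicates."""
        n_rep, n = 2000, 212
        rejections = 0
        for _ in range(n_rep):
            k = rng.binomial(n, 0.5)
            res = trial_preference(_trials(k, n - k))
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestTrialMixedLogistic:
    def test_reduces_to_raw_odds_ratio(self):
        # ten time points, identical 3 unspotted : 2 spotted composition
        frames = [
            _trials(3, 2, times=[t] * 5).assign(trial_id=range(5 * t, 5 * t + 5))
            for t in range(10)
        ]
        trials = pd.concat(frames, ignore_index=True)
        res = trial_mixed_logistic(trials)
        assert res.odds_ratio == pytest.approx(2 / 3, abs=1e-3)

    def test_complete_separation_rejected(self):
        with pytest.raises(SeparationError):
            trial_mixed_logistic(_trials(20, 0, times=[0] * 10 + [1] * 10))

    def test_single_time_point_rejected(self):
        with pytest.raises(ValueError, match="time points"):
            trial_mixed_logistic(_trials(5, 5, times=[0] * 10))


class TestGridState:
    def test_half_removal_matches_published_state(self):
        state = grid_state(fixtures.grid_assay_log(), 32).set_index("category")
        assert state.loc["unspotted", "remaining"] == 8
        assert state.loc["spotted", "remaining"] == 24

    @pytest.mark.parametrize("k,remaining", [(0, 32), (64, 0)])
    def test_boundary_states(self, k, remaining):
        state = grid_state(fixtures.grid_assay_log(), k).set_index("category")
        assert (state["remaining"] == remaining).all()

    def test_conservation_for_every_k(self):
        assay = generate_grid(AssayGenParams(grid_preference=0.7, seed=5))
        for k in range(0, 65, 8):
            state = grid_state(assay, k)
            assert (state["removed"] + state["remaining"] == state["initial"]).all()
            assert state["removed"].sum() == k

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 64\]"):
            grid_state(fixtures.grid_assay_log(), 65)

    def test_event_on_empty_cell_rejected(self):
        layout = checkerboard_layout(4)
        events = pd.DataFrame(
            {"event_index": [1], "time": [1.0], "row": [9], "col": [9]}
        )
        with pytest.raises(ValueError, match="empty cells"):
            GridAssay(layout=layout, events=events)

    def test_improper_coloring_rejected(self):
        layout = checkerboard_layout(4)
        layout.loc[0, "category"] = "spotted"  # clash with its neighbor
        with pytest.raises(ValueError, match="2-coloring"):
            GridAssay(layout=layout, events=pd.DataFrame(columns=["event_index", "time", "row", "col"]))


class TestGridRankTest:
    @staticmethod
    def _events_with_pattern(layout, pattern):
        pools = {
            cat: layout[layout.category == cat].reset_index(drop=True)
            for cat in ("unspotted", "spotted")
        }
        used = {cat: 0 for cat in pools}
        rows = []
        for i, cat in enumerate(pattern, start=1):
            src = pools[cat]
            rows.append(
                {
                    "event_index": i,
                    "time": float(i),
                    "row": src.loc[used[cat], "row"],
                    "col": src.loc[used[cat], "col"],
                }
            )
            used[cat] += 1
        return pd.DataFrame(rows)

    def test_balanced_interleaving_is_null(self):
        """A rank-balanced removal pattern (USSU repeated) is not significant.

        Note plain strict alternation USUS... keeps one category a single
        rank ahead throughout, which is a small systematic (not null)
        pattern; the USSU interleaving equalizes the rank sums exactly.
        """
        layout = fixtures.grid_assay_log().layout
        pattern = ["unspotted", "spotted", "spotted", "unspotted"] * 16
        res = grid_rank_test(
            GridAssay(layout=layout, events=self._events_with_pattern(layout, pattern))
        )
        assert res.p_value >= 0.9
        # plain alternation: slightly offset but still far from significant
        alt = ["unspotted", "spotted"] * 32
        res_alt = grid_rank_test(
            GridAssay(layout=layout, events=self._events_with_pattern(layout, alt))
        )
        assert res_alt.p_value >= 0.5

    def test_maximal_separation_vanishing_p(self):
        assay = generate_grid(AssayGenParams(grid_preference=1.0, seed=1))
        assert grid_rank_test(assay).p_value < 1e-10

    def test_delegates_to_shared_rank_sum(self):
        assay = generate_grid(AssayGenParams(grid_preference=0.7, seed=2))
        cats = assay.event_categories().to_numpy()
        ranks = np.arange(1, 65, dtype=float)
        ref = rank_sum_test(ranks[cats == "unspotted"], ranks[cats == "spotted"])
        res = grid_rank_test(assay)
        assert res.statistic == ref.statistic and res.p_value == ref.p_value


class TestRandomRemovalNull:
    def test_trivial_tail_is_one(self):
        assert random_removal_null(0, 32, 32, 64) == 1.0

    def test_impossible_count_is_zero(self):
        assert random_removal_null(33, 33, 32, 64) == 0.0

    def test_matches_direct_pmf_summation_and_monte_carlo(self, rng):
        # P(X >= 24) for 32 blind draws from 32 + 32 seeds
        p = random_removal_null(24, 32, 32, 64)
        direct = sum(
            math.comb(32, j) * math.comb(32, 32 - j) / math.comb(64, 32)
            for j in range(24, 33)
        )
        assert p == pytest.approx(direct, rel=1e-12)
        draws = rng.hypergeometric(32, 32, 32, size=1_000_000)
        mc = (draws >= 24).mean()
        se = math.sqrt(direct * (1 - direct) / 1_000_000)
        assert abs(mc - p) <= 3 * max(se, 1e-7)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            random_removal_null(5, 3, 32, 64)
        with pytest.raises(ValueError):
            random_removal_null(1, 2, 70, 64)
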