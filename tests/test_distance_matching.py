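"""Distance-binned curves, possession returns, and matching-law statistics."""

import numpy as np
import pandas as pd
import pytest

from helpers import build_table
from hooplearn.distance_matching import (
    bin_learning_curve,
    bin_pair_counts,
    compute_returns,
    make_bins,
    matching_analysis,
    return_vs_distance,
    select_players_bins,
    shooting_pct_curve,
)
from hooplearn.events_io import ShotTable


def _table_at_distances(entries, season="S1"):
    """Rows of (player, game, order, distance, outcome, pclass[, return])."""
    recs = []
    for e in entries:
        player, game, order, d, outcome, pclass = e[:6]
        ret = e[6] if len(e) > 6 else pd.NA
        recs.append(
            {
                "player_id": player,
                "season": season,
                "game_id": game,
                "order_in_game": order,
                "x_ft": 0.0,
                "y_ft": 5.25 + d,
                "outcome": outcome,
                "point_value": pclass,
                "return_points": ret,
            }
        )
    return ShotTable(pd.DataFrame(recs))


class TestBins:
    def test_make_bins_half_open_grid(self):
        bins = make_bins(2.0, (2.0, 8.0))
        assert bins == [(2.0, 4.0), (4.0, 6.0), (6.0, 8.0)]

    def test_empty_range_raises(self):
        with pytest.raises(ValueError):
            make_bins(2.0, (10.0, 10.0))

    def test_mean_distance_within_bin(self):
        t = _table_at_distances(
            [("A", "G1", 1, 22.1, "S", 2), ("A", "G1", 2, 23.9, "F", 2)]
        )
        c = bin_pair_counts(t, (22.0, 24.0, 2))
        assert float((c["dist_sum"] / c["attempts"]).iloc[0]) == pytest.approx(23.0)

    def test_classes_sharing_a_bin_are_separate_cells(self):
        t = _table_at_distances(
            [("A", "G1", 1, 23.0, "S", 2), ("A", "G1", 2, 23.9, "F", 3)]
        )
        assert int(bin_pair_counts(t, (22.0, 24.0, 2))["attempts"].sum()) == 1
        assert int(bin_pair_counts(t, (22.0, 24.0, 3))["attempts"].sum()) == 1


class TestSelection:
    def test_player_missing_a_make_in_one_bin_excluded(self):
        t = _table_at_distances(
            [
                ("A", "G1", 1, 3.0, "F", 2), ("A", "G1", 2, 3.0, "F", 2),
                ("A", "G1", 3, 10.0, "S", 2), ("A", "G1", 4, 10.0, "F", 2),
            ]
        )
        bins = [(2.0, 4.0, 2), (10.0, 12.0, 2)]
        assert select_players_bins(t, bins) == []

    def test_exactly_one_make_and_miss_everywhere_included(self):
        t = _table_at_distances(
            [
                ("A", "G1", 1, 3.0, "S", 2), ("A", "G1", 2, 3.0, "F", 2),
                ("A", "G1", 3, 10.0, "S", 2), ("A", "G1", 4, 10.0, "F", 2),
            ]
        )
        bins = [(2.0, 4.0, 2), (10.0, 12.0, 2)]
        assert select_players_bins(t, bins) == [("A", "S1")]

    def test_empty_bin_list_is_vacuous(self):
        t = _table_at_distances([("A", "G1", 1, 3.0, "S", 2)])
        assert select_players_bins(t, []) == [("A", "S1")]


class TestLearningCurve:
    def test_matches_brute_force_pair_count(self, rng):
        """learning_diff equals a hand enumeration of (antecedent, consequent)."""
        for _ in range(25):
            entries = []
            n = int(rng.integers(6, 14))
            for t in range(1, n + 1):
                d = float(rng.uniform(2, 28))
                pclass = 3 if d > 23.75 else 2
                entries.append(("A", "G1", t, d, "S" if rng.random() < 0.5 else "F", pclass))
            table = _table_at_distances(entries)
            bins = [(2.0, 24.0, 2)]  # one wide 2 pt cell
            curve = bin_learning_curve(table, bins=bins, players=[("A", "S1")])
            # brute force on the entry list
            num = {"S": [0, 0], "F": [0, 0]}
            for a, c in zip(entries[:-1], entries[1:]):
                if 2.0 <= a[3] < 24.0 and a[5] == 2:
                    num[a[4]][0] += 1
                    num[a[4]][1] += int(c[5] == 3)
            expected = np.nan
            if num["S"][0] and num["F"][0]:
                expected = num["S"][1] / num["S"][0] - num["F"][1] / num["F"][0]
            if np.isnan(expected):
                assert curve[0].n_players == 0
            else:
                assert curve[0].learning_diff == pytest.approx(expected)

    def test_memoryless_cohort_flat(self):
        from hooplearn.synthetic import planted_paper_scenario, generate_cohort

        cfg = planted_paper_scenario(n_players=30, learning_rate=0.0, seed=21)
        curve = bin_learning_curve(generate_cohort(cfg))
        for db in curve:
            if db.n_players >= 10 and np.isfinite(db.learning_diff_sem):
                assert abs(db.learning_diff) < 4 * db.learning_diff_sem


class TestShootingPct:
    def test_all_makes(self):
        t = _table_at_distances(
            [("A", "G1", t, 5.0, "S", 2) for t in range(1, 5)]
        )
        curve = shooting_pct_curve(t, bins=[(4.0, 6.0, 2)], players=[("A", "S1")])
        assert curve[0].shooting_pct == pytest.approx(1.0)

    def test_recovers_generative_difficulty(self):
        from hooplearn.synthetic import planted_paper_scenario, generate_cohort, default_difficulty

        cfg = planted_paper_scenario(n_players=40, seed=23)
        curve = shooting_pct_curve(generate_cohort(cfg))
        for db in curve:
            if db.n_players >= 20 and np.isfinite(db.shooting_pct_sem):
                q = float(default_difficulty(db.mean_distance))
                assert abs(db.shooting_pct - q) < 5 * db.shooting_pct_sem + 0.01


class TestComputeReturns:
    def test_scripted_possessions(self):
        logs = [
            [  # made 3, opponent ball next -> return 3
                ("shot", "A", "S1", "G1", 0.0, 30.0, "S"),
                ("opp",),
                # missed FG, teammate putback 2, then opponent ball -> return 2
                ("shot", "A", "S1", "G1", 0.0, 15.0, "F"),
                ("points", 2),
                ("opp",),
                # missed FG, opponent rebound -> return 0
                ("shot", "A", "S1", "G1", 0.0, 15.0, "F"),
                ("opp",),
            ]
        ]
        table = compute_returns(logs)
        assert list(table.df["return_points"]) == [3, 2, 0]
        assert list(table.df["point_value"]) == [3, 2, 2]

    def test_chained_possession_credits_all_open_shots(self):
        logs = [
            [
                ("shot", "A", "S1", "G1", 0.0, 15.0, "F"),
                ("shot", "A", "S1", "G1", 0.0, 10.0, "S"),  # own putback FG
                ("opp",),
            ]
        ]
        table = compute_returns(logs)
        assert list(table.df["return_points"]) == [2, 2]

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            compute_returns([[("steal",)]])


class TestMatching:
    def test_constructed_equality_sits_on_diagonal(self):
        # 2 of 5 attempts are 3 pt; equal per-attempt returns in both classes
        entries = [
            ("A", "G1", 1, 25.0, "S", 3, 3),
            ("A", "G1", 2, 25.0, "F", 3, 3),
            ("A", "G1", 3, 10.0, "S", 2, 2),
            ("A", "G1", 4, 10.0, "S", 2, 2),
            ("A", "G1", 5, 10.0, "S", 2, 5),
        ]
        records, summary = matching_analysis(_table_at_distances(entries))
        r = records[0]
        assert r.frac_3pt_attempts == pytest.approx(0.4)
        assert r.return_2pt == pytest.approx(3.0)
        assert r.return_3pt == pytest.approx(3.0)
        assert r.frac_3pt_income == pytest.approx(0.4)
        assert summary["matching_deviation"] == pytest.approx(0.0)

    def test_income_identity(self, rng):
        """frac_3pt_income equals sum of 3 pt returns over all returns, exactly."""
        entries = []
        for t in range(1, 40):
            is3 = rng.random() < 0.4
            d = 25.0 if is3 else 8.0
            made = rng.random() < 0.45
            ret = (3 if is3 else 2) if made else (2 if rng.random() < 0.2 else 0)
            entries.append(("A", "G1", t, d, "S" if made else "F", 3 if is3 else 2, ret))
        records, _ = matching_analysis(_table_at_distances(entries))
        df = _table_at_distances(entries).df
        manual = df.loc[df.point_value == 3, "return_points"].sum() / df["return_points"].sum()
        assert records[0].frac_3pt_income == pytest.approx(float(manual))

    def test_single_class_player_flagged(self):
        entries = [("A", "G1", t, 10.0, "S", 2, 2) for t in range(1, 5)]
        records, summary = matching_analysis(_table_at_distances(entries))
        assert records[0].flagged
        assert summary["n_included"] == 0


class TestReturnVsDistance:
    def test_all_miss_cohort_returns_zero(self):
        entries = [("A", "G1", t, 10.0, "F", 2, 0) for t in range(1, 6)]
        out = return_vs_distance(_table_at_distances(entries), bins=[(10.0, 12.0, 2)],
                                 players=[("A", "S1")])
        assert out[0].return_mean == pytest.approx(0.0)

    def test_constant_difficulty_closed_form(self):
        """q constant, no putbacks: 2 pt return 2q and 3 pt return 3q."""
        from hooplearn.synthetic import planted_paper_scenario, generate_cohort

        cfg = planted_paper_scenario(n_players=40, seed=31, learning_rate=0.0).with_(
            putback_prob=0.0
        )
        # flatten difficulty: every region equally makeable
        regions = tuple(r.__class__(**{**r.__dict__, "make_prob": 0.4}) for r in cfg.regions)
        cfg = cfg.with_(regions=regions)
        table = generate_cohort(cfg)
        out = return_vs_distance(table)
        for db in out:
            if db.n_players >= 20:
                expected = 0.4 * db.point_class
                assert db.return_mean == pytest.approx(expected, abs=0.05)

    def test_requires_returns(self):
        t = _table_at_distances([("A", "G1", 1, 10.0, "S", 2)])
        with pytest.raises(ValueError):
            return_vs_distance(t)
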