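"""Conditional-probability estimation and the learning matrix."""

import numpy as np
import pytest

from helpers import brute_force_conditionals, build_table, random_small_table, toy_map
from hooplearn.court import Group
from hooplearn.learning import (
    COARSE,
    ConditionalTable,
    EmptyTableError,
    LearningError,
    PlayerCounts,
    UndefinedColumnError,
    aggregate,
    coarse_matrix,
    cohort_learning,
    estimate_conditionals,
    learning_matrix,
    select_players_fine,
)

TOY2 = toy_map(2, {1: Group.THREE, 2: Group.SHORT2})


class TestEstimateConditionals:
    def test_hand_counted_toy(self):
        # one game: (r1, S), (r1, F), (r2, S)
        table = build_table(
            [("A", "G1", 1, 1, "S"), ("A", "G1", 2, 1, "F"), ("A", "G1", 3, 2, "S")]
        )
        ct = estimate_conditionals(table, TOY2)
        assert ct.prior == pytest.approx([2 / 3, 1 / 3])
        assert ct.cond_make[0] == pytest.approx([1.0, 0.0])  # (r1,S) -> r1
        assert ct.cond_miss[0] == pytest.approx([0.0, 1.0])  # (r1,F) -> r2
        assert np.isnan(ct.cond_make[1]).all()  # r2 never antecedent
        L = learning_matrix(ct)
        assert L.values[0] == pytest.approx([1.5, -3.0])
        assert list(L.valid) == [True, False]

    def test_pairs_never_cross_games(self):
        table = build_table([("A", "G1", 1, 1, "S"), ("A", "G2", 1, 2, "F")])
        ct = estimate_conditionals(table, TOY2)
        assert np.isnan(ct.cond_make).all() and np.isnan(ct.cond_miss).all()

    def test_empty_table_raises(self):
        table = build_table([("A", "G1", 1, 99, "S")])  # region outside the map
        with pytest.raises(EmptyTableError):
            estimate_conditionals(table, TOY2)

    def test_two_players_requires_key(self):
        table = build_table([("A", "G1", 1, 1, "S"), ("B", "G1", 1, 2, "F")])
        with pytest.raises(LearningError):
            estimate_conditionals(table, TOY2)
        ct = estimate_conditionals(table, TOY2, player_key=("A", "S1"))
        assert ct.prior == pytest.approx([1.0, 0.0])

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_brute_force_enumeration(self, seed):
        """Oracle equivalence against dict-counting on random small tables."""
        table = random_small_table(np.random.default_rng(seed))
        m = toy_map(4)
        for key in table.player_keys:
            P, cS, cF, n_pairs = brute_force_conditionals(table, m.labels, key)
            ct = estimate_conditionals(table, m, player_key=key)
            np.testing.assert_allclose(ct.prior, P, atol=1e-12)
            np.testing.assert_allclose(ct.cond_make, cS, atol=1e-12, equal_nan=True)
            np.testing.assert_allclose(ct.cond_miss, cF, atol=1e-12, equal_nan=True)
            assert int(ct.counts.pair_counts.sum()) == n_pairs


def _uniform_counts(R=4, labels=None):
    return PlayerCounts(
        ("A", "S1"), labels or tuple(range(1, R + 1)), "fine16",
        np.full(R, 10), np.zeros((2, R, R), dtype=int),
    )


class TestLearningMatrix:
    def test_no_learning_player_is_zero(self):
        # cond_make == cond_miss == prior => L == 0 identically
        R = 3
        pc = _uniform_counts(R)
        prior = np.full(R, 1 / R)
        ct = ConditionalTable(
            ("A", "S1"), pc.labels, "fine16", prior,
            np.tile(prior, (R, 1)), np.tile(prior, (R, 1)), pc,
        )
        L = learning_matrix(ct)
        assert np.allclose(L.values, 0.0)
        assert L.complete

    def test_extreme_repeat_after_make_player(self):
        # uniform prior 0.25; always repeat after S, never after F (uniform elsewhere)
        R = 4
        prior = np.full(R, 0.25)
        cond_make = np.eye(R)
        cond_miss = (1.0 - np.eye(R)) / (R - 1)
        ct = ConditionalTable(("A", "S1"), tuple(range(1, 5)), "fine16", prior,
                              cond_make, cond_miss, _uniform_counts(R))
        L = learning_matrix(ct)
        assert np.allclose(np.diag(L.values), 4.0)
        off = L.values[~np.eye(R, dtype=bool)]
        assert np.allclose(off, -4.0 / 3.0)

    def test_zero_prior_region_is_an_error(self):
        ct = ConditionalTable(
            ("A", "S1"), (1, 2), "fine16", np.array([1.0, 0.0]),
            np.full((2, 2), 0.5), np.full((2, 2), 0.5), _uniform_counts(2, (1, 2)),
        )
        with pytest.raises(UndefinedColumnError):
            learning_matrix(ct)


class TestCoarseMatrix:
    def test_grouped_toy_hand_count(self):
        # one pair (THREE,S)->THREE and one (THREE,F)->SHORT2, via 2 games
        m = toy_map(3, {1: Group.THREE, 2: Group.THREE, 3: Group.SHORT2})
        table = build_table(
            [
                ("A", "G1", 1, 1, "S"), ("A", "G1", 2, 2, "S"),
                ("A", "G2", 1, 1, "F"), ("A", "G2", 2, 3, "F"),
            ]
        )
        L = coarse_matrix(table, m)
        p_three = 0.75
        assert L.values[0, 0] == pytest.approx((1.0 - 0.0) / p_three)
        # the toy map has no LONG2 regions, so the coarse partition has 2 groups
        assert list(L.labels) == ["THREE", "SHORT2"]

    def test_memoryless_synthetic_player_is_zero(self):
        from hooplearn.synthetic import planted_paper_scenario, generate_cohort

        cfg = planted_paper_scenario(n_players=1, n_games=40, shots_per_game=25,
                                     learning_rate=0.0, seed=5)
        table = generate_cohort(cfg)
        L = coarse_matrix(table, __import__("hooplearn").SectorRegionMap())
        # finite-sample noise only: entries are zero-mean and small
        assert np.nanmax(np.abs(L.values)) < 0.5


class TestSelection:
    def _cohort(self, per_region, break_make_region=None):
        rows = []
        # alternate S/F so antecedent rows stay defined
        for g in range(per_region):
            game = f"G{g}"
            for t, reg in enumerate([1, 2, 1, 2], start=1):
                out = "S" if (t + g) % 2 else "F"
                if reg == break_make_region:
                    out = "F"
                rows.append(("A", game, t, reg, out))
        return build_table(rows)

    def test_count_threshold(self):
        table = self._cohort(5)  # 10 shots per region
        assert select_players_fine(table, TOY2, min_per_region=10) == [("A", "S1")]
        assert select_players_fine(table, TOY2, min_per_region=11) == []

    def test_ill_defined_row_excludes(self):
        table = self._cohort(6, break_make_region=1)  # no makes from region 1
        assert select_players_fine(table, TOY2, min_per_region=10) == []


class TestAggregate:
    def _mat(self, values):
        values = np.asarray(values, dtype=float)
        return learning_matrix(
            ConditionalTable(
                ("A", "S1"), (1, 2), "fine16", np.full(2, 0.5),
                np.full(2, 0.5) + values * 0.25, np.full(2, 0.5) - values * 0.25,
                _uniform_counts(2, (1, 2)),
            )
        )

    def test_identical_matrices(self):
        m = self._mat([[0.2, -0.2], [0.1, -0.1]])
        agg = aggregate([m, m])
        np.testing.assert_allclose(agg.mean, m.values)
        np.testing.assert_allclose(agg.sem, 0.0, atol=1e-15)

    def test_mean_of_zero_and_double(self):
        M = np.array([[0.4, -0.4], [0.2, -0.2]])
        agg = aggregate([self._mat(M * 0.0), self._mat(2.0 * M)])
        np.testing.assert_allclose(agg.mean, M, atol=1e-12)

    def test_requires_consistent_resolution(self):
        m = self._mat([[0.0, 0.0], [0.0, 0.0]])
        other = self._mat([[0.0, 0.0], [0.0, 0.0]])
        other.resolution = COARSE
        with pytest.raises(LearningError):
            aggregate([m, other])

    def test_duplicating_one_players_games_leaves_cohort_mean_unchanged(self):
        """Equal weighting: within-player duplication cannot shift the average."""
        rows_a = [("A", "G1", t, 1 + t % 2, "S" if t % 3 else "F") for t in range(1, 13)]
        rows_b = [("B", "G1", t, 1 + (t + 1) % 2, "F" if t % 3 else "S") for t in range(1, 13)]
        base = build_table(rows_a + rows_b)
        dup = build_table(
            rows_a + [("A", "G9", t, r, o) for (_, _, t, r, o) in rows_a] + rows_b
        )
        agg1, _ = cohort_learning(base, TOY2, min_per_region=1)
        agg2, _ = cohort_learning(dup, TOY2, min_per_region=1)
        np.testing.assert_allclose(agg1.mean, agg2.mean, atol=1e-12)


def test_outcome_shuffle_drives_matrix_to_zero(rng):
    """Zero-point: shuffling outcomes independently of locations kills learning."""
    from hooplearn.synthetic import planted_paper_scenario, generate_cohort
    from hooplearn import SectorRegionMap, OperantLearningModel

    cfg = planted_paper_scenario(n_players=30, n_games=40, shots_per_game=20,
                                 learning_rate=0.5, seed=7)
    table = generate_cohort(cfg)
    df = table.df.copy()
    df["outcome"] = rng.permutation(df["outcome"].to_numpy())
    df["return_points"] = None
    shuffled = type(table)(df)
    res = OperantLearningModel(shuffled, SectorRegionMap()).fit()
    z = np.sqrt((res.mean**2).sum() / (res.sem**2).sum())
    assert z < 3.0
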