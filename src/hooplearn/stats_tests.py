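"""Significance machinery: surrogate-sequence Monte-Carlo tests and the sign test.

The permutation null destroys outcome dependence while preserving marginals:
independently for each player, the prior region probabilities are estimated
from the data, and each consequent shot of every within-game pair is replaced
by an independent draw from that prior (antecedent locations and outcomes
untouched). Recomputing the statistic of interest on many such surrogates
yields its no-learning distribution; the reported p-value is the fraction of
repetitions in which the surrogate statistic strictly exceeded the observed
one (ties count as non-exceeding, the conservative direction). A p-value of
0 therefore means "p < 1/n_rep".

For the cohort statistics used here the surrogate draws enter only through
per-player multinomial/binomial counts, so repetitions are sampled directly
from those distributions rather than by materializing surrogate tables —
distributionally identical and orders of magnitude faster at the default
10^4 repetitions. :func:`surrogate_table` still materializes an explicit
surrogate table for inspection and unit testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hooplearn.court import Group, LabelRegionMap, RegionMap
from hooplearn.events_io import ShotTable
from hooplearn.learning import (
    FINE,
    MAKE,
    MISS,
    LearningError,
    cohort_counts,
    cohort_learning,
)

LEARNING_DIFF = "LEARNING_DIFF"
SHOOTING_PCT = "SHOOTING_PCT"


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact one-tailed upper binomial tail ``P(X >= k)`` for X ~ Bin(n, p0).

    Computed by direct summation of the exact terms.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a probability")
    return float(
        sum(math.comb(n, i) * p0**i * (1.0 - p0) ** (n - i) for i in range(k, n + 1))
    )


@dataclass
class PermutationResult:
    """Observed statistic, its surrogate distribution, and the Monte-Carlo p-value."""

    observed: float
    surrogate: np.ndarray
    n_rep: int
    seed: int | None
    statistic: str = "statistic"

    @property
    def p_value(self) -> float:
        return float(np.count_nonzero(self.surrogate > self.observed)) / self.n_rep

    def report(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": float(self.observed),
            "p_value": self.p_value,
            "p_floor": 1.0 / self.n_rep,
            "n_rep": self.n_rep,
            "seed": self.seed,
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p = self.p_value
        ptxt = f"p<{1.0 / self.n_rep:g}" if p == 0 else f"p={p:g}"
        return (
            f"PermutationResult({self.statistic}: observed={self.observed:.4g}, "
            f"{ptxt}, n_rep={self.n_rep})"
        )


def surrogate_table(
    table: ShotTable, region_map: RegionMap, rng_seed: int | None = None
) -> ShotTable:
    """Materialize one surrogate table.

    Per player, shots at within-game positions 2..N get a region drawn i.i.d.
    from that player's estimated prior (coordinates moved to the drawn
    region's representative point for geometric maps); outcomes and the game
    skeleton are untouched. Return points are cleared (they are meaningless
    after relocation).
    """
    rng = np.random.default_rng(rng_seed)
    df = table.df.copy()
    counts = cohort_counts(table, region_map, FINE)
    labels = np.array(region_map.labels)
    geometric = not isinstance(region_map, LabelRegionMap)
    if geometric:
        reps = np.array([region_map.representative_point(l) for l in region_map.labels])
    pv_of = np.array(
        [3 if region_map.group_of(l) is Group.THREE else 2 for l in region_map.labels]
    )
    for key, pc in counts.items():
        total = pc.prior_counts.sum()
        if total == 0:
            raise LearningError(f"player {key} has an undefined prior (no included shots)")
        prior = pc.prior_counts / total
        mask = (
            (df["player_id"] == key[0])
            & (df["season"] == key[1])
            & (df["order_in_game"] >= 2)
        ).to_numpy()
        draw = rng.choice(len(labels), size=int(mask.sum()), p=prior)
        if geometric:
            df.loc[mask, "x_ft"] = reps[draw, 0]
            df.loc[mask, "y_ft"] = reps[draw, 1]
        if "region" in df.columns:
            df.loc[mask, "region"] = labels[draw]
        df.loc[mask, "point_value"] = pv_of[draw]
    df["return_points"] = pd.NA
    return ShotTable(df, provenance=dict(table.provenance, surrogate_seed=rng_seed))


def _surrogate_offdiag_sds(
    counts: dict, players: list, n_rep: int, rng: np.random.Generator
) -> np.ndarray:
    """Off-diagonal SDs of surrogate cohort-average learning matrices.

    For each repetition and player, consequent counts for each (antecedent
    region, outcome) row are redrawn as Multinomial(n_row, prior); the
    player's surrogate learning index uses his original prior estimate, per
    the surrogate construction.
    """
    R = len(counts[players[0]].prior_counts)
    acc = np.zeros((n_rep, R, R))
    for key in players:
        pc = counts[key]
        prior = pc.prior_counts / pc.prior_counts.sum()
        n_rows = pc.ante_counts.reshape(2 * R)  # MAKE rows then MISS rows
        draws = rng.multinomial(n_rows, prior, size=(n_rep, 2 * R)).astype(float)
        cond = draws / n_rows[None, :, None]
        cond = cond.reshape(n_rep, 2, R, R)
        acc += (cond[:, MAKE] - cond[:, MISS]) / prior[None, None, :]
    mean = acc / len(players)
    off = ~np.eye(R, dtype=bool)
    return np.std(mean[:, off], axis=1, ddof=1)


def perm_test_offdiag_sd(
    table: ShotTable,
    region_map: RegionMap,
    n_rep: int = 10_000,
    seed: int | None = None,
    min_per_region: int = 10,
    resolution: str = FINE,
) -> PermutationResult:
    """Is the off-diagonal SD of the cohort learning matrix larger than chance?

    Observed: ``offdiag_sd`` of the player-averaged learning matrix over the
    players passing the fine selection. Null: surrogate cohorts with
    consequents redrawn from each player's prior.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    agg, players = cohort_learning(table, region_map, resolution, min_per_region)
    counts = cohort_counts(table, region_map, resolution)
    rng = np.random.default_rng(seed)
    surr = _surrogate_offdiag_sds(counts, players, n_rep, rng)
    return PermutationResult(agg.offdiag_sd, surr, n_rep, seed, "offdiag_sd")


def perm_test_bin_difference(
    table: ShotTable,
    bin_a: tuple[float, float, int],
    bin_b: tuple[float, float, int],
    statistic: str = LEARNING_DIFF,
    n_rep: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Between-bin difference test for two distance bins (e.g. the near-arc pair).

    Bins are ``(low_ft, high_ft, point_class)``. The observed statistic is the
    player-averaged difference (bin_a minus bin_b) of either the learning
    difference ``P(next 3 pt | make) - P(next 3 pt | miss)`` or the shooting
    percentage. Surrogates redraw each cell's successes from the player's
    pooled prior across the two bins.
    """
    from hooplearn.distance_matching import bin_pair_counts

    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if statistic not in (LEARNING_DIFF, SHOOTING_PCT):
        raise ValueError(f"unknown statistic: {statistic!r}")
    ca = bin_pair_counts(table, bin_a)
    cb = bin_pair_counts(table, bin_b)
    both = ca.join(cb, lsuffix="_a", rsuffix="_b", how="inner")
    if statistic == LEARNING_DIFF:
        ok = (
            (both["n_make_a"] > 0)
            & (both["n_miss_a"] > 0)
            & (both["n_make_b"] > 0)
            & (both["n_miss_b"] > 0)
        )
    else:
        ok = (both["attempts_a"] > 0) & (both["attempts_b"] > 0)
    both = both[ok]
    if len(both) == 0:
        raise ValueError("no player has populated cells in both bins")
    rng = np.random.default_rng(seed)

    if statistic == LEARNING_DIFF:
        nS_a = both["n_make_a"].to_numpy()
        kS_a = both["k3_make_a"].to_numpy()
        nF_a = both["n_miss_a"].to_numpy()
        kF_a = both["k3_miss_a"].to_numpy()
        nS_b = both["n_make_b"].to_numpy()
        kS_b = both["k3_make_b"].to_numpy()
        nF_b = both["n_miss_b"].to_numpy()
        kF_b = both["k3_miss_b"].to_numpy()
        observed = float(
            np.mean((kS_a / nS_a - kF_a / nF_a) - (kS_b / nS_b - kF_b / nF_b))
        )
        pooled = (kS_a + kF_a + kS_b + kF_b) / (nS_a + nF_a + nS_b + nF_b)
        size = (n_rep, len(both))
        dS_a = rng.binomial(nS_a, pooled, size=size) / nS_a
        dF_a = rng.binomial(nF_a, pooled, size=size) / nF_a
        dS_b = rng.binomial(nS_b, pooled, size=size) / nS_b
        dF_b = rng.binomial(nF_b, pooled, size=size) / nF_b
        surr = np.mean((dS_a - dF_a) - (dS_b - dF_b), axis=1)
    else:
        att_a = both["attempts_a"].to_numpy()
        mk_a = both["makes_a"].to_numpy()
        att_b = both["attempts_b"].to_numpy()
        mk_b = both["makes_b"].to_numpy()
        observed = float(np.mean(mk_a / att_a - mk_b / att_b))
        pooled = (mk_a + mk_b) / (att_a + att_b)
        size = (n_rep, len(both))
        pa = rng.binomial(att_a, pooled, size=size) / att_a
        pb = rng.binomial(att_b, pooled, size=size) / att_b
        surr = np.mean(pa - pb, axis=1)
    return PermutationResult(observed, surr, n_rep, seed, statistic.lower())
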