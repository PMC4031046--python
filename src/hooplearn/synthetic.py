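"""Generative model of shot sequences with planted, tunable generalization.

ONE_STEP mode (the exactly solvable model). Each player carries base region
weights ``w`` and a generalization kernel ``K``. The first attempt of a game
samples a region with probability proportional to ``w``; its outcome is
Bernoulli in the region's make probability ``q``. After an attempt from
region ``i`` that was made (S) / missed (F), the next attempt's weights are
``w_j * exp(+eta * K_ij)`` / ``w_j * exp(-eta * K_ij)``, the next region is
sampled proportionally, and the policy then resets to ``w`` (one-step
memory). The multiplicative-exponential update gives the outcome-conditioned
next-region distributions a closed softmax form, so every statistic the
pipeline estimates has an exact value, computed by
:func:`oracle_statistics` from the Markov chain on (region, outcome) states.
To first order in ``eta`` the planted learning matrix is
``L_ij ~ 2 eta (K_ij - sum_k P_k K_ik)``.

MELIORATION mode (matching-law demonstrations only). Players choose between
the 2 pt and 3 pt class with a propensity that drifts toward the class with
the higher recent per-attempt return, under diminishing returns (make
probability decreases with the class's attempt frequency) — melioration
dynamics whose fixed point equalizes class returns, i.e. the matching law.
Make probability also falls with distance within each class, so returns at a
finer distance resolution remain unequal even at the matching equilibrium.

Returns: a made FG contributes its point value; a missed FG yields a 2 pt
teammate putback with probability ``putback_prob``; no free throws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from hooplearn.court import (
    DEFAULT_REGION_MAP,
    GROUP_ORDER,
    Group,
    RegionMap,
    SectorRegionMap,
)
from hooplearn.events_io import ShotTable
from hooplearn.learning import MAKE, MISS

ONE_STEP = "ONE_STEP"
MELIORATION = "MELIORATION"


def default_difficulty(distance) -> np.ndarray:
    """Default make probability as a decreasing function of distance (ft).

    Roughly 0.6 close to the basket and 0.39 at the arc, the shape real
    shooting percentages follow.
    """
    return np.clip(0.63 - 0.0105 * np.asarray(distance, dtype=float), 0.05, 0.95)


@dataclass(frozen=True)
class SyntheticRegion:
    """One region of the generative model: label, group, emit point, policy weight, difficulty."""

    label: int
    group: Group
    x: float
    y: float
    weight: float
    make_prob: float

    def distance(self, basket_y: float = 5.25) -> float:
        return math.hypot(self.x, self.y - basket_y)


@dataclass(frozen=True)
class MeliorationParams:
    """Two-class melioration dynamics with diminishing, distance-dependent returns.

    ``q3 = q3_base - q3_freq_slope * f3 - dist_slope * (d - mid(band3))`` and
    symmetrically for the 2 pt class (``f3`` = recent 3 pt attempt frequency).
    ``lr`` scales the propensity drift toward the higher-return class; ``ema``
    is the smoothing constant of the frequency/return estimates.
    """

    theta0: float = 0.5
    lr: float = 0.01
    ema: float = 0.02
    q2_base: float = 0.50
    q2_freq_slope: float = 0.10
    band2: tuple[float, float] = (5.0, 20.0)
    q3_base: float = 0.36
    q3_freq_slope: float = 0.30
    band3: tuple[float, float] = (23.9, 27.0)
    dist_slope: float = 0.010
    burn_in_shots: int = 2000


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic cohort."""

    regions: tuple[SyntheticRegion, ...]
    kernel: np.ndarray  # (R, R) generalization kernel K_ij
    learning_rate: float = 0.3
    n_players: int = 100
    n_games: int = 50
    shots_per_game: int = 20
    putback_prob: float = 0.1
    mode: str = ONE_STEP
    seed: int = 0
    season: str = "SYN"
    melioration: MeliorationParams = field(default_factory=MeliorationParams)

    def __post_init__(self) -> None:
        w = self.weights
        if np.any(w <= 0):
            raise ValueError("region weights must be positive")
        q = self.make_probs
        if np.any((q < 0) | (q > 1)):
            raise ValueError("make probabilities must lie in [0, 1]")
        K = np.asarray(self.kernel, dtype=float)
        if K.shape != (len(self.regions),) * 2 or not np.all(np.isfinite(K)):
            raise ValueError("kernel must be a finite RxR matrix")
        object.__setattr__(self, "kernel", K)
        if self.shots_per_game < 2:
            raise ValueError("shots_per_game must be >= 2 for pair statistics")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.mode not in (ONE_STEP, MELIORATION):
            raise ValueError(f"unknown mode: {self.mode!r}")

    # -- convenience views --------------------------------------------------

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(r.label for r in self.regions)

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight for r in self.regions], dtype=float)

    @property
    def make_probs(self) -> np.ndarray:
        return np.array([r.make_prob for r in self.regions], dtype=float)

    @property
    def point_values(self) -> np.ndarray:
        return np.array(
            [3 if r.group is Group.THREE else 2 for r in self.regions], dtype=int
        )

    @property
    def group_codes(self) -> np.ndarray:
        return np.array([GROUP_ORDER.index(r.group) for r in self.regions], dtype=int)

    @property
    def distances(self) -> np.ndarray:
        return np.array([r.distance() for r in self.regions], dtype=float)

    @property
    def n_shots_per_player(self) -> int:
        return self.n_games * self.shots_per_game

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_region_map(
        cls,
        region_map: SectorRegionMap = DEFAULT_REGION_MAP,
        weights: Sequence[float] | dict[int, float] | None = None,
        difficulty: Callable = default_difficulty,
        kernel: np.ndarray | None = None,
        group_kernel: np.ndarray | None = None,
        points: dict[int, tuple[float, float]] | None = None,
        **kw,
    ) -> "SyntheticConfig":
        """Build a config whose regions mirror a geometric map.

        Each region emits shots at a fixed representative interior point, so
        the geometric pipeline recovers the generating region labels exactly.
        ``group_kernel`` is a 3x3 kernel over (THREE, LONG2, SHORT2) expanded
        to region level.
        """
        labels = region_map.labels
        R = len(labels)
        if weights is None:
            weights = {l: 1.0 for l in labels}
        elif not isinstance(weights, dict):
            weights = dict(zip(labels, weights))
        points = dict(points or {})
        regions = []
        for l in labels:
            x, y = points.get(l, region_map.representative_point(l))
            d = math.hypot(x - region_map.spec.basket_x, y - region_map.spec.basket_y)
            regions.append(
                SyntheticRegion(
                    l, region_map.group_of(l), x, y, float(weights[l]), float(difficulty(d))
                )
            )
        if kernel is None:
            gk = np.zeros((3, 3)) if group_kernel is None else np.asarray(group_kernel, float)
            gcodes = [GROUP_ORDER.index(r.group) for r in regions]
            kernel = gk[np.ix_(gcodes, gcodes)]
        return cls(regions=tuple(regions), kernel=np.asarray(kernel, float), **kw)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "learning_rate": self.learning_rate,
            "n_players": self.n_players,
            "n_games": self.n_games,
            "shots_per_game": self.shots_per_game,
            "putback_prob": self.putback_prob,
            "seed": self.seed,
            "season": self.season,
            "regions": [
                {
                    "label": r.label,
                    "group": r.group.value,
                    "x": r.x,
                    "y": r.y,
                    "weight": r.weight,
                    "make_prob": r.make_prob,
                }
                for r in self.regions
            ],
            "kernel": np.asarray(self.kernel).tolist(),
            "melioration": self.melioration.__dict__ | {
                "band2": list(self.melioration.band2),
                "band3": list(self.melioration.band3),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        regions = tuple(
            SyntheticRegion(
                int(r["label"]), Group(r["group"]), float(r["x"]), float(r["y"]),
                float(r["weight"]), float(r["make_prob"]),
            )
            for r in d["regions"]
        )
        meli = d.get("melioration")
        mp = MeliorationParams(
            **{**meli, "band2": tuple(meli["band2"]), "band3": tuple(meli["band3"])}
        ) if meli else MeliorationParams()
        return cls(
            regions=regions,
            kernel=np.asarray(d["kernel"], dtype=float),
            learning_rate=float(d.get("learning_rate", 0.3)),
            n_players=int(d.get("n_players", 100)),
            n_games=int(d.get("n_games", 50)),
            shots_per_game=int(d.get("shots_per_game", 20)),
            putback_prob=float(d.get("putback_prob", 0.1)),
            mode=d.get("mode", ONE_STEP),
            seed=int(d.get("seed", 0)),
            season=d.get("season", "SYN"),
            melioration=mp,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# closed-form policy pieces


def conditional_transitions(config: SyntheticConfig) -> np.ndarray:
    """(2, R, R) next-region distributions: [MAKE/MISS, antecedent, consequent].

    Row ``(o, i)`` is the softmax of ``log w + sign(o) * eta * K_i``.
    """
    logw = np.log(config.weights)
    eta = config.learning_rate
    K = config.kernel
    out = np.empty((2, len(logw), len(logw)))
    for sign, o in ((+1.0, MAKE), (-1.0, MISS)):
        z = logw[None, :] + sign * eta * K
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        out[o] = e / e.sum(axis=1, keepdims=True)
    return out


def base_policy(config: SyntheticConfig) -> np.ndarray:
    w = config.weights
    return w / w.sum()


# ---------------------------------------------------------------------------
# cohort generation


def _row_draw(cum_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Categorical draws from per-row CDFs ``cum_rows`` (n, R) given uniforms u (n,)."""
    return (cum_rows < u[:, None]).sum(axis=1)


def _generate_one_step(config: SyntheticConfig, rng: np.random.Generator):
    P, G, S = config.n_players, config.n_games, config.shots_per_game
    R = len(config.regions)
    p0 = base_policy(config)
    trans = conditional_transitions(config)
    q = config.make_probs
    cum0 = np.cumsum(p0)
    cumT = np.cumsum(trans, axis=2)

    regions = np.empty((G, S, P), dtype=np.int64)
    made = np.empty((G, S, P), dtype=bool)
    for g in range(G):
        r = np.searchsorted(cum0, rng.random(P))
        m = rng.random(P) < q[r]
        regions[g, 0], made[g, 0] = r, m
        for t in range(1, S):
            rows = cumT[np.where(m, MAKE, MISS), r]
            r = _row_draw(rows, rng.random(P))
            m = rng.random(P) < q[r]
            regions[g, t], made[g, t] = r, m
    # (G, S, P) -> per player, game, order
    regions = regions.transpose(2, 0, 1).reshape(-1)
    made = made.transpose(2, 0, 1).reshape(-1)
    return regions, made


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> ShotTable:
    """Simulate a cohort; bit-identical output for a fixed seed.

    ``seed`` overrides ``config.seed``. Draws are vectorized across players in
    lockstep from a single master stream.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    P, G, S = config.n_players, config.n_games, config.shots_per_game
    n = P * G * S

    if config.mode == ONE_STEP:
        regions, made = _generate_one_step(config, rng)
        xs = np.array([r.x for r in config.regions])[regions]
        ys = np.array([r.y for r in config.regions])[regions]
        pv = config.point_values[regions]
        region_labels = np.array(config.labels)[regions]
    else:
        xs, ys, pv, made = _generate_melioration(config, rng)
        region_labels = None

    putback = (~made) & (rng.random(n) < config.putback_prob)
    ret = np.where(made, pv, 0) + np.where(putback, 2, 0)

    df = pd.DataFrame(
        {
            "player_id": np.repeat([f"P{i:04d}" for i in range(P)], G * S),
            "season": config.season,
            "game_id": np.tile(np.repeat([f"G{g:04d}" for g in range(G)], S), P),
            "order_in_game": np.tile(np.arange(1, S + 1), P * G),
            "x_ft": xs,
            "y_ft": ys,
            "outcome": np.where(made, "S", "F"),
            "point_value": pv,
            "return_points": pd.array(ret, dtype="Int64"),
        }
    )
    if region_labels is not None:
        df["region"] = region_labels
    return ShotTable(
        df,
        provenance={
            "source": "synthetic",
            "mode": config.mode,
            "seed": int(config.seed if seed is None else seed),
        },
    )


def _generate_melioration(config: SyntheticConfig, rng: np.random.Generator):
    mp = config.melioration
    P = config.n_players
    T = config.n_games * config.shots_per_game
    mid2 = 0.5 * (mp.band2[0] + mp.band2[1])
    mid3 = 0.5 * (mp.band3[0] + mp.band3[1])

    theta = np.full(P, mp.theta0)
    f3 = theta.copy()
    # return estimates initialized at their expected values under theta0
    r2 = np.full(P, 2.0 * (mp.q2_base - mp.q2_freq_slope * (1 - mp.theta0)))
    r3 = np.full(P, 3.0 * (mp.q3_base - mp.q3_freq_slope * mp.theta0))

    is3 = np.empty((T, P), dtype=bool)
    dist = np.empty((T, P))
    made = np.empty((T, P), dtype=bool)
    for t in range(T):
        c3 = rng.random(P) < theta
        d = np.where(
            c3,
            mp.band3[0] + (mp.band3[1] - mp.band3[0]) * rng.random(P),
            mp.band2[0] + (mp.band2[1] - mp.band2[0]) * rng.random(P),
        )
        q = np.where(
            c3,
            mp.q3_base - mp.q3_freq_slope * f3 - mp.dist_slope * (d - mid3),
            mp.q2_base - mp.q2_freq_slope * (1 - f3) - mp.dist_slope * (d - mid2),
        )
        q = np.clip(q, 0.02, 0.98)
        m = rng.random(P) < q
        # realized return incl. putbacks (putback draw deferred to generate_cohort
        # for the table; the learner tracks the expected putback component)
        ret = np.where(m, np.where(c3, 3.0, 2.0), 0.0) + np.where(
            m, 0.0, 2.0 * config.putback_prob
        )
        f3 += mp.ema * (c3 - f3)
        r3[c3] += mp.ema * (ret[c3] - r3[c3])
        r2[~c3] += mp.ema * (ret[~c3] - r2[~c3])
        theta = np.clip(theta + mp.lr * (r3 - r2) * theta * (1 - theta), 0.02, 0.98)
        is3[t], dist[t], made[t] = c3, d, m

    # (T, P) -> player-major flat order
    is3 = is3.T.reshape(-1)
    dist = dist.T.reshape(-1)
    made = made.T.reshape(-1)
    xs = np.zeros(is3.size)
    ys = 5.25 + dist  # center axis: distance maps directly onto y
    pv = np.where(is3, 3, 2)
    return xs, ys, pv, made


# ---------------------------------------------------------------------------
# exact oracle


@dataclass
class OracleStatistics:
    """Exact population values of every ONE_STEP pipeline statistic.

    ``prior`` is the exact distribution of an attempt's region averaged over
    the ``shots_per_game`` within-game positions (the first attempt follows
    the base policy, later ones the chain), matching what the prior estimator
    measures. ``ante_weight[(o, i)]`` is the probability that a pair's
    antecedent is (region i, outcome o), used to pool exact conditionals over
    groups or distance bins. ``stationary`` is the chain's stationary law on
    (region, outcome) states.
    """

    config: SyntheticConfig
    labels: tuple
    prior: np.ndarray  # (R,)
    cond: np.ndarray  # (2, R, R) exact conditionals, [MAKE/MISS]
    learning: np.ndarray  # (R, R) exact L
    prior_coarse: np.ndarray  # (3,)
    cond_coarse: np.ndarray  # (2, 3, 3)
    learning_coarse: np.ndarray  # (3, 3)
    ante_weight: np.ndarray  # (2, R)
    stationary: np.ndarray  # (2, R)

    def bin_learning_diff(self, bin_: tuple[float, float, int]) -> float:
        """Exact ``P(next 3 pt | make) - P(next 3 pt | miss)`` for a distance-bin cell."""
        lo, hi, pclass = bin_
        cfg = self.config
        d = cfg.distances
        member = (d >= lo) & (d < hi) & (cfg.point_values == pclass)
        if not member.any():
            raise ValueError(f"no synthetic region falls in bin {bin_}")
        p_next3 = self.cond[:, :, cfg.group_codes == 0].sum(axis=2)  # (2, R)
        out = []
        for o in (MAKE, MISS):
            w = self.ante_weight[o] * member
            out.append(float((w / w.sum()) @ p_next3[o]))
        return out[0] - out[1]

    def bin_shooting_pct(self, bin_: tuple[float, float, int]) -> float:
        lo, hi, pclass = bin_
        cfg = self.config
        d = cfg.distances
        member = (d >= lo) & (d < hi) & (cfg.point_values == pclass)
        w = self.prior * member
        return float((w / w.sum()) @ cfg.make_probs)

    def class_returns(self) -> dict[int, float]:
        """Exact per-attempt return of the 2 pt and 3 pt classes."""
        cfg = self.config
        q, v = cfg.make_probs, cfg.point_values
        ret = q * v + (1 - q) * cfg.putback_prob * 2.0
        out = {}
        for pv in (2, 3):
            w = self.prior * (v == pv)
            out[pv] = float((w / w.sum()) @ ret) if w.sum() > 0 else np.nan
        return out


def oracle_statistics(config: SyntheticConfig) -> OracleStatistics:
    """Exact statistics of the ONE_STEP model via its (region, outcome) chain.

    The chain transition is ``P((i,o) -> (j,o')) = P(j|i,o) * q_j^[o'=S]
    (1-q_j)^[o'=F]``; position marginals within a game follow from iterating
    it from the base-policy law of the first attempt.
    """
    if config.mode != ONE_STEP:
        raise ValueError("oracle_statistics requires ONE_STEP mode")
    R = len(config.regions)
    q = config.make_probs
    p0 = base_policy(config)
    if np.any(p0 <= 0):
        raise ValueError("non-ergodic chain: some region has zero weight")
    trans = conditional_transitions(config)

    # state index s = o * R + i  (o = MAKE/MISS)
    out_prob = np.empty((2, R))
    out_prob[MAKE], out_prob[MISS] = q, 1.0 - q
    M = np.zeros((2 * R, 2 * R))
    for o in (MAKE, MISS):
        for op in (MAKE, MISS):
            M[o * R : (o + 1) * R, op * R : (op + 1) * R] = trans[o] * out_prob[op][None, :]

    mu = np.empty((config.shots_per_game, 2 * R))
    mu[0] = np.concatenate([p0 * q, p0 * (1 - q)])
    for t in range(1, config.shots_per_game):
        mu[t] = mu[t - 1] @ M

    prior = (mu.sum(axis=0) / config.shots_per_game).reshape(2, R).sum(axis=0)
    ante = mu[:-1].sum(axis=0).reshape(2, R)
    ante_weight = ante / ante.sum()

    learning = (trans[MAKE] - trans[MISS]) / prior[None, :]

    # coarse: conditionals pooled over antecedent groups with exact weights
    g = config.group_codes
    cond_coarse = np.zeros((2, 3, 3))
    for o in (MAKE, MISS):
        to_group = np.stack([trans[o][:, g == h].sum(axis=1) for h in range(3)], axis=1)
        for h in range(3):
            w = ante_weight[o] * (g == h)
            cond_coarse[o, h] = (w / w.sum()) @ to_group
    prior_coarse = np.array([prior[g == h].sum() for h in range(3)])
    learning_coarse = (cond_coarse[MAKE] - cond_coarse[MISS]) / prior_coarse[None, :]

    # stationary law of the chain (left eigenvector), for balance diagnostics
    vals, vecs = np.linalg.eig(M.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = pi / pi.sum()

    return OracleStatistics(
        config=config,
        labels=config.labels,
        prior=prior,
        cond=trans.copy(),
        learning=learning,
        prior_coarse=prior_coarse,
        cond_coarse=cond_coarse,
        learning_coarse=learning_coarse,
        ante_weight=ante_weight,
        stationary=pi.reshape(2, R),
    )


# ---------------------------------------------------------------------------
# the planted scenario


#: group-level kernel (rows/cols ordered THREE, LONG2, SHORT2): outcomes of
#: 3 pt attempts transfer mainly to 3 pt attempts; long 2 pt outcomes are
#: repeated at the expense of short 2 pt attempts and spill mildly onto 3 pt;
#: short 2 pt outcomes barely matter.
PLANTED_GROUP_KERNEL = np.array(
    [
        [1.20, 0.00, 0.15],
        [0.15, 0.45, -0.30],
        [0.00, 0.00, 0.10],
    ]
)

#: emit points overriding the defaults so that the near-arc 2 ft bin [22, 24)
#: contains both a 3 pt region (corner three at 23.1 ft) and a 2 pt region
#: (deep baseline two at 22.7 ft) — the corner/arc dissociation.
_NEAR_ARC_POINTS = {
    14: (22.5, 5.25 + math.sqrt(23.1**2 - 22.5**2)),  # corner 3, 23.1 ft
    15: (21.0, 5.25 + math.sqrt(22.7**2 - 21.0**2)),  # deep corner 2, 22.7 ft
}

#: base weights: heavy central region, moderate everywhere else (min share ~3%)
_PLANTED_WEIGHTS = {
    **{l: 4.0 for l in (1, 4, 7, 11, 14)},  # THREE
    **{l: 4.5 for l in (2, 5, 8, 12, 15)},  # LONG2
    **{l: 2.5 for l in (3, 6, 9, 10, 13)},  # SHORT2 bands
    16: 25.0,  # at the basket
}


def planted_paper_scenario(
    n_players: int = 100,
    n_games: int = 50,
    shots_per_game: int = 20,
    learning_rate: float = 0.3,
    seed: int = 0,
) -> SyntheticConfig:
    """The reference ONE_STEP scenario with categorical 2 pt/3 pt generalization.

    Its oracle learning matrix has the qualitative structure the pipeline is
    meant to detect: the (THREE, THREE) coarse entry is by far the largest;
    (LONG2, LONG2) is positive at the expense of (LONG2, SHORT2); short 2 pt
    outcomes have little effect; and the near-arc bins dissociate — the
    learning signal jumps across the 2 pt/3 pt boundary while the make
    probability varies smoothly with distance.
    """
    return SyntheticConfig.from_region_map(
        DEFAULT_REGION_MAP,
        weights=_PLANTED_WEIGHTS,
        group_kernel=PLANTED_GROUP_KERNEL,
        points=_NEAR_ARC_POINTS,
        learning_rate=learning_rate,
        n_players=n_players,
        n_games=n_games,
        shots_per_game=shots_per_game,
        seed=seed,
    )


def discard_burn_in(table: ShotTable, config: SyntheticConfig) -> ShotTable:
    """Drop each player's initial learning transient (MELIORATION analyses).

    Removes the first ``ceil(burn_in_shots / shots_per_game)`` games of every
    player, leaving the equilibrium portion of the sequence.
    """
    g0 = -(-config.melioration.burn_in_shots // config.shots_per_game)
    keep = table.df["game_id"] >= f"G{g0:04d}"
    out = ShotTable(
        table.df[keep].reset_index(drop=True),
        provenance=dict(table.provenance, burn_in_games=g0),
    )
    return out


def three_block_scenario(
    n_players: int = 200,
    n_games: int = 100,
    shots_per_game: int = 20,
    learning_rate: float = 0.3,
    seed: int = 0,
) -> SyntheticConfig:
    """ONE_STEP scenario with a pure 3-block kernel (within-group 1, between 0).

    Outcomes generalize fully within a coarse group and not at all across
    groups, planting sharp block structure in every learning-matrix row and
    column — the reference scenario for estimator-consistency and cluster
    recovery checks.
    """
    return SyntheticConfig.from_region_map(
        DEFAULT_REGION_MAP,
        weights=_PLANTED_WEIGHTS,
        group_kernel=np.eye(3),
        points=_NEAR_ARC_POINTS,
        learning_rate=learning_rate,
        n_players=n_players,
        n_games=n_games,
        shots_per_game=shots_per_game,
        seed=seed,
    )


#: the near-arc bin pair used by the dissociation analyses
NEAR_ARC_BIN_3PT = (22.0, 24.0, 3)
NEAR_ARC_BIN_2PT = (22.0, 24.0, 2)
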