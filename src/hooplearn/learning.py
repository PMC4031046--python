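"""Outcome-conditioned shot-location probabilities and the learning matrix.

For a player with region prior ``P_j`` (fraction of all included attempts
taken from region ``j``) and conditional next-shot probabilities
``P(j|S_i)`` / ``P(j|F_i)`` (region of the next within-game attempt given the
previous attempt was a make / miss from region ``i``), the learning matrix is

    L_ij = (P(j|S_i) - P(j|F_i)) / P_j

``L = 0`` for a player whose policy ignores outcomes (the two conditionals
coincide); a pure win-stay/lose-shift player has positive diagonal and
non-positive off-diagonal entries. ``L_ij > 0`` for ``i != j`` indicates
generalization: outcomes in ``i`` transfer to subsequent attempts from ``j``.

Estimation is per player-season ("player"), pairs are within-game only, and
cohort statistics weight every player equally. The matrix can be estimated at
the fine 16-region resolution or at the coarse 3-group resolution
(3 pt / long 2 pt / short 2 pt); the coarse matrix is re-estimated on grouped
events, not averaged from the fine matrix, because the index is nonlinear in
the underlying probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from hooplearn.court import NO_REGION, GROUP_ORDER, Group, LabelRegionMap, RegionMap
from hooplearn.events_io import PLAYER_KEYS, ShotTable, pair_indices

FINE = "fine16"
COARSE = "coarse3"

# outcome axis of pair-count arrays: index 0 = make (S), 1 = miss (F)
MAKE, MISS = 0, 1


class LearningError(ValueError):
    pass


class EmptyTableError(LearningError):
    pass


class UndefinedColumnError(LearningError):
    """A region with zero prior probability was included in the analysis."""


def resolve_codes(df: pd.DataFrame, region_map: RegionMap, resolution: str = FINE) -> np.ndarray:
    """Map each shot to an integer region code (0..R-1; -1 = excluded).

    Geometric maps assign from the coordinates; a :class:`LabelRegionMap`
    requires a stored ``region`` column.
    """
    if isinstance(region_map, LabelRegionMap):
        if "region" not in df.columns:
            raise LearningError("LabelRegionMap requires a stored 'region' column")
        labels = df["region"].to_numpy(dtype=int)
    else:
        labels = region_map.assign(df["x_ft"].to_numpy(), df["y_ft"].to_numpy())
    lookup = {lab: i for i, lab in enumerate(region_map.labels)}
    codes = np.array([lookup.get(int(l), -1) for l in labels], dtype=int)
    if resolution == COARSE:
        present = _present_groups(region_map)
        group_of_code = np.array(
            [present.index(region_map.group_of(lab)) for lab in region_map.labels]
        )
        codes = np.where(codes >= 0, group_of_code[np.clip(codes, 0, None)], -1)
    elif resolution != FINE:
        raise ValueError(f"unknown resolution: {resolution!r}")
    return codes


def _present_groups(region_map: RegionMap) -> list[Group]:
    """Coarse groups that actually occur in the map, in canonical order."""
    groups = {region_map.group_of(lab) for lab in region_map.labels}
    return [g for g in GROUP_ORDER if g in groups]


def _labels_for(region_map: RegionMap, resolution: str) -> tuple:
    if resolution == COARSE:
        return tuple(g.value for g in _present_groups(region_map))
    return tuple(region_map.labels)


@dataclass
class PlayerCounts:
    """Raw sufficient statistics for one player at one resolution."""

    player_key: tuple[str, str]
    labels: tuple
    resolution: str
    prior_counts: np.ndarray  # (R,) attempts per region, all included shots
    pair_counts: np.ndarray  # (2, R, R): [MAKE/MISS, antecedent, consequent]

    @property
    def n_shots(self) -> int:
        return int(self.prior_counts.sum())

    @property
    def ante_counts(self) -> np.ndarray:
        """(2, R) antecedent counts by outcome."""
        return self.pair_counts.sum(axis=2)


def _player_counts(
    df: pd.DataFrame, codes: np.ndarray, labels: tuple, resolution: str, key
) -> PlayerCounts:
    R = len(labels)
    keep = codes >= 0
    sub = df.loc[keep]
    kept_codes = codes[keep]
    prior_counts = np.bincount(kept_codes, minlength=R)
    pair_counts = np.zeros((2, R, R), dtype=np.int64)
    ia, ic = pair_indices(sub)
    if len(ia):
        out = np.where(sub["outcome"].to_numpy()[ia] == "S", MAKE, MISS)
        np.add.at(pair_counts, (out, kept_codes[ia], kept_codes[ic]), 1)
    return PlayerCounts(key, labels, resolution, prior_counts, pair_counts)


def cohort_counts(
    table: ShotTable, region_map: RegionMap, resolution: str = FINE
) -> dict[tuple[str, str], PlayerCounts]:
    """Sufficient statistics for every player in the table."""
    df = table.df
    codes = resolve_codes(df, region_map, resolution)
    labels = _labels_for(region_map, resolution)
    out: dict[tuple[str, str], PlayerCounts] = {}
    for key, idx in df.groupby(list(PLAYER_KEYS), sort=False).indices.items():
        idx = np.sort(idx)
        out[tuple(key)] = _player_counts(
            df.iloc[idx], codes[idx], labels, resolution, tuple(key)
        )
    return out


@dataclass
class ConditionalTable:
    """Per-player prior and outcome-conditioned next-region probabilities.

    Conditional rows are defined only where the player has at least one
    antecedent of the corresponding outcome from that region; undefined rows
    are NaN.
    """

    player_key: tuple[str, str]
    labels: tuple
    resolution: str
    prior: np.ndarray  # (R,)
    cond_make: np.ndarray  # (R, R), row i = P(. | S_i)
    cond_miss: np.ndarray  # (R, R), row i = P(. | F_i)
    counts: PlayerCounts

    @classmethod
    def from_counts(cls, pc: PlayerCounts) -> "ConditionalTable":
        n = pc.prior_counts.sum()
        if n == 0:
            raise EmptyTableError(f"player {pc.player_key} has no included shots")
        prior = pc.prior_counts / n
        ante = pc.ante_counts.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = pc.pair_counts / ante[:, :, None]
        cond[ante == 0] = np.nan
        return cls(
            pc.player_key, pc.labels, pc.resolution, prior, cond[MAKE], cond[MISS], pc
        )


def estimate_conditionals(
    table: ShotTable,
    region_map: RegionMap,
    resolution: str = FINE,
    player_key: tuple[str, str] | None = None,
) -> ConditionalTable:
    """Estimate a single player's :class:`ConditionalTable`.

    The table must contain exactly one player unless ``player_key`` selects
    one. Shots outside every region are dropped before pairing, so consecutive
    included shots within a game form the pairs.
    """
    if player_key is not None:
        table = table.for_player(player_key)
    keys = table.player_keys
    if len(keys) == 0:
        raise EmptyTableError("no shots in table")
    if len(keys) > 1:
        raise LearningError(f"table contains {len(keys)} players; pass player_key")
    df = table.df
    codes = resolve_codes(df, region_map, resolution)
    pc = _player_counts(df, codes, _labels_for(region_map, resolution), resolution, keys[0])
    return ConditionalTable.from_counts(pc)


@dataclass
class LearningMatrix:
    """A player's learning matrix with a row-validity mask."""

    values: np.ndarray  # (R, R); NaN on invalid rows
    valid: np.ndarray  # (R,) bool: row i valid iff both S_i and F_i rows defined
    labels: tuple
    resolution: str
    player_key: tuple[str, str] | None = None

    @property
    def complete(self) -> bool:
        return bool(self.valid.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def learning_matrix(ct: ConditionalTable) -> LearningMatrix:
    """Compute ``L_ij = (P(j|S_i) - P(j|F_i)) / P_j`` from a conditional table.

    Raises :class:`UndefinedColumnError` if some region has zero prior
    probability for this player (such regions must be excluded upstream).
    """
    if np.any(ct.prior == 0):
        bad = [ct.labels[i] for i in np.flatnonzero(ct.prior == 0)]
        raise UndefinedColumnError(
            f"player {ct.player_key}: zero prior probability for regions {bad}"
        )
    values = (ct.cond_make - ct.cond_miss) / ct.prior[None, :]
    valid = ~np.isnan(ct.cond_make).any(axis=1) & ~np.isnan(ct.cond_miss).any(axis=1)
    values[~valid] = np.nan
    return LearningMatrix(values, valid, ct.labels, ct.resolution, ct.player_key)


def coarse_matrix(
    table: ShotTable, region_map: RegionMap, player_key: tuple[str, str] | None = None
) -> LearningMatrix:
    """3x3 learning matrix over {THREE, LONG2, SHORT2}, re-estimated on grouped events."""
    return learning_matrix(estimate_conditionals(table, region_map, COARSE, player_key))


def select_players_fine(
    table: ShotTable,
    region_map: RegionMap,
    min_per_region: int = 10,
    resolution: str = FINE,
) -> list[tuple[str, str]]:
    """Players meeting the fine-analysis inclusion criteria.

    A player-season is included iff it has at least ``min_per_region`` attempts
    from every region and every learning-matrix row is well defined (at least
    one made and one missed antecedent from every region).
    """
    counts = cohort_counts(table, region_map, resolution)
    selected = []
    for key, pc in counts.items():
        if pc.prior_counts.min() >= min_per_region and (pc.ante_counts > 0).all():
            selected.append(key)
    return selected


@dataclass
class AggregateLearning:
    """Equal-weight player average of learning matrices, with SEM.

    ``diag_mean`` summarizes the win-stay/lose-shift tendency (mean diagonal of
    the averaged matrix); ``offdiag_sd`` the spatial heterogeneity of
    generalization (SD of its off-diagonal entries).
    """

    mean: np.ndarray
    sem: np.ndarray
    n_players: int
    labels: tuple
    resolution: str

    @property
    def diag_mean(self) -> float:
        return float(np.mean(np.diag(self.mean)))

    @property
    def offdiag_sd(self) -> float:
        off = self.mean[~np.eye(len(self.labels), dtype=bool)]
        return float(np.std(off, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean, index=list(self.labels), columns=list(self.labels))

    def report(self) -> dict:
        return {
            "resolution": self.resolution,
            "n_players": self.n_players,
            "diag_mean": self.diag_mean,
            "offdiag_sd": self.offdiag_sd,
        }


def aggregate(matrices: Sequence[LearningMatrix]) -> AggregateLearning:
    """Entrywise equal-weight mean and SEM over players.

    All matrices must share resolution and labels and be complete (every row
    valid) — players with any invalid row at this resolution are excluded from
    the analysis entirely, upstream.
    """
    if len(matrices) < 2:
        raise LearningError("need at least two matrices to aggregate")
    res = {m.resolution for m in matrices}
    if len(res) > 1:
        raise LearningError(f"mixed resolutions: {sorted(res)}")
    labs = {m.labels for m in matrices}
    if len(labs) > 1:
        raise LearningError("mixed label sets")
    if not all(m.complete for m in matrices):
        raise LearningError("aggregate requires complete matrices; filter players upstream")
    stack = np.stack([m.values for m in matrices])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(matrices))
    return AggregateLearning(mean, sem, len(matrices), matrices[0].labels, matrices[0].resolution)


def cohort_learning(
    table: ShotTable,
    region_map: RegionMap,
    resolution: str = FINE,
    min_per_region: int = 10,
    players: Iterable[tuple[str, str]] | None = None,
) -> tuple[AggregateLearning, list[tuple[str, str]]]:
    """Select players, estimate per-player matrices, and aggregate.

    Returns the aggregate and the list of included players. ``players``
    overrides the selection (used by permutation machinery).
    """
    counts = cohort_counts(table, region_map, resolution)
    if players is None:
        players = [
            k
            for k, pc in counts.items()
            if pc.prior_counts.min() >= min_per_region and (pc.ante_counts > 0).all()
        ]
    players = list(players)
    if len(players) < 2:
        raise LearningError(f"only {len(players)} players pass the selection criteria")
    mats = [learning_matrix(ConditionalTable.from_counts(counts[k])) for k in players]
    return aggregate(mats), players
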