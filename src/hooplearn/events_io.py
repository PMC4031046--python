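"""Canonical shot-event tables: schema, validation, CSV round-trip, pairing.

One row per field-goal attempt. Canonical CSV columns, in order::

    player_id,season,game_id,order_in_game,x_ft,y_ft,outcome,point_value,return_points

``outcome`` is ``S`` (made) or ``F`` (missed); ``return_points`` — the points
the shooter's team gained from the attempt until the opponent got possession —
may be empty (absent is not zero). ``order_in_game`` is the 1-based index of
the attempt within the player's own sequence for that game; a valid table has
a contiguous 1..N sequence per (player, season, game).

A "player" is a player-season: all analyses key on ``(player_id, season)`` and
never pool a player across seasons. Pairing of consecutive shots is within a
game only — the outcome of shots 1..N-1 is related to the locations of shots
2..N, never across a game boundary.

Tables may carry an optional ``region`` column (precomputed region labels);
it is not part of the canonical CSV and is dropped on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from hooplearn.court import CourtSpec, shot_distance

CANONICAL_COLUMNS = (
    "player_id",
    "season",
    "game_id",
    "order_in_game",
    "x_ft",
    "y_ft",
    "outcome",
    "point_value",
    "return_points",
)

GROUP_KEYS = ("player_id", "season", "game_id")
PLAYER_KEYS = ("player_id", "season")

#: slack added to the half-court diagonal when checking shot distances
DISTANCE_MARGIN_FT = 10.0


class SchemaError(ValueError):
    """The file/frame does not have the canonical column set."""


class ValidationError(ValueError):
    """Rows violate a table invariant; the message names offending groups."""


class ShotEvent(NamedTuple):
    """A single field-goal attempt."""

    player_id: str
    season: str
    game_id: str
    order_in_game: int
    x_ft: float
    y_ft: float
    outcome: str
    point_value: int
    return_points: int | None = None

    @property
    def made(self) -> bool:
        return self.outcome == "S"


@dataclass
class ShotTable:
    """An ordered, validated collection of shot events.

    Thin wrapper over a :class:`pandas.DataFrame` with the canonical columns
    (plus optional extras such as ``region``), stably sorted by
    (player, season, game, order). ``provenance`` records where the table came
    from (e.g. the seed of a synthetic cohort).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _normalize(self.df)
        _validate(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def player_keys(self) -> list[tuple[str, str]]:
        """Unique (player_id, season) keys, in table order."""
        seen = self.df[list(PLAYER_KEYS)].drop_duplicates()
        return list(map(tuple, seen.itertuples(index=False)))

    def for_player(self, key: tuple[str, str]) -> "ShotTable":
        pid, season = key
        sub = self.df[(self.df["player_id"] == pid) & (self.df["season"] == season)]
        out = object.__new__(ShotTable)
        out.df = sub.reset_index(drop=True)
        out.provenance = dict(self.provenance, player=key)
        return out

    def events(self) -> Iterator[ShotEvent]:
        for row in self.df.itertuples(index=False):
            rp = row.return_points
            yield ShotEvent(
                row.player_id,
                row.season,
                row.game_id,
                int(row.order_in_game),
                float(row.x_ft),
                float(row.y_ft),
                row.outcome,
                int(row.point_value),
                None if pd.isna(rp) else int(rp),
            )

    def equals(self, other: "ShotTable") -> bool:
        a = self.df[list(CANONICAL_COLUMNS)].reset_index(drop=True)
        b = other.df[list(CANONICAL_COLUMNS)].reset_index(drop=True)
        return a.equals(b)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing canonical columns: {missing}")
    df = df.copy()
    for col in ("player_id", "season", "game_id", "outcome"):
        df[col] = df[col].astype(str)
    df["order_in_game"] = pd.to_numeric(df["order_in_game"]).astype(int)
    df["x_ft"] = pd.to_numeric(df["x_ft"]).astype(float)
    df["y_ft"] = pd.to_numeric(df["y_ft"]).astype(float)
    df["point_value"] = pd.to_numeric(df["point_value"]).astype(int)
    df["return_points"] = pd.to_numeric(df["return_points"], errors="coerce").astype("Int64")
    extras = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    df = df[list(CANONICAL_COLUMNS) + extras]
    return df.sort_values(
        ["player_id", "season", "game_id", "order_in_game"], kind="stable"
    ).reset_index(drop=True)


def _validate(df: pd.DataFrame, spec: CourtSpec = CourtSpec()) -> None:
    problems: list[str] = []
    bad_outcome = ~df["outcome"].isin(["S", "F"])
    if bad_outcome.any():
        problems.append(f"invalid outcome values in rows {list(df.index[bad_outcome][:5])}")
    bad_pv = ~df["point_value"].isin([2, 3])
    if bad_pv.any():
        problems.append(f"point_value outside {{2,3}} in rows {list(df.index[bad_pv][:5])}")
    if not np.isfinite(df["x_ft"]).all() or not np.isfinite(df["y_ft"]).all():
        problems.append("non-finite coordinates")
    else:
        d = shot_distance(df["x_ft"].to_numpy(), df["y_ft"].to_numpy(), spec)
        too_far = d > spec.half_court_y + DISTANCE_MARGIN_FT
        if np.any(too_far):
            problems.append(f"shot distance beyond half court in rows {list(df.index[too_far][:5])}")
        if (df["y_ft"].to_numpy() < 0).any():
            problems.append("negative y_ft")
    rp = df["return_points"]
    present = rp.notna()
    if present.any():
        if (rp[present] < 0).any():
            problems.append("negative return_points")
        made = present & (df["outcome"] == "S")
        short = made & (rp < df["point_value"]).fillna(False)
        if short.any():
            problems.append(
                "made shots with return_points below their point value in rows "
                f"{list(df.index[short][:5])}"
            )
    # contiguous 1..N order within each player-game
    for key, grp in df.groupby(list(GROUP_KEYS), sort=False):
        orders = np.sort(grp["order_in_game"].to_numpy())
        if not np.array_equal(orders, np.arange(1, len(orders) + 1)):
            problems.append(f"non-contiguous order_in_game for group {key}")
    if problems:
        raise ValidationError("; ".join(problems))


def read_shot_table(path, dialect: str = "canonical") -> ShotTable:
    """Read and validate a canonical shot CSV."""
    if dialect != "canonical":
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, dtype={"player_id": str, "season": str, "game_id": str})
    table = ShotTable(df, provenance={"source": str(path)})
    return table


def write_shot_table(table: ShotTable, path) -> None:
    """Write a table as canonical CSV (fixed column order; absent returns stay empty)."""
    out = table.df[list(CANONICAL_COLUMNS)].copy()
    out.to_csv(path, index=False)


def pair_indices(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Integer row positions of (antecedent, consequent) within-game pairs.

    The frame must be in canonical sort order. Rows ``i`` and ``i+1`` form a
    pair iff they belong to the same (player, season, game); with contiguous
    orders this is exactly the shots-(1..N-1, 2..N) pairing.
    """
    if len(df) < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    same = np.ones(len(df) - 1, dtype=bool)
    for col in GROUP_KEYS:
        v = df[col].to_numpy()
        same &= v[:-1] == v[1:]
    idx = np.flatnonzero(same)
    return idx, idx + 1


def consecutive_pairs(
    table: ShotTable, player_key: tuple[str, str] | None = None
) -> list[tuple[ShotEvent, ShotEvent]]:
    """Within-game consecutive shot pairs, optionally for a single player.

    Returns exactly ``sum(N_g - 1)`` pairs over the games ``g``; no pair spans
    a game boundary. A player whose games all contain a single shot yields an
    empty list.
    """
    sub = table.for_player(player_key) if player_key is not None else table
    events = list(sub.events())
    ia, ic = pair_indices(sub.df)
    return [(events[a], events[c]) for a, c in zip(ia, ic)]
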