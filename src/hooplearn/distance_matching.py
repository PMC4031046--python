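"""Distance-resolved learning and difficulty curves, returns, and matching.

Shots are sorted into 2 ft wide half-open distance bins ``[lo, hi)``,
separately for 2 pt and 3 pt attempts (the 22–23.75 ft band contains both
classes, at different angles). Per bin and player the module computes the
scalar learning signal ``P(next FG is 3 pt | make) - P(next FG is 3 pt | miss)``
(consequent = the player's next within-game attempt), the shooting percentage
(makes/attempts, a difficulty proxy), and the mean return; cohort curves are
equal-weight player averages with SEM.

The return of a field goal is the number of points the shooter's team gained
from the attempt until the opponent got possession (its own points if made,
plus any subsequent team points — e.g. putbacks — before the change of
possession). Matching-law statistics compare each player's fraction of 3 pt
attempts with his fractional 3 pt income; equal per-attempt returns across
the two classes put a player exactly on the matching diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hooplearn.court import CourtSpec, classify_point_value, shot_distance
from hooplearn.events_io import PLAYER_KEYS, ShotTable, pair_indices

BinSpec = tuple[float, float, int]  # (low_ft, high_ft, point_class)


@dataclass
class DistanceBin:
    """Cohort summary of one (distance bin, point class) cell."""

    edge_low: float
    edge_high: float
    point_class: int
    n_players: int = 0
    mean_distance: float = np.nan
    p3_make: float = np.nan
    p3_miss: float = np.nan
    learning_diff: float = np.nan
    learning_diff_sem: float = np.nan
    shooting_pct: float = np.nan
    shooting_pct_sem: float = np.nan
    return_mean: float = np.nan
    return_sem: float = np.nan

    @property
    def spec(self) -> BinSpec:
        return (self.edge_low, self.edge_high, self.point_class)


def make_bins(
    bin_width: float = 2.0, drange: tuple[float, float] = (2.0, 30.0)
) -> list[tuple[float, float]]:
    """Half-open bin edges ``[lo, lo+w)`` covering the analysis range."""
    lo, hi = drange
    if not hi > lo or bin_width <= 0:
        raise ValueError("empty distance range or non-positive bin width")
    edges = np.arange(lo, hi + 1e-9, bin_width)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def _bin_membership(df: pd.DataFrame, bin_: BinSpec, spec: CourtSpec) -> np.ndarray:
    lo, hi, pclass = bin_
    d = shot_distance(df["x_ft"].to_numpy(), df["y_ft"].to_numpy(), spec)
    return (d >= lo) & (d < hi) & (df["point_value"].to_numpy() == pclass)


def bin_pair_counts(
    table: ShotTable, bin_: BinSpec, spec: CourtSpec = CourtSpec()
) -> pd.DataFrame:
    """Per-player raw counts for one bin cell.

    Columns: ``attempts``, ``makes`` (all shots in the cell), ``n_make``,
    ``k3_make``, ``n_miss``, ``k3_miss`` (antecedent shots in the cell that
    have a within-game consequent, split by outcome; ``k3`` counts consequents
    that are 3 pt attempts), ``dist_sum`` (for mean distances),
    ``return_sum``/``return_n`` (over shots with recorded returns).
    """
    df = table.df
    member = _bin_membership(df, bin_, spec)
    ia, ic = pair_indices(df)
    made = (df["outcome"].to_numpy() == "S")
    next_is_3 = np.zeros(len(df), dtype=bool)
    has_next = np.zeros(len(df), dtype=bool)
    next_is_3[ia] = df["point_value"].to_numpy()[ic] == 3
    has_next[ia] = True

    d = shot_distance(df["x_ft"].to_numpy(), df["y_ft"].to_numpy(), spec)
    rp = df["return_points"]
    rp_present = rp.notna().to_numpy()
    rp_vals = rp.fillna(0).to_numpy(dtype=float)

    g = df.loc[member, list(PLAYER_KEYS)]
    frame = pd.DataFrame(
        {
            "player_id": g["player_id"],
            "season": g["season"],
            "attempts": 1,
            "makes": made[member].astype(int),
            "n_make": (made & has_next)[member].astype(int),
            "k3_make": (made & has_next & next_is_3)[member].astype(int),
            "n_miss": (~made & has_next)[member].astype(int),
            "k3_miss": (~made & has_next & next_is_3)[member].astype(int),
            "dist_sum": d[member],
            "return_sum": np.where(rp_present[member], rp_vals[member], 0.0),
            "return_n": rp_present[member].astype(int),
        }
    )
    return frame.groupby(list(PLAYER_KEYS)).sum()


def select_players_bins(
    table: ShotTable, bins: Sequence[BinSpec], spec: CourtSpec = CourtSpec()
) -> list[tuple[str, str]]:
    """Players with at least one make and one miss in every listed bin cell.

    An empty bin list is vacuous: every player is included.
    """
    keys = set(table.player_keys)
    for b in bins:
        c = bin_pair_counts(table, b, spec)
        ok = c[(c["makes"] > 0) & (c["makes"] < c["attempts"])].index
        keys &= set(map(tuple, ok))
    return [k for k in table.player_keys if k in keys]


def _cohort_bins(
    table: ShotTable,
    bins: Sequence[BinSpec],
    spec: CourtSpec,
    players: Iterable[tuple[str, str]] | None,
) -> tuple[list[pd.DataFrame], list[tuple[str, str]]]:
    counts = [bin_pair_counts(table, b, spec) for b in bins]
    if players is None:
        players = select_players_bins(table, bins, spec)
    players = list(players)
    return [c.reindex(players, fill_value=0) for c in counts], players


def _mean_sem(values: np.ndarray) -> tuple[float, float, int]:
    values = values[np.isfinite(values)]
    n = len(values)
    if n == 0:
        return np.nan, np.nan, 0
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return float(np.mean(values)), sem, n


def candidate_bins(
    table: ShotTable,
    bin_width: float = 2.0,
    drange: tuple[float, float] = (2.0, 30.0),
    spec: CourtSpec = CourtSpec(),
    min_shots: int = 1,
) -> list[BinSpec]:
    """All (bin, point-class) cells with at least ``min_shots`` cohort shots."""
    out = []
    for lo, hi in make_bins(bin_width, drange):
        for pclass in (2, 3):
            if _bin_membership(table.df, (lo, hi, pclass), spec).sum() >= min_shots:
                out.append((lo, hi, pclass))
    return out


def _warn_on_value_mismatch(table: ShotTable, spec: CourtSpec) -> None:
    derived = classify_point_value(
        table.df["x_ft"].to_numpy(), table.df["y_ft"].to_numpy(), spec
    )
    n_bad = int((derived != table.df["point_value"].to_numpy()).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} shots have recorded point_value inconsistent with their "
            "coordinates; the recorded value is used",
            stacklevel=3,
        )


def bin_learning_curve(
    table: ShotTable,
    bin_width: float = 2.0,
    drange: tuple[float, float] = (2.0, 30.0),
    spec: CourtSpec = CourtSpec(),
    bins: Sequence[BinSpec] | None = None,
    players: Iterable[tuple[str, str]] | None = None,
) -> list[DistanceBin]:
    """Distance-resolved learning curve (2 pt and 3 pt cells separately).

    Players default to those with >= 1 make and miss in every non-empty cell;
    per player and cell the learning difference uses the antecedent shots with
    a within-game consequent, and the cohort value is the equal-weight player
    mean (players without both conditionals defined in a cell are skipped in
    that cell; ``n_players`` records the per-cell count).
    """
    _warn_on_value_mismatch(table, spec)
    if bins is None:
        bins = candidate_bins(table, bin_width, drange, spec)
    if not bins:
        raise ValueError("no populated bins in range")
    counts, players = _cohort_bins(table, bins, spec, players)
    out = []
    for b, c in zip(bins, counts):
        with np.errstate(invalid="ignore", divide="ignore"):
            p3m = c["k3_make"] / c["n_make"]
            p3x = c["k3_miss"] / c["n_miss"]
            diff = (p3m - p3x).to_numpy(dtype=float)
            dist = (c["dist_sum"] / c["attempts"]).to_numpy(dtype=float)
        mean, sem, n = _mean_sem(diff)
        db = DistanceBin(*b, n_players=n)
        db.mean_distance = _mean_sem(dist)[0]
        db.p3_make = _mean_sem(p3m.to_numpy(dtype=float))[0]
        db.p3_miss = _mean_sem(p3x.to_numpy(dtype=float))[0]
        db.learning_diff, db.learning_diff_sem = mean, sem
        out.append(db)
    return out


def shooting_pct_curve(
    table: ShotTable,
    bins: Sequence[BinSpec] | None = None,
    bin_width: float = 2.0,
    drange: tuple[float, float] = (2.0, 30.0),
    spec: CourtSpec = CourtSpec(),
    players: Iterable[tuple[str, str]] | None = None,
) -> list[DistanceBin]:
    """Shooting percentage (makes/attempts) per distance bin and point class."""
    if bins is None:
        bins = candidate_bins(table, bin_width, drange, spec)
    counts, players = _cohort_bins(table, bins, spec, players)
    out = []
    for b, c in zip(bins, counts):
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = (c["makes"] / c["attempts"]).to_numpy(dtype=float)
            dist = (c["dist_sum"] / c["attempts"]).to_numpy(dtype=float)
        mean, sem, n = _mean_sem(pct)
        db = DistanceBin(*b, n_players=n)
        db.mean_distance = _mean_sem(dist)[0]
        db.shooting_pct, db.shooting_pct_sem = mean, sem
        out.append(db)
    return out


def return_vs_distance(
    table: ShotTable,
    bins: Sequence[BinSpec] | None = None,
    bin_width: float = 2.0,
    drange: tuple[float, float] = (2.0, 30.0),
    spec: CourtSpec = CourtSpec(),
    players: Iterable[tuple[str, str]] | None = None,
) -> list[DistanceBin]:
    """Mean return per distance bin and point class (requires recorded returns)."""
    if table.df["return_points"].isna().all():
        raise ValueError("table has no recorded return_points")
    if bins is None:
        bins = candidate_bins(table, bin_width, drange, spec)
    counts, players = _cohort_bins(table, bins, spec, players)
    out = []
    for b, c in zip(bins, counts):
        with np.errstate(invalid="ignore", divide="ignore"):
            ret = (c["return_sum"] / c["return_n"]).to_numpy(dtype=float)
            dist = (c["dist_sum"] / c["attempts"]).to_numpy(dtype=float)
        mean, sem, n = _mean_sem(ret)
        db = DistanceBin(*b, n_players=n)
        db.mean_distance = _mean_sem(dist)[0]
        db.return_mean, db.return_sem = mean, sem
        out.append(db)
    return out


# ---------------------------------------------------------------------------
# returns from possession logs


def compute_returns(possessions: Iterable[Sequence], spec: CourtSpec = CourtSpec()) -> ShotTable:
    """Build a shot table with returns from explicit possession logs.

    ``possessions`` is an iterable of game logs; each log is a sequence of
    events for one (season, game), from the perspective of the shooting
    player's team:

    - ``("shot", player_id, season, game_id, x_ft, y_ft, outcome)`` — a
      tracked field-goal attempt (point value derived from the coordinates);
    - ``("points", p)`` — additional team points (e.g. a teammate putback);
    - ``("opp",)`` — the opposing team gains possession.

    The return of each FG is the sum of team points from that attempt
    (inclusive of its own, if made) until the next change of possession.
    """
    rows: list[dict] = []
    returns: list[int] = []
    order_counter: dict[tuple, int] = {}
    for log in possessions:
        open_shots: list[int] = []
        for ev in log:
            kind = ev[0]
            if kind == "shot":
                _, pid, season, game, x, y, outcome = ev
                pv = int(classify_point_value(float(x), float(y), spec))
                key = (pid, season, game)
                order_counter[key] = order_counter.get(key, 0) + 1
                rows.append(
                    {
                        "player_id": pid,
                        "season": season,
                        "game_id": game,
                        "order_in_game": order_counter[key],
                        "x_ft": float(x),
                        "y_ft": float(y),
                        "outcome": outcome,
                        "point_value": pv,
                    }
                )
                returns.append(0)
                open_shots.append(len(rows) - 1)
                if outcome == "S":
                    for i in open_shots:
                        returns[i] += pv
            elif kind == "points":
                for i in open_shots:
                    returns[i] += int(ev[1])
            elif kind == "opp":
                open_shots = []
            else:
                raise ValueError(f"unknown possession event: {ev!r}")
        # end of log closes the window
    df = pd.DataFrame(rows)
    df["return_points"] = pd.array(returns, dtype="Int64")
    return ShotTable(df, provenance={"source": "possession-log"})


# ---------------------------------------------------------------------------
# matching law


@dataclass
class MatchingRecord:
    """Per-player matching-law quantities."""

    player_key: tuple[str, str]
    n_attempts: int
    frac_3pt_attempts: float
    frac_3pt_income: float
    return_2pt: float
    return_3pt: float
    flagged: bool = False  # zero attempts of a class or zero income

    @property
    def matching_deviation(self) -> float:
        return abs(self.frac_3pt_attempts - self.frac_3pt_income)


def matching_analysis(
    table: ShotTable,
) -> tuple[list[MatchingRecord], dict]:
    """Per-player attempt/income fractions and returns, plus cohort summary.

    Uses shots with recorded returns. The cohort deviation-from-matching
    statistic is the mean absolute deviation ``|frac_attempts - frac_income|``
    over unflagged players; equal per-attempt returns in the two classes put
    a player exactly on the diagonal.
    """
    df = table.df[table.df["return_points"].notna()]
    if len(df) == 0:
        raise ValueError("table has no recorded return_points")
    records = []
    for key, g in df.groupby(list(PLAYER_KEYS), sort=False):
        is3 = g["point_value"].to_numpy() == 3
        ret = g["return_points"].to_numpy(dtype=float)
        n3, n2 = int(is3.sum()), int((~is3).sum())
        income3, income2 = float(ret[is3].sum()), float(ret[~is3].sum())
        total = income2 + income3
        flagged = n2 == 0 or n3 == 0 or total == 0
        records.append(
            MatchingRecord(
                tuple(key),
                n2 + n3,
                n3 / (n2 + n3),
                income3 / total if total > 0 else np.nan,
                income2 / n2 if n2 else np.nan,
                income3 / n3 if n3 else np.nan,
                flagged,
            )
        )
    ok = [r for r in records if not r.flagged]
    summary = {
        "n_players": len(records),
        "n_included": len(ok),
        "matching_deviation": float(np.mean([r.matching_deviation for r in ok]))
        if ok
        else np.nan,
        "return_2pt": float(np.mean([r.return_2pt for r in ok])) if ok else np.nan,
        "return_3pt": float(np.mean([r.return_3pt for r in ok])) if ok else np.nan,
        "frac_3pt_attempts": float(np.mean([r.frac_3pt_attempts for r in ok]))
        if ok
        else np.nan,
        "frac_3pt_income": float(np.mean([r.frac_3pt_income for r in ok])) if ok else np.nan,
    }
    return records, summary
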