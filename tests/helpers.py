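"""Independent test oracles and random-table builders.

Everything here is deliberately written from scratch against the definitions
(dict counting, exhaustive linkage recomputation) so the implementations in
the package are checked against an independent route, not against themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hooplearn.court import Group, LabelRegionMap
from hooplearn.events_io import ShotTable


def toy_map(n_regions: int = 4, groups=None) -> LabelRegionMap:
    """Abstract region map with labels 1..n."""
    if groups is None:
        cycle = [Group.THREE, Group.LONG2, Group.SHORT2]
        groups = {i + 1: cycle[i % 3] for i in range(n_regions)}
    return LabelRegionMap(groups)


def build_table(rows, season: str = "S1") -> ShotTable:
    """Table from (player, game, order, region, outcome[, point_value]) tuples."""
    recs = []
    for row in rows:
        player, game, order, region, outcome = row[:5]
        pv = row[5] if len(row) > 5 else 2
        recs.append(
            {
                "player_id": str(player),
                "season": season,
                "game_id": str(game),
                "order_in_game": order,
                "x_ft": 0.0,
                "y_ft": 10.0,
                "outcome": outcome,
                "point_value": pv,
                "return_points": pd.NA,
                "region": region,
            }
        )
    return ShotTable(pd.DataFrame(recs))


def random_small_table(rng: np.random.Generator, n_regions: int = 4) -> ShotTable:
    """A random multi-player table over an abstract region set."""
    rows = []
    for p in range(rng.integers(1, 4)):
        for g in range(rng.integers(1, 5)):
            n = int(rng.integers(1, 9))
            for t in range(1, n + 1):
                rows.append(
                    (
                        f"P{p}",
                        f"G{g}",
                        t,
                        int(rng.integers(1, n_regions + 1)),
                        "S" if rng.random() < 0.5 else "F",
                    )
                )
    return build_table(rows)


def brute_force_conditionals(table: ShotTable, labels, player_key):
    """Dict-counting estimate of prior and conditionals for one player.

    Walks games event by event; pairs are consecutive shots within a game
    after dropping shots with regions outside ``labels``.
    """
    df = table.for_player(player_key).df
    labels = list(labels)
    shots = []  # (game, order, region, outcome)
    for r in df.itertuples(index=False):
        if r.region in labels:
            shots.append((r.game_id, r.order_in_game, r.region, r.outcome))
    shots.sort(key=lambda s: (s[0], s[1]))
    n = len(shots)
    prior = {l: 0 for l in labels}
    for _, _, reg, _ in shots:
        prior[reg] += 1
    pairs = [
        (a, b)
        for a, b in zip(shots[:-1], shots[1:])
        if a[0] == b[0]  # same game
    ]
    cond = {("S", i): {l: 0 for l in labels} for i in labels}
    cond.update({("F", i): {l: 0 for l in labels} for i in labels})
    for a, b in pairs:
        cond[(a[3], a[2])][b[2]] += 1
    R = len(labels)
    P = np.array([prior[l] / n for l in labels]) if n else np.full(R, np.nan)
    out = {}
    for o in ("S", "F"):
        M = np.full((R, R), np.nan)
        for i, li in enumerate(labels):
            tot = sum(cond[(o, li)].values())
            if tot:
                M[i] = [cond[(o, li)][lj] / tot for lj in labels]
        out[o] = M
    return P, out["S"], out["F"], len(pairs)


def brute_force_ward(X: np.ndarray, form: str = "sqrt"):
    """Exhaustive Ward linkage recomputed from member sets at every step.

    Same tie-break contract as the package (smallest id pair); returns the
    merge list [(a, b, height, new_id)].
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    members = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for a in sorted(members):
            for b in sorted(members):
                if b <= a:
                    continue
                ca = X[members[a]].mean(axis=0)
                cb = X[members[b]].mean(axis=0)
                na, nb = len(members[a]), len(members[b])
                w = 2.0 * na * nb / (na + nb)
                gap = float(np.linalg.norm(ca - cb))
                d = np.sqrt(w) * gap if form == "sqrt" else w * gap * gap
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d, a, b = best
        new = n + step
        members[new] = members.pop(a) + members.pop(b)
        merges.append((a, b, d, new))
    return merges


PLANTED_PARTITION = sorted(
    [sorted({1, 4, 7, 11, 14}), sorted({2, 5, 8, 12, 15}), sorted({3, 6, 9, 10, 13, 16})]
)


def as_partition(cut) -> list:
    return sorted(sorted(group) for group in cut)
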