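"""Model/Results facade over the learning-matrix pipeline.

``OperantLearningModel`` binds a shot table to a region map and selection
criteria; ``fit()`` estimates per-player learning matrices and their
equal-weight cohort aggregate, returning an ``OperantLearningResults`` that
carries the estimates and uncertainties and exposes the downstream analyses
(sign test, clustering, permutation test, summary table, plots).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hooplearn.clustering import (
    PROSPECTIVE,
    Dendrogram,
    DissimilarityMatrix,
    cut_clusters,
    row_dissimilarity,
    ward_cluster,
)
from hooplearn.court import DEFAULT_REGION_MAP, RegionMap
from hooplearn.events_io import ShotTable, read_shot_table
from hooplearn.learning import (
    FINE,
    AggregateLearning,
    ConditionalTable,
    LearningMatrix,
    cohort_counts,
    learning_matrix,
)
from hooplearn.stats_tests import PermutationResult, binomial_tail, perm_test_offdiag_sd


class OperantLearningModel:
    """Cohort learning-matrix estimation for located shot sequences.

    Parameters
    ----------
    table:
        Validated shot table (one row per FG attempt).
    region_map:
        Court partition; defaults to the 16-region sector map.
    resolution:
        ``"fine16"`` or ``"coarse3"``.
    min_per_region:
        Minimum attempts per region for a player-season to enter the cohort;
        players with any ill-defined matrix row are excluded as well.
    """

    def __init__(
        self,
        table: ShotTable,
        region_map: RegionMap = DEFAULT_REGION_MAP,
        resolution: str = FINE,
        min_per_region: int = 10,
    ):
        self.table = table
        self.region_map = region_map
        self.resolution = resolution
        self.min_per_region = min_per_region

    @classmethod
    def from_csv(cls, path, **kw) -> "OperantLearningModel":
        return cls(read_shot_table(path), **kw)

    def fit(self) -> "OperantLearningResults":
        counts = cohort_counts(self.table, self.region_map, self.resolution)
        selected, excluded = [], []
        matrices = []
        for key, pc in counts.items():
            if pc.prior_counts.min() >= self.min_per_region and (pc.ante_counts > 0).all():
                selected.append(key)
                matrices.append(learning_matrix(ConditionalTable.from_counts(pc)))
            else:
                excluded.append(key)
        if len(selected) < 2:
            raise ValueError(
                f"only {len(selected)} of {len(counts)} players pass the selection criteria"
            )
        from hooplearn.learning import aggregate as _aggregate

        agg = _aggregate(matrices)
        return OperantLearningResults(self, agg, matrices, selected, excluded)


@dataclass
class OperantLearningResults:
    """Fitted cohort learning matrix with uncertainties and diagnostics."""

    model: OperantLearningModel
    aggregate: AggregateLearning
    matrices: list[LearningMatrix]
    players: list[tuple[str, str]]
    excluded: list[tuple[str, str]]

    @property
    def mean(self) -> np.ndarray:
        return self.aggregate.mean

    @property
    def sem(self) -> np.ndarray:
        return self.aggregate.sem

    @property
    def n_players(self) -> int:
        return self.aggregate.n_players

    @property
    def diag_mean(self) -> float:
        return self.aggregate.diag_mean

    @property
    def offdiag_sd(self) -> float:
        return self.aggregate.offdiag_sd

    def diagonal_sign_test(self, p0: float = 0.5) -> dict:
        """One-tailed exact binomial test on the number of positive diagonal entries."""
        diag = np.diag(self.mean)
        k, n = int((diag > 0).sum()), len(diag)
        return {"k_positive": k, "n": n, "p_value": binomial_tail(k, n, p0)}

    def dissimilarity(self, axis: str = PROSPECTIVE, include_self: bool = True) -> DissimilarityMatrix:
        return row_dissimilarity(self.aggregate, axis, include_self)

    def cluster(self, axis: str = PROSPECTIVE, form: str = "sqrt") -> Dendrogram:
        vectors = self.mean if axis == PROSPECTIVE else self.mean.T
        return ward_cluster(vectors, labels=self.aggregate.labels, form=form)

    def cut(self, k: int, axis: str = PROSPECTIVE, form: str = "sqrt") -> list[set]:
        return cut_clusters(self.cluster(axis, form), k)

    def perm_test_offdiag_sd(self, n_rep: int = 10_000, seed: int | None = None) -> PermutationResult:
        return perm_test_offdiag_sd(
            self.model.table,
            self.model.region_map,
            n_rep=n_rep,
            seed=seed,
            min_per_region=self.model.min_per_region,
            resolution=self.model.resolution,
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        sign = self.diagonal_sign_test()
        rows = [
            ("resolution", self.aggregate.resolution),
            ("players included", f"{self.n_players} (of {self.n_players + len(self.excluded)})"),
            ("shots analyzed", f"{len(self.model.table)}"),
            ("diagonal mean", f"{self.diag_mean:+.4f}"),
            ("off-diagonal SD", f"{self.offdiag_sd:.4f}"),
            (
                "diagonal sign test",
                f"{sign['k_positive']}/{sign['n']} positive, one-tailed p = {sign['p_value']:.4g}",
            ),
        ]
        width = 62
        lines = ["Operant Learning Matrix".center(width), "=" * width]
        for name, value in rows:
            lines.append(f"{name:<24}{value:>38}")
        lines.append("=" * width)
        return "\n".join(lines)

    def to_report(self) -> dict:
        sign = self.diagonal_sign_test()
        return {
            **self.aggregate.report(),
            "n_excluded": len(self.excluded),
            "diag_sign_test": sign,
        }

    def save(self, outdir) -> dict:
        """Write matrix/SEM CSVs and a JSON report; returns the file map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        res = self.aggregate.resolution
        files = {
            "mean": outdir / f"learning_matrix_{res}.csv",
            "sem": outdir / f"learning_matrix_{res}_sem.csv",
            "report": outdir / f"learning_report_{res}.json",
        }
        self.aggregate.to_frame().to_csv(files["mean"])
        import pandas as pd

        pd.DataFrame(
            self.sem, index=list(self.aggregate.labels), columns=list(self.aggregate.labels)
        ).to_csv(files["sem"])
        files["report"].write_text(json.dumps(self.to_report(), indent=2))
        return {k: str(v) for k, v in files.items()}

    # -- plotting -----------------------------------------------------------

    def plot_matrix(self, ax=None):
        """Heatmap of the averaged learning matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lim = np.nanmax(np.abs(self.mean))
        im = ax.imshow(self.mean, cmap="RdBu_r", vmin=-lim, vmax=lim)
        ticks = range(len(self.aggregate.labels))
        ax.set_xticks(ticks, [str(l) for l in self.aggregate.labels])
        ax.set_yticks(ticks, [str(l) for l in self.aggregate.labels])
        ax.set_xlabel("consequent region")
        ax.set_ylabel("antecedent region")
        ax.figure.colorbar(im, ax=ax, label="learning index")
        return ax

    def plot_dendrogram(self, axis: str = PROSPECTIVE, ax=None):
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

        if ax is None:
            _, ax = plt.subplots()
        tree = self.cluster(axis)
        _scipy_dendrogram(
            tree.to_linkage(),
            labels=[str(l) for l in tree.labels],
            ax=ax,
            color_threshold=0.0,
        )
        ax.set_ylabel("Ward distance")
        ax.set_title(axis.lower())
        return ax
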