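"""Rank aggregation: per-solver dense ranks, their mean, and finalized ranks.

Each solver's scores are converted to a dense 1-based ranking (ties share a
rank, no gaps), the per-feature ranks are averaged across solvers, and the
averages are densely re-ranked to give the aggregated finalized rank (AFR)
vector.  Averaging ranks rather than raw coefficients puts the three solvers
— whose scores live on incompatible scales — on equal footing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import Dataset, RunConfig
from .solvers import SolverScores, score_all

__all__ = [
    "RankTable",
    "AggregatedRanking",
    "dense_rank",
    "aggregate_ranks",
    "finalize_ranks",
    "acrfs_rank",
]


@dataclasses.dataclass
class RankTable:
    """Per-solver dense ranks: ``(n_features, n_solvers)`` integer matrix."""

    per_solver_ranks: np.ndarray
    solver_names: list[str]

    def __post_init__(self) -> None:
        self.per_solver_ranks = np.asarray(self.per_solver_ranks, dtype=int)
        if self.per_solver_ranks.ndim != 2:
            raise ValueError("per_solver_ranks must be 2-D")
        if self.per_solver_ranks.shape[1] != len(self.solver_names):
            raise ValueError("one solver name per rank column required")
        if self.per_solver_ranks.shape[1] == 0:
            raise ValueError("rank table needs at least one solver column")


@dataclasses.dataclass
class AggregatedRanking:
    """Aggregated rank means and the finalized per-feature ranks (AFR)."""

    agg_values: np.ndarray
    final_ranks: np.ndarray
    feature_names: list[str]
    rank_method: str = "dense"
    rank_table: RankTable | None = None

    def __post_init__(self) -> None:
        self.agg_values = np.asarray(self.agg_values, dtype=float)
        self.final_ranks = np.asarray(self.final_ranks, dtype=int)
        n = len(self.feature_names)
        if not (len(self.agg_values) == len(self.final_ranks) == n):
            raise ValueError("agg_values, final_ranks, and feature_names must align")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"feature": self.feature_names}
        if self.rank_table is not None:
            short = {"mutual_information": "mi", "chi_square": "chi2", "pcc": "pcc"}
            for j, name in enumerate(self.rank_table.solver_names):
                data[f"{short.get(name, name)}_rank"] = self.rank_table.per_solver_ranks[:, j]
        data["agg_rank"] = self.agg_values
        data["final_rank"] = self.final_ranks
        return pd.DataFrame(data)

    def to_dict(self) -> dict:
        return self.to_frame().to_dict(orient="list")


def dense_rank(scores: np.ndarray, direction: str = "higher_better") -> np.ndarray:
    """Dense 1-based ranking of scores.

    The best score receives rank 1, equal scores share a rank, and the ranks
    used are consecutive integers with no gaps.  ``direction`` says whether
    larger scores (``higher_better``) or smaller ones (``lower_better``,
    e.g. p-values) are better.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if direction == "higher_better":
        keyed = -scores
    elif direction == "lower_better":
        keyed = scores
    else:
        raise ValueError("direction must be 'higher_better' or 'lower_better'")
    return rankdata(keyed, method="dense").astype(int)


def aggregate_ranks(table: RankTable) -> np.ndarray:
    """Element-wise mean of per-solver ranks (generalizes to any solver count)."""
    return table.per_solver_ranks.mean(axis=1)


def finalize_ranks(agg_values: np.ndarray, rank_method: str = "dense") -> np.ndarray:
    """Re-rank aggregated means into the finalized rank vector.

    Smaller mean rank is better and receives rank 1.  ``dense`` keeps ties
    tied; ``ordinal`` breaks them by feature order (stable), guaranteeing at
    most k features at rank <= k for strict top-k selection.
    """
    agg_values = np.asarray(agg_values, dtype=float)
    if agg_values.size == 0:
        raise ValueError("empty aggregated values")
    if rank_method == "dense":
        return dense_rank(agg_values, "lower_better")
    if rank_method == "ordinal":
        return rankdata(agg_values, method="ordinal").astype(int)
    raise ValueError("rank_method must be 'dense' or 'ordinal'")


def rank_solver_scores(
    scores: list[SolverScores],
    feature_names: list[str],
    rank_method: str = "dense",
) -> AggregatedRanking:
    """Aggregate already-computed solver scores into a finalized ranking."""
    if not scores:
        raise ValueError("need at least one solver")
    columns = [dense_rank(s.values, s.direction) for s in scores]
    table = RankTable(np.column_stack(columns), [s.solver_name for s in scores])
    agg = aggregate_ranks(table)
    final = finalize_ranks(agg, rank_method)
    return AggregatedRanking(agg, final, list(feature_names), rank_method, table)


def acrfs_rank(dataset: Dataset, config: RunConfig | None = None) -> AggregatedRanking:
    """Full ranking stage: score with all solvers, rank, aggregate, finalize.

    With ``smote_stage='pre_rank'`` the class balance is corrected before
    scoring (the seed then matters); the default scores the data as given.
    """
    config = config or RunConfig()
    if dataset.n_features < 2:
        raise ValueError("need at least 2 features to rank")
    if config.smote_stage == "pre_rank":
        from .balance import smote_balance

        dataset = smote_balance(dataset, config.smote_k, config.seed).dataset
    scores = score_all(dataset, config)
    return rank_solver_scores(scores, dataset.feature_names, config.rank_method)
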