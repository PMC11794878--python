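"""Threshold-rank subset selection and three-tier feature categorization.

A feature enters the selected subset iff its finalized rank is at most the
threshold value rank (TVR).  Features are further categorized into primary
(selected), secondary (the next band of ranks), and less-influential tiers —
a hierarchy that keeps the discarded features interpretable instead of
silently dropping them.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .data_io import Dataset
from .ranking import AggregatedRanking

__all__ = [
    "SelectionResult",
    "CategoryMap",
    "select_subset",
    "subset_dataset",
    "categorize",
]

CATEGORIES = ("primary", "secondary", "less_influential")


@dataclasses.dataclass
class SelectionResult:
    """The feature subset whose finalized rank is at most ``tvr``."""

    selected: list[str]
    selected_indices: list[int]
    tvr: int
    n_total: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class CategoryMap:
    """Assignment of every feature to exactly one relevance tier."""

    assignment: dict[str, str]
    boundaries: tuple[int, int]

    def sizes(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for cat in self.assignment.values():
            out[cat] += 1
        return out

    def members(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return [f for f, c in self.assignment.items() if c == category]

    def to_dict(self) -> dict:
        return {"assignment": self.assignment, "boundaries": list(self.boundaries)}


def select_subset(ranking: AggregatedRanking, tvr: int) -> SelectionResult:
    """Select the features with finalized rank <= ``tvr``, original order kept.

    Under dense ranking, ties at the boundary may push the subset size above
    ``tvr``; under ordinal ranking the size is at most ``tvr``.  An empty or
    total selection is legal but warned about.
    """
    if tvr < 1:
        raise ValueError("tvr must be >= 1")
    if ranking.n_features == 0:
        raise ValueError("empty ranking")
    mask = ranking.final_ranks <= tvr
    indices = [int(i) for i in np.flatnonzero(mask)]
    names = [ranking.feature_names[i] for i in indices]
    if not names:
        warnings.warn(f"selection with tvr={tvr} is empty", stacklevel=2)
    elif len(names) == ranking.n_features:
        warnings.warn(f"selection with tvr={tvr} keeps every feature", stacklevel=2)
    return SelectionResult(names, indices, tvr, ranking.n_features)


def subset_dataset(
    dataset: Dataset, selection: SelectionResult, allow_empty: bool = False
) -> Dataset:
    """Restrict a dataset to the selected feature columns; labels untouched."""
    if not selection.selected and not allow_empty:
        raise ValueError("empty selection: a classifier cannot train on 0 features")
    name_to_col = {name: j for j, name in enumerate(dataset.feature_names)}
    missing = [n for n in selection.selected if n not in name_to_col]
    if missing:
        raise ValueError(f"selected features not in dataset: {missing}")
    cols = [name_to_col[n] for n in selection.selected]
    return Dataset(
        features=dataset.features[:, cols],
        labels=dataset.labels.copy(),
        feature_names=list(selection.selected),
        label_name=dataset.label_name,
    )


def categorize(
    ranking: AggregatedRanking,
    tvr: int = 20,
    secondary_width: int = 5,
    mode: str = "default",
) -> CategoryMap:
    """Assign each feature to the primary / secondary / less-influential tier.

    ``default`` mode keeps categorization consistent with subset selection:
    primary iff rank <= tvr (exactly the selected set), secondary for the
    next ``secondary_width`` ranks, less-influential beyond.  ``literal_bounds``
    applies the fixed published-style piecewise bounds (rank < 20 primary,
    20 <= rank < 25 secondary, the rest less influential) with the top
    interval closed so no feature is left uncategorized.
    """
    if ranking.n_features == 0:
        raise ValueError("empty ranking")
    if tvr < 1 or secondary_width < 1:
        raise ValueError("tvr and secondary_width must be positive")
    if mode == "default":
        primary_max, secondary_max = tvr, tvr + secondary_width
    elif mode == "literal_bounds":
        primary_max, secondary_max = 19, 24
    else:
        raise ValueError(f"unknown categorization mode {mode!r}")
    assignment: dict[str, str] = {}
    for name, rank in zip(ranking.feature_names, ranking.final_ranks):
        if rank <= primary_max:
            assignment[name] = "primary"
        elif rank <= secondary_max:
            assignment[name] = "secondary"
        else:
            assignment[name] = "less_influential"
    return CategoryMap(assignment, (primary_max, secondary_max))
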