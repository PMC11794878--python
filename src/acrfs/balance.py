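"""Minority-class oversampling with SMOTE.

Classic SMOTE: each synthetic sample is a convex combination
``x + u * (x' - x)`` of a minority sample ``x`` and one of its ``k`` nearest
minority neighbors ``x'``, with ``u`` uniform on [0, 1].  The minority class
is oversampled until both classes have equal counts.  Base sample, neighbor,
and interpolation factor all come from one seeded generator, so results are
reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .data_io import Dataset

__all__ = ["BalancedDataset", "smote_balance", "check_balance"]


@dataclasses.dataclass
class BalancedDataset:
    """A dataset with equal class counts plus provenance of the synthetic rows.

    Original rows appear unchanged, in their original order, before all
    synthetic rows; ``synthetic_mask`` is True exactly on the generated rows.
    """

    dataset: Dataset
    synthetic_mask: np.ndarray
    seed: int
    k_neighbors: int


def check_balance(dataset: Dataset) -> dict[int, int]:
    """Per-class sample counts."""
    return dataset.class_counts()


def smote_balance(dataset: Dataset, k_neighbors: int = 5, seed: int = 0) -> BalancedDataset:
    """Oversample the minority class to the majority count with SMOTE.

    ``k_neighbors`` larger than minority_count - 1 is clamped (with a
    warning) so a neighborhood always exists.  Neighbor search is Euclidean
    and restricted to minority samples.  An already balanced dataset is
    returned unchanged.
    """
    counts = check_balance(dataset)
    if len(counts) < 2:
        raise ValueError("single-class dataset cannot be balanced")
    minority_label = min(counts, key=lambda c: (counts[c], c))
    majority_label = max(counts, key=lambda c: (counts[c], -c))
    n_minority = counts[minority_label]
    n_needed = counts[majority_label] - n_minority
    if n_needed == 0:
        return BalancedDataset(
            dataset, np.zeros(dataset.n_samples, dtype=bool), seed, k_neighbors
        )
    if n_minority < 2:
        raise ValueError("need at least 2 minority samples to interpolate")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= n_minority:
        warnings.warn(
            f"k_neighbors={k_neighbors} >= minority count {n_minority}; "
            f"clamping to {n_minority - 1}",
            stacklevel=2,
        )
        k_neighbors = n_minority - 1

    minority = dataset.features[dataset.labels == minority_label]
    # +1 because each point is its own nearest neighbor
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority)
    neighbor_idx = nn.kneighbors(minority, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_minority, size=n_needed)
    pick = rng.integers(0, k_neighbors, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    x = minority[base]
    x_nbr = minority[neighbor_idx[base, pick]]
    synthetic = x + u[:, None] * (x_nbr - x)

    features = np.vstack([dataset.features, synthetic])
    labels = np.concatenate(
        [dataset.labels, np.full(n_needed, minority_label, dtype=int)]
    )
    mask = np.zeros(len(labels), dtype=bool)
    mask[dataset.n_samples :] = True
    balanced = Dataset(features, labels, list(dataset.feature_names), dataset.label_name)
    return BalancedDataset(balanced, mask, seed, k_neighbors)
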