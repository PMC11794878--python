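"""Per-feature association coefficients: mutual information, chi-square, Pearson.

Each solver scores the strength of association between one feature vector and
the binary label.  The three capture complementary structure: mutual
information sees arbitrary (including non-linear) dependence on a discretized
copy of the feature, the chi-square test compares per-class feature mass
against the class proportions, and the Pearson coefficient measures linear
association.  Scores feed the ranking stage; each solver carries a ranking
direction so that "better" is unambiguous downstream.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Any

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .data_io import Dataset, RunConfig

logger = logging.getLogger("acrfs")

__all__ = [
    "SolverScores",
    "compute_mutual_information",
    "compute_chi_square",
    "compute_pcc",
    "score_all",
    "SOLVER_NAMES",
]

SOLVER_NAMES = ("mutual_information", "chi_square", "pcc")


@dataclasses.dataclass
class SolverScores:
    """One coefficient per feature for a single solver.

    ``direction`` states how scores map to ranks: ``higher_better`` for
    mutual information and |PCC|, ``lower_better`` for chi-square p-values.
    """

    solver_name: str
    values: np.ndarray
    direction: str
    metadata: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError("direction must be 'higher_better' or 'lower_better'")


def _quantile_bin(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize ``x`` into at most ``bins`` quantile bins (0-based codes).

    When the feature takes ``bins`` or fewer distinct values its empirical
    distribution is already discrete and the values themselves are the codes;
    otherwise observations are cut at interior quantile edges (duplicate
    edges from heavy ties collapse, lowering the effective bin count).
    """
    unique, codes = np.unique(x, return_inverse=True)
    if len(unique) <= bins:
        return codes
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)))
    return np.searchsorted(edges[1:-1], x, side="right")


def compute_mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Plug-in mutual information (bits) between a quantile-binned feature and y.

    The feature is discretized into at most ``bins`` quantile bins and
    I(X;Y) = sum_{ij} p_ij log2(p_ij / (p_i p_j)) is evaluated on the joint
    histogram, with the convention 0*log(0/q) = 0.  The logarithm base only
    rescales values and never reorders ranks.  A constant feature carries no
    information and scores 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size == 0:
        raise ValueError("empty input")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if np.all(x == x[0]):
        return 0.0
    codes = _quantile_bin(x, bins)
    joint = _contingency(codes, y).astype(float)
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(p, p / (px * py)) / np.log(2.0)
    return float(np.nansum(terms))


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Joint count table of two code vectors."""
    a_codes, a_inv = np.unique(a, return_inverse=True)
    b_codes, b_inv = np.unique(b, return_inverse=True)
    table = np.zeros((len(a_codes), len(b_codes)), dtype=np.int64)
    np.add.at(table, (a_inv, b_inv), 1)
    return table


def compute_chi_square(
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "frequency",
    bins: int = 10,
) -> tuple[float, float]:
    """Chi-square statistic and p-value for feature/label association.

    ``frequency`` mode treats the per-class sums of a non-negative feature as
    observed counts and the class proportions of the total mass as expected
    counts — the test applied to raw positive-valued measurements, with
    df = n_classes - 1.  ``binned`` mode builds a contingency table of the
    quantile-binned feature against the label,
    df = (n_bins - 1) * (n_classes - 1).  P-values come from the chi-square
    survival function.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size == 0:
        raise ValueError("empty input")
    classes = np.unique(y)
    if mode == "frequency":
        if np.any(x < 0):
            raise ValueError("frequency mode requires non-negative feature values")
        total = x.sum()
        if total <= 0:
            raise ValueError("zero total feature mass; expected counts undefined")
        observed = np.array([x[y == c].sum() for c in classes])
        proportions = np.array([(y == c).mean() for c in classes])
        expected = total * proportions
        statistic = float(((observed - expected) ** 2 / expected).sum())
        df = len(classes) - 1
    elif mode == "binned":
        codes = _quantile_bin(x, bins)
        table = _contingency(codes, y)
        if table.shape[0] < 2 or table.shape[1] < 2:
            return 0.0, 1.0
        statistic, _, df, _ = stats.chi2_contingency(table, correction=False)
        statistic = float(statistic)
    else:
        raise ValueError(f"unknown chi-square mode {mode!r}")
    if df < 1:
        return 0.0, 1.0
    p_value = float(stats.chi2.sf(statistic, df))
    return statistic, p_value


def compute_pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient between a feature and the label.

    A zero-variance feature is defined as uninformative (returns 0 with a
    warning) rather than raising, so a degenerate column cannot abort a
    whole-table scoring pass.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        warnings.warn("zero-variance input to PCC; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def score_all(dataset: Dataset, config: RunConfig | None = None) -> list[SolverScores]:
    """Score every feature with all three solvers.

    Returns one :class:`SolverScores` per solver, values aligned with
    ``dataset.feature_names``.  The chi-square entry ranks by p-value
    ascending (direction ``lower_better``); PCC uses |r| by default so that
    strong negative linear association counts as influential.
    """
    config = config or RunConfig()
    X, y = dataset.features, dataset.labels
    mi = np.empty(dataset.n_features)
    chi_stat = np.empty(dataset.n_features)
    chi_p = np.empty(dataset.n_features)
    pcc = np.empty(dataset.n_features)
    for j, name in enumerate(dataset.feature_names):
        try:
            mi[j] = compute_mutual_information(X[:, j], y, bins=config.mi_bins)
            chi_stat[j], chi_p[j] = compute_chi_square(X[:, j], y, mode=config.chi2_mode)
            pcc[j] = compute_pcc(X[:, j], y)
        except ValueError as exc:
            raise ValueError(f"solver failed on feature {name!r}: {exc}") from exc
    pcc_values = np.abs(pcc) if config.pcc_mode == "absolute" else pcc
    return [
        SolverScores("mutual_information", mi, "higher_better", {"bins": config.mi_bins}),
        SolverScores(
            "chi_square", chi_p, "lower_better",
            {"mode": config.chi2_mode, "statistics": chi_stat.copy()},
        ),
        SolverScores(
            "pcc", pcc_values, "higher_better",
            {"mode": config.pcc_mode, "signed": pcc.copy()},
        ),
    ]
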