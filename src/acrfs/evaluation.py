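"""Train/test split, confusion-matrix metrics, and the before/after harness.

The harness trains each classifier twice — once on the full feature set and
once on the rank-selected subset — with identical balancing and split seeds
on both arms, so the only difference between the two columns of the report
is the feature set.  Metrics are computed from the confusion counts in
closed form: accuracy, precision, recall, F1, Cohen's kappa, and the
Matthews correlation coefficient (MCC).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Any, Callable, Protocol

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balance import smote_balance
from .data_io import Dataset, RunConfig
from .ranking import AggregatedRanking
from .selection import select_subset, subset_dataset

logger = logging.getLogger("acrfs")

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "EvalReport",
    "ModelAdapter",
    "split_dataset",
    "confusion",
    "compute_metrics",
    "evaluate_before_after",
    "make_default_adapters",
]


@dataclasses.dataclass
class ConfusionCounts:
    """Binary confusion counts with label 1 as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass
class MetricsReport:
    """The six classification metrics derived from one confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    mcc: float
    averaging: str = "macro"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


class ModelAdapter(Protocol):
    """Contract every classifier must satisfy to enter the harness."""

    name: str

    def fit(self, X: np.ndarray, y: np.ndarray) -> Any: ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


@dataclasses.dataclass
class SklearnAdapter:
    """Thin adapter around a scikit-learn estimator factory."""

    name: str
    factory: Callable[[int], Any]
    seed: int = 0

    def __post_init__(self) -> None:
        self._model = self.factory(self.seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnAdapter":
        self._model = self.factory(self.seed)
        self._model.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._model.predict(X), dtype=int)


def make_default_adapters(seed: int = 0) -> list[SklearnAdapter]:
    """The six reference classifiers: RF, GNB, DT, KNN, SVM, SGD.

    Library defaults are used throughout (no tuning); every stochastic
    estimator receives the given seed.
    """
    return [
        SklearnAdapter("RF", lambda s: RandomForestClassifier(random_state=s), seed),
        SklearnAdapter("GNB", lambda s: GaussianNB(), seed),
        SklearnAdapter("DT", lambda s: DecisionTreeClassifier(random_state=s), seed),
        SklearnAdapter("KNN", lambda s: KNeighborsClassifier(), seed),
        SklearnAdapter("SVM", lambda s: SVC(random_state=s), seed),
        SklearnAdapter("SGD", lambda s: SGDClassifier(random_state=s), seed),
    ]


def split_dataset(
    dataset: Dataset,
    ratio: float = 0.75,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[Dataset, Dataset]:
    """Seeded train/test split; stratified by class by default."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    idx = np.arange(dataset.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=ratio,
        random_state=seed,
        shuffle=True,
        stratify=dataset.labels if stratified else None,
    )
    def take(rows: np.ndarray) -> Dataset:
        return Dataset(
            dataset.features[rows],
            dataset.labels[rows],
            list(dataset.feature_names),
            dataset.label_name,
        )
    return take(train_idx), take(test_idx)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts for binary vectors; label 1 is positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty prediction vectors")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0.0:
        warnings.warn(f"{what} undefined (0/0); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts, averaging: str = "macro") -> MetricsReport:
    """Closed-form metrics from confusion counts.

    ``macro`` averages precision/recall over both classes before forming F1
    as their harmonic mean; ``positive_class`` reports class-1 precision and
    recall directly.  Cohen's kappa uses the marginal-product chance
    agreement; MCC is the usual four-count correlation.  Any 0/0 metric is
    reported as 0 with a warning.
    """
    if averaging not in ("macro", "positive_class"):
        raise ValueError("averaging must be 'macro' or 'positive_class'")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    n = c.n
    accuracy = (tp + tn) / n
    prec_pos = _safe_div(tp, tp + fp, "positive precision")
    rec_pos = _safe_div(tp, tp + fn, "positive recall")
    if averaging == "macro":
        prec_neg = _safe_div(tn, tn + fn, "negative precision")
        rec_neg = _safe_div(tn, tn + fp, "negative recall")
        precision = (prec_pos + prec_neg) / 2.0
        recall = (rec_pos + rec_neg) / 2.0
    else:
        precision, recall = prec_pos, rec_pos
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "F1")
    p_o = accuracy
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, mcc_den, "MCC")
    return MetricsReport(accuracy, precision, recall, f1, kappa, mcc, averaging)


@dataclasses.dataclass
class EvalReport:
    """Before/after feature-selection metrics for every model."""

    per_model: dict[str, dict[str, MetricsReport]]
    config: dict[str, Any]
    seed: int
    errors: dict[str, str] = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, phases in self.per_model.items():
            for phase in ("before", "after"):
                m = phases[phase]
                rows.append(
                    {
                        "model": model,
                        "phase": phase,
                        "accuracy": m.accuracy,
                        "precision": m.precision,
                        "recall": m.recall,
                        "f1": m.f1,
                        "kappa": m.kappa,
                        "mcc": m.mcc,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict[str, Any]:
        return {
            "per_model": {
                model: {phase: m.to_dict() for phase, m in phases.items()}
                for model, phases in self.per_model.items()
            },
            "config": self.config,
            "seed": self.seed,
            "errors": self.errors,
        }


def _prepare_arm(dataset: Dataset, config: RunConfig) -> tuple[Dataset, Dataset]:
    """Balance and split one evaluation arm according to the config.

    The default order (balance, then split) mirrors the reference pipeline;
    ``leakage_safe`` splits first and oversamples the training partition
    only, which is the methodologically sound order.
    """
    balance_on = config.smote_stage != "off"
    if config.leakage_safe:
        train, test = split_dataset(dataset, config.split_ratio, config.seed)
        if balance_on:
            train = smote_balance(train, config.smote_k, config.seed).dataset
        return train, test
    if balance_on:
        dataset = smote_balance(dataset, config.smote_k, config.seed).dataset
    return split_dataset(dataset, config.split_ratio, config.seed)


def evaluate_before_after(
    dataset: Dataset,
    ranking: AggregatedRanking,
    config: RunConfig | None = None,
    models: list[ModelAdapter] | None = None,
) -> EvalReport:
    """Train and score every model on the full and on the selected feature set.

    Adapter failures are recorded per model (``report.errors``) rather than
    aborting the whole comparison.
    """
    config = config or RunConfig()
    models = models if models is not None else make_default_adapters(config.seed)
    if not models:
        raise ValueError("need at least one model adapter")
    selection = select_subset(ranking, config.tvr)
    arms = {
        "before": dataset,
        "after": subset_dataset(dataset, selection),
    }
    splits = {name: _prepare_arm(arm, config) for name, arm in arms.items()}
    per_model: dict[str, dict[str, MetricsReport]] = {}
    errors: dict[str, str] = {}
    for adapter in models:
        phases: dict[str, MetricsReport] = {}
        try:
            for phase, (train, test) in splits.items():
                adapter.fit(train.features, train.labels)
                pred = adapter.predict(test.features)
                phases[phase] = compute_metrics(
                    confusion(test.labels, pred), config.metric_average
                )
            per_model[adapter.name] = phases
        except Exception as exc:  # adapter failure is not fatal to the run
            logger.error("model %s failed: %s", adapter.name, exc)
            errors[adapter.name] = str(exc)
    return EvalReport(per_model, config.to_dict(), config.seed, errors)
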