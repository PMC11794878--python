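"""Tabular data loading, validation, imputation, label encoding, and report I/O.

The pipeline consumes plain CSV tables with a header row, numeric feature
columns, and one binary label column (for example benign/malignant biopsy
calls).  Missing numeric cells are imputed with the per-column mean of the
observed values; the two raw label values are mapped deterministically to
{0, 1} with the lexicographically smaller value becoming 0.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("acrfs")

__all__ = [
    "Dataset",
    "RunConfig",
    "load_dataset",
    "encode_labels",
    "write_report",
    "read_report",
]


@dataclasses.dataclass
class Dataset:
    """A fully numeric feature matrix with binary labels.

    Parameters
    ----------
    features:
        ``(n_samples, n_features)`` float array with no missing values.
    labels:
        Integer vector in ``{0, 1}`` of length ``n_samples``.
    feature_names:
        Unique column identifiers, one per feature, in matrix order.
    label_name:
        Name of the label column in the source table.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    label_name: str = "label"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.ndim != 1 or len(self.labels) != self.features.shape[0]:
            raise ValueError("labels length must match the number of rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must contain only 0 and 1")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values after load")
        names = list(self.feature_names)
        if len(names) != self.features.shape[1]:
            raise ValueError("feature_names length must match the number of columns")
        if len(set(names)) != len(names):
            raise ValueError("feature_names must be unique")
        self.feature_names = names

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=self.feature_names)
        frame[self.label_name] = self.labels
        return frame


#: Stages at which minority oversampling may be inserted into the pipeline.
SMOTE_STAGES = ("post_select", "pre_rank", "off")
CHI2_MODES = ("frequency", "binned")
PCC_MODES = ("absolute", "signed")
METRIC_AVERAGES = ("macro", "positive_class")
RANK_METHODS = ("dense", "ordinal")


@dataclasses.dataclass
class RunConfig:
    """Pipeline settings with defaults that reproduce the reference study design.

    ``tvr`` is the threshold value rank: features whose finalized rank is at
    most ``tvr`` form the selected subset.  ``split_ratio`` is the training
    fraction of the train/test split.  ``smote_stage`` places minority
    oversampling either after subset selection (default), before ranking, or
    disables it; ``leakage_safe`` restricts oversampling to the training
    partition.
    """

    tvr: int = 20
    smote_stage: str = "post_select"
    smote_k: int = 5
    split_ratio: float = 0.75
    seed: int = 0
    mi_bins: int = 10
    chi2_mode: str = "frequency"
    pcc_mode: str = "absolute"
    metric_average: str = "macro"
    rank_method: str = "dense"
    leakage_safe: bool = False

    def __post_init__(self) -> None:
        if self.tvr < 1:
            raise ValueError("tvr must be a positive integer")
        if self.smote_stage not in SMOTE_STAGES:
            raise ValueError(f"smote_stage must be one of {SMOTE_STAGES}")
        if self.smote_k < 1:
            raise ValueError("smote_k must be a positive integer")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.mi_bins < 1:
            raise ValueError("mi_bins must be a positive integer")
        if self.chi2_mode not in CHI2_MODES:
            raise ValueError(f"chi2_mode must be one of {CHI2_MODES}")
        if self.pcc_mode not in PCC_MODES:
            raise ValueError(f"pcc_mode must be one of {PCC_MODES}")
        if self.metric_average not in METRIC_AVERAGES:
            raise ValueError(f"metric_average must be one of {METRIC_AVERAGES}")
        if self.rank_method not in RANK_METHODS:
            raise ValueError(f"rank_method must be one of {RANK_METHODS}")

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a JSON or YAML config file whose keys mirror this dataclass."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def encode_labels(raw: Sequence[Any]) -> np.ndarray:
    """Map a two-valued label vector to {0, 1}.

    The lexicographically smaller raw value (compared as text) becomes 0; the
    mapping is logged so runs are auditable.  One or more than two distinct
    values is an error.
    """
    arr = np.asarray(raw)
    if arr.size == 0:
        raise ValueError("empty label vector")
    values = sorted({str(v) for v in arr})
    if len(values) != 2:
        raise ValueError(
            f"label column must have exactly 2 distinct values, found {len(values)}: {values}"
        )
    mapping = {values[0]: 0, values[1]: 1}
    logger.info("label encoding: %r -> 0, %r -> 1", values[0], values[1])
    return np.array([mapping[str(v)] for v in arr], dtype=int)


def _dedupe_names(names: Iterable[str]) -> list[str]:
    """Disambiguate duplicate column names with deterministic numeric suffixes."""
    seen: dict[str, int] = {}
    out: list[str] = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}_{seen[name]}")
        else:
            seen[name] = 1
            out.append(name)
    return out


def load_dataset(
    path: str | Path,
    label_column: str,
    drop_columns: Sequence[str] = (),
) -> Dataset:
    """Load a CSV table into a :class:`Dataset`.

    Missing numeric cells are imputed with the per-column mean of the
    non-missing values; the label column is encoded to {0, 1}.  Non-feature
    columns (sample identifiers and the like) are removed via ``drop_columns``.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the label column is absent, has more than two values, or a feature
        column is non-numeric or entirely missing (nothing to impute from).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    frame = pd.read_csv(path)
    frame.columns = _dedupe_names(str(c) for c in frame.columns)
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")
    for col in drop_columns:
        if col not in frame.columns:
            raise ValueError(f"drop column {col!r} not found in {path.name}")
    frame = frame.drop(columns=list(drop_columns))

    raw_labels = frame[label_column]
    if raw_labels.isna().any():
        n_bad = int(raw_labels.isna().sum())
        logger.warning("dropping %d rows with missing label", n_bad)
        frame = frame.loc[~raw_labels.isna()]
        raw_labels = frame[label_column]
    labels = encode_labels(raw_labels.to_numpy())

    feature_frame = frame.drop(columns=[label_column])
    for col in feature_frame.columns:
        coerced = pd.to_numeric(feature_frame[col], errors="coerce")
        newly_missing = coerced.isna() & ~feature_frame[col].isna()
        if newly_missing.any():
            raise ValueError(f"feature column {col!r} contains non-numeric values")
        feature_frame[col] = coerced
        if coerced.isna().all():
            raise ValueError(f"feature column {col!r} is entirely missing; cannot impute")
        if coerced.isna().any():
            mean = float(coerced.mean())
            logger.info(
                "imputed %d missing cells in %r with column mean %.6g",
                int(coerced.isna().sum()), col, mean,
            )
            feature_frame[col] = coerced.fillna(mean)

    return Dataset(
        features=feature_frame.to_numpy(dtype=float),
        labels=labels,
        feature_names=list(feature_frame.columns),
        label_name=label_column,
    )


def write_report(report: Any, path: str | Path, format: str = "csv") -> None:
    """Serialize a report object to CSV or JSON.

    Any object exposing ``to_frame()`` (tabular reports such as rankings or
    evaluation tables) or ``to_dict()`` can be written.  Values survive a
    round trip to at least 12 significant digits.
    """
    path = Path(path)
    if not path.parent.exists():
        raise ValueError(f"parent directory does not exist: {path.parent}")
    if format == "csv":
        if hasattr(report, "to_frame"):
            frame = report.to_frame()
        elif isinstance(report, pd.DataFrame):
            frame = report
        else:
            raise TypeError(f"cannot write {type(report).__name__} as CSV")
        frame.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        if hasattr(report, "to_dict"):
            payload = report.to_dict()
        elif isinstance(report, dict):
            payload = report
        elif hasattr(report, "to_frame"):
            payload = report.to_frame().to_dict(orient="list")
        else:
            raise TypeError(f"cannot write {type(report).__name__} as JSON")
        path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def read_report(path: str | Path, format: str = "csv") -> Any:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        return json.loads(path.read_text())
    raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")
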