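"""Reading, normalization and splitting of expression-style matrices.

The package consumes samples × features matrices with one categorical label
per sample, read from delimited text (CSV/TSV, one header row, one label
column).  Feature values are rescaled per feature to [0, 1] by min-max
normalization, x' = (x - min) / (max - min), with the extrema taken per
feature.  By default the extrema are fit on the training split only and the
test split is clipped into [0, 1], which keeps evaluation leakage-safe; a
``before_split`` mode normalizes the full matrix first for pipelines that
want the alternative order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split


class ParseError(ValueError):
    """Raised for malformed input files (bad cells, duplicate columns)."""


class ConfigurationError(ValueError):
    """Raised for invalid run configuration (missing columns/paths)."""


@dataclass
class DataMatrix:
    """A numeric samples × features matrix with labels and names."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match n_features")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match n_samples")
        if len(self.labels) != n:
            raise ValueError("labels length does not match n_samples")
        if len(set(self.feature_names)) != d:
            raise ParseError("duplicate feature names")
        if len(set(self.sample_ids)) != n:
            raise ParseError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset_rows(self, indices: np.ndarray) -> "DataMatrix":
        indices = np.asarray(indices, dtype=int)
        return DataMatrix(
            values=self.values[indices],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in indices],
            labels=self.labels[indices],
        )

    def with_values(self, values: np.ndarray) -> "DataMatrix":
        return DataMatrix(
            values=values,
            feature_names=list(self.feature_names),
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
        )


@dataclass
class NormalizationParams:
    """Per-feature minima/maxima of the fitting matrix."""

    per_feature_min: np.ndarray
    per_feature_max: np.ndarray

    def __post_init__(self) -> None:
        self.per_feature_min = np.asarray(self.per_feature_min, dtype=float)
        self.per_feature_max = np.asarray(self.per_feature_max, dtype=float)
        if self.per_feature_min.shape != self.per_feature_max.shape:
            raise ValueError("min/max length mismatch")
        if np.any(self.per_feature_min > self.per_feature_max):
            raise ValueError("per_feature_min exceeds per_feature_max")

    def save(self, path: str | Path) -> None:
        payload = {
            "per_feature_min": self.per_feature_min.tolist(),
            "per_feature_max": self.per_feature_max.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            per_feature_min=np.asarray(payload["per_feature_min"]),
            per_feature_max=np.asarray(payload["per_feature_max"]),
        )


@dataclass
class SplitSpec:
    """A stratified train/test index partition."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(sorted(self.train_indices), dtype=int)
        self.test_indices = np.asarray(sorted(self.test_indices), dtype=int)
        overlap = set(self.train_indices.tolist()) & set(self.test_indices.tolist())
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def read_matrix(
    path: str | Path,
    label_column: str = "class",
    delimiter: str = ",",
    impute_missing: bool = False,
) -> DataMatrix:
    """Read a delimited matrix with a header row and a label column.

    Missing cells are rejected by default; with ``impute_missing`` they are
    replaced by the per-feature median.  gzip input is handled transparently
    (by extension).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    header = pd.read_csv(path, sep=delimiter, header=None, nrows=1).iloc[0]
    dupes = header[header.duplicated()].tolist()
    if dupes:  # pandas silently renames duplicates, so check the raw header
        raise ParseError(f"duplicate feature names: {dupes}")
    df = pd.read_csv(path, sep=delimiter)
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found; columns: {list(df.columns)[:8]}..."
        )
    labels = df[label_column].astype(str).to_numpy()
    feats = df.drop(columns=[label_column])
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~feats.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell at row {r} column {feats.columns[c]!r}: "
            f"{feats.iat[r, c]!r}"
        )
    if numeric.isna().any().any():
        if not impute_missing:
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise ParseError(f"missing value at row {r} column {feats.columns[c]!r}")
        numeric = numeric.fillna(numeric.median())
    return DataMatrix(
        values=numeric.to_numpy(dtype=float),
        feature_names=[str(c) for c in feats.columns],
        sample_ids=[str(i) for i in range(len(df))],
        labels=labels,
    )


def write_matrix(X: DataMatrix, path: str | Path, label_column: str = "class",
                 delimiter: str = ",") -> None:
    df = pd.DataFrame(X.values, columns=X.feature_names)
    df[label_column] = X.labels
    df.to_csv(path, sep=delimiter, index=False)


def fit_minmax(train: DataMatrix | np.ndarray) -> NormalizationParams:
    """Per-feature column extrema of the training matrix."""
    values = train.values if isinstance(train, DataMatrix) else np.asarray(train, float)
    if values.size == 0:
        raise ValueError("cannot fit normalization on an empty matrix")
    return NormalizationParams(
        per_feature_min=values.min(axis=0),
        per_feature_max=values.max(axis=0),
    )


def apply_minmax(params: NormalizationParams, X: DataMatrix | np.ndarray):
    """Map each cell to (x - min)/(max - min), clipped to [0, 1].

    Constant features (max == min) map to 0.  Values outside the fitted
    range (test data) are clipped so the codomain contract holds.
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, float)
    lo, hi = params.per_feature_min, params.per_feature_max
    if values.shape[1] != lo.shape[0]:
        raise ValueError(
            f"feature count {values.shape[1]} != params length {lo.shape[0]}"
        )
    span = hi - lo
    out = np.zeros_like(values, dtype=float)
    nz = span > 0
    out[:, nz] = (values[:, nz] - lo[nz]) / span[nz]
    np.clip(out, 0.0, 1.0, out=out)
    if isinstance(X, DataMatrix):
        return X.with_values(out)
    return out


def stratified_split(X: DataMatrix, ratio: float = 0.8, seed: int = 0) -> SplitSpec:
    """Deterministic stratified train/test split with train fraction ≈ ratio."""
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must lie strictly in (0, 1), got {ratio}")
    classes, counts = np.unique(X.labels, return_counts=True)
    singletons = classes[counts < 2]
    if singletons.size:
        raise ValueError(
            f"classes with a single sample cannot be split: {singletons.tolist()}; "
            "merge or remove them"
        )
    idx = np.arange(X.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=ratio,
        random_state=seed,
        stratify=X.labels,
        shuffle=True,
    )
    return SplitSpec(train_indices=train_idx, test_indices=test_idx,
                     ratio=ratio, seed=seed)
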