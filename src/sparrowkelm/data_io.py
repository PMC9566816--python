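"""Dataset loading, preprocessing and fold splitting.

Covers the tabular-classification plumbing: delimited-text loading against
a small schema (label column, positive value, missing markers), removal of
rows with missing cells, [-1, 1] min-max normalization, seeded k-fold
splitting, and a synthetic two-class generator that stands in for the real
clinical tables so the whole pipeline is testable offline.

Missing cells are represented internally as NaN. ``provenance`` records
every applied transform in order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Dataset",
    "SynthConfig",
    "load_schema",
    "builtin_schema",
    "load_table",
    "drop_missing",
    "normalize_minmax",
    "fit_minmax",
    "apply_minmax",
    "kfold_indices",
    "synth_generate",
]

BUILTIN_SCHEMAS = (
    "breast_cancer",
    "heart_disease",
    "parkinson",
    "autism_child",
    "cleveland",
    "bupa",
)


@dataclass
class Dataset:
    features: np.ndarray  # n x d, NaN marks missing
    labels: np.ndarray  # {+1, -1}
    feature_names: List[str]
    positive_label_name: str = "positive"
    provenance: List[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(
            features=df.to_numpy(dtype=float),
            labels=labels.astype(float),
            feature_names=list(df.columns),
            provenance=[f"loaded from {path}"],
        )


@dataclass
class SynthConfig:
    n_samples: int = 300
    n_informative_features: int = 5
    n_noise_features: int = 3
    class_separation: float = 3.0
    positive_fraction: float = 0.5
    missing_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")


def load_schema(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def builtin_schema(name: str) -> dict:
    """One of the shipped schemas for the six clinical UCI-style tables."""
    if name not in BUILTIN_SCHEMAS:
        raise KeyError(f"no builtin schema {name!r}; have {BUILTIN_SCHEMAS}")
    ref = resources.files("sparrowkelm") / "schemas" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def load_table(path, schema: dict) -> Dataset:
    """Load a delimited text file into a Dataset using a schema.

    Schema keys: ``label_column`` (name or 0-based index), ``positive_values``
    (list of raw label values mapped to +1) or ``label_rule:
    greater_than_zero``, ``missing_markers`` (default ``["?", ""]``),
    ``drop_columns``, ``categorical_columns``, ``delimiter``, ``header``
    (bool, default true), ``positive_label_name``.
    """
    delimiter = schema.get("delimiter", ",")
    header = 0 if schema.get("header", True) else None
    markers = schema.get("missing_markers", ["?", ""])
    df = pd.read_csv(
        path, delimiter=delimiter, header=header, na_values=markers,
        keep_default_na=True, skipinitialspace=True,
    )
    if header is None:
        df.columns = [f"col{i}" for i in range(df.shape[1])]

    label_col = schema["label_column"]
    if isinstance(label_col, int):
        label_col = df.columns[label_col]
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {list(df.columns)}")

    for col in schema.get("drop_columns", []):
        if col in df.columns:
            df = df.drop(columns=[col])

    raw_labels = df.pop(label_col)
    if schema.get("label_rule") == "greater_than_zero":
        labels = np.where(pd.to_numeric(raw_labels) > 0, 1.0, -1.0)
    else:
        positive_values = schema["positive_values"]
        known = set(schema.get("negative_values", [])) | set(positive_values)
        raw_str = raw_labels.astype(str).str.strip()
        if schema.get("negative_values"):
            unknown = sorted(set(raw_str) - {str(v) for v in known})
            if unknown:
                raise ValueError(f"unknown label values: {unknown}")
        labels = np.where(raw_str.isin([str(v) for v in positive_values]), 1.0, -1.0)

    for col in schema.get("categorical_columns", []):
        if col not in df.columns:
            continue
        cats = sorted(df[col].dropna().astype(str).unique())
        mapping = {c: i for i, c in enumerate(cats)}
        df[col] = df[col].map(lambda v: mapping.get(str(v), np.nan) if pd.notna(v) else np.nan)

    try:
        features = df.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable non-numeric cells: {exc}") from exc

    return Dataset(
        features=features,
        labels=labels,
        feature_names=list(df.columns),
        positive_label_name=schema.get("positive_label_name", "positive"),
        provenance=[f"loaded {path}"],
    )


def drop_missing(ds: Dataset) -> Dataset:
    """Remove every row containing at least one missing cell (idempotent)."""
    mask = ~np.any(np.isnan(ds.features), axis=1)
    removed = int(np.sum(~mask))
    if mask.sum() == 0:
        warnings.warn("all rows contained missing values; dataset is empty", stacklevel=2)
    return replace(
        ds,
        features=ds.features[mask],
        labels=ds.labels[mask],
        provenance=ds.provenance + [f"drop_missing removed {removed} rows"],
    )


def fit_minmax(X: np.ndarray):
    """Column minima/maxima for the [-1, 1] map, fitted on training data."""
    X = np.asarray(X, dtype=float)
    return X.min(axis=0), X.max(axis=0)


def apply_minmax(X: np.ndarray, params) -> np.ndarray:
    """Map x -> 2 (x - min)/(max - min) - 1; constant columns map to 0.

    Values outside the fitted range map outside [-1, 1] and are not clipped.
    """
    lo, hi = params
    span = hi - lo
    const = span == 0
    safe_span = np.where(const, 1.0, span)
    out = 2.0 * (np.asarray(X, dtype=float) - lo) / safe_span - 1.0
    out[:, const] = 0.0
    return out


def normalize_minmax(ds: Dataset) -> Dataset:
    """Normalize every column of the whole dataset to [-1, 1]."""
    if np.any(np.isnan(ds.features)):
        raise ValueError("normalize_minmax requires a dataset without missing values")
    lo, hi = fit_minmax(ds.features)
    if np.any(hi == lo):
        warnings.warn("constant columns normalized to 0", stacklevel=2)
    return replace(
        ds,
        features=apply_minmax(ds.features, (lo, hi)),
        provenance=ds.provenance + ["normalized to [-1, 1]"],
    )


def kfold_indices(n: int, k: int, seed=None) -> List[np.ndarray]:
    """Seeded shuffle then contiguous split into k folds (sizes differ <= 1)."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def synth_generate(config: SynthConfig) -> Dataset:
    """Two multivariate-normal classes plus pure-noise features.

    Informative coordinates have unit within-class standard deviation and
    class mean vectors ``class_separation`` apart in Euclidean distance;
    optional uniform missing-cell injection at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    d_inf = config.n_informative_features
    d_noise = config.n_noise_features
    n_pos = int(round(config.positive_fraction * n))
    labels = np.concatenate([np.ones(n_pos), -np.ones(n - n_pos)])

    offset = config.class_separation / (2.0 * np.sqrt(d_inf)) if d_inf else 0.0
    informative = rng.standard_normal((n, d_inf)) + labels[:, None] * offset
    noise = rng.standard_normal((n, d_noise))
    features = np.hstack([informative, noise])

    if config.missing_rate > 0:
        mask = rng.uniform(size=features.shape) < config.missing_rate
        features[mask] = np.nan

    perm = rng.permutation(n)
    names = [f"x{i}" for i in range(d_inf)] + [f"noise{i}" for i in range(d_noise)]
    return Dataset(
        features=features[perm],
        labels=labels[perm],
        feature_names=names,
        provenance=[f"synthetic two-class generator ({config})"],
    )
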