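"""Cohort preprocessing: labels, numeric encoding, standardization, folds.

The classifier input is one numeric column per risk factor: continuous
features pass through, categorical features keep their survey integer
codes as ordinal numerics (the published architecture's 15-neuron input
layer — 14 risk factors plus the reconstruction-error feature — rules
out one-hot blocks).  Standardization is the usual z-score with the
population (divide-by-n) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    ANOMALY_COLUMN,
    CATEGORICAL_FEATURES,
    CATEGORY_CODES,
    CONTINUOUS_FEATURES,
    DISORDER_FLAGS,
    FEATURE_ORDER,
    LABEL_COLUMN,
    CohortSchemaError,
)

__all__ = [
    "FeatureMatrix",
    "Standardizer",
    "FoldPlan",
    "derive_labels",
    "encode_features",
    "fit_standardizer",
    "apply_standardizer",
    "make_folds",
]


@dataclass
class FeatureMatrix:
    """An n x d numeric matrix with named, ordered columns."""

    values: np.ndarray
    column_names: list[str]
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column count does not match column_names")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def derive_labels(flags) -> np.ndarray:
    """Binary label per row: 1 iff any of the 6 disorder flags is 1."""
    if isinstance(flags, pd.DataFrame):
        missing = [f for f in DISORDER_FLAGS if f not in flags.columns]
        if missing:
            raise CohortSchemaError(f"missing disorder-flag columns: {missing}")
        arr = flags[DISORDER_FLAGS].to_numpy()
    else:
        arr = np.asarray(flags)
    if arr.ndim != 2 or arr.shape[1] != len(DISORDER_FLAGS):
        raise ValueError(f"expected {len(DISORDER_FLAGS)} flag columns")
    if not np.isin(arr, [0, 1]).all():
        raise ValueError("disorder flags must be 0/1")
    return (arr == 1).any(axis=1).astype(int)


def encode_features(
    table: pd.DataFrame, features: list[str] | None = None
) -> FeatureMatrix:
    """Encode a cohort table as a numeric matrix in canonical column order.

    Continuous features pass through; categorical features contribute
    their integer codes as a single ordinal column each (special codes
    8/9/88 included).  Input column order is irrelevant — the output is
    always in the canonical order, restricted to *features* if given.
    """
    if features is None:
        features = FEATURE_ORDER
    else:
        unknown = [f for f in features if f not in FEATURE_ORDER]
        if unknown:
            raise CohortSchemaError(f"unknown features: {unknown}")
        features = [f for f in FEATURE_ORDER if f in features]
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise CohortSchemaError(f"missing feature columns: {missing}")
    cols = []
    for feat in features:
        col = pd.to_numeric(table[feat], errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            rows = np.nonzero(np.isnan(col))[0][:5].tolist()
            raise CohortSchemaError(
                f"non-numeric or missing values in {feat!r} at rows {rows}"
            )
        if feat in CATEGORICAL_FEATURES:
            codes = set(CATEGORY_CODES[feat].values())
            bad = ~np.isin(col, list(codes))
            if bad.any():
                rows = np.nonzero(bad)[0][:5].tolist()
                raise CohortSchemaError(
                    f"unknown category codes in {feat!r} at rows {rows}"
                )
        cols.append(col)
    return FeatureMatrix(np.column_stack(cols), list(features), standardized=False)


@dataclass
class Standardizer:
    """Per-column z-score parameters (population-SD convention)."""

    means: np.ndarray
    sds: np.ndarray
    column_names: list[str]

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "column_names": list(self.column_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(
            np.asarray(d["means"], dtype=float),
            np.asarray(d["sds"], dtype=float),
            list(d["column_names"]),
        )

    def transform(self, X: FeatureMatrix) -> FeatureMatrix:
        if X.column_names != self.column_names:
            raise ValueError("column names/order do not match the fitted params")
        return FeatureMatrix(
            (X.values - self.means) / self.sds, list(X.column_names), standardized=True
        )

    def inverse_transform(self, X: FeatureMatrix) -> FeatureMatrix:
        if X.column_names != self.column_names:
            raise ValueError("column names/order do not match the fitted params")
        return FeatureMatrix(
            X.values * self.sds + self.means, list(X.column_names), standardized=False
        )


def fit_standardizer(X: FeatureMatrix) -> Standardizer:
    """Fit per-column mean/SD on (training) rows; rejects constant columns."""
    means = X.values.mean(axis=0)
    sds = X.values.std(axis=0)  # population convention (ddof=0)
    constant = np.nonzero(sds <= 0)[0]
    if constant.size:
        names = [X.column_names[i] for i in constant]
        raise ValueError(f"constant columns cannot be standardized: {names}")
    return Standardizer(means, sds, list(X.column_names))


def apply_standardizer(params: Standardizer, X: FeatureMatrix) -> FeatureMatrix:
    return params.transform(X)


@dataclass
class FoldPlan:
    """A k-way partition of rows: ``assignments[i]`` is row i's fold."""

    k: int
    assignments: np.ndarray

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        counts = np.bincount(self.assignments, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every fold must be nonempty")
        if self.assignments.min() < 0 or self.assignments.max() >= self.k:
            raise ValueError("fold indices out of range")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments != fold)[0]


def make_folds(n: int, k: int, stratify_on, seed: int = 0) -> FoldPlan:
    """Seeded stratified k-fold plan.

    Within each label class, rows are shuffled and dealt round-robin,
    continuing the deal across classes so overall fold sizes differ by
    at most one while each class is split as evenly as possible.
    """
    y = np.asarray(stratify_on)
    if len(y) != n:
        raise ValueError("stratify_on length must equal n")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} rows")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        assignments[idx] = (offset + np.arange(len(idx))) % k
        offset += len(idx)
    return FoldPlan(k, assignments)
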