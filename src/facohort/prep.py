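"""Pre-modelling steps: variable removal, attendance binning, sample
weighting, train/test splitting and feature standardization.

The attendance target is binned into the three classes used throughout:
class 0 (low, < 5 visits), class 1 (mid, 5-10 visits) and class 2 (high
intensity use, > 10 visits).  Patients with fewer than three visits violate
the cohort inclusion criterion and are rejected, never silently binned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .config import TARGET_COLUMN

__all__ = [
    "InclusionCriterionError",
    "SampleWeighting",
    "EncodedDesign",
    "DEFAULT_EXCLUSIONS",
    "bin_attendance",
    "drop_excluded_variables",
    "compute_sample_weights",
    "split_train_test",
    "encode_features",
]

#: Variables removed before modelling on externally supplied tables: the
#: SPARRA score is derived from other variables in the table and the local
#: authority duplicates the geographic signal carried by the SIMD quintile.
#: The synthetic generator never emits either, so this is a no-op there.
DEFAULT_EXCLUSIONS = ("sparra_score", "local_authority")

N_CLASSES = 3


class InclusionCriterionError(ValueError):
    """Attendance below the three-visit cohort inclusion threshold."""


def bin_attendance(v):
    """Map attendance counts to classes 0 (<5), 1 (5-10), 2 (>10).

    Accepts a scalar or array; counts below 3 raise
    :class:`InclusionCriterionError`.
    """
    arr = np.asarray(v)
    if np.any(arr < 3):
        raise InclusionCriterionError(
            "attendance counts below 3 violate the cohort inclusion criterion"
        )
    classes = np.where(arr < 5, 0, np.where(arr <= 10, 1, 2))
    return classes if arr.ndim else int(classes)


def drop_excluded_variables(table: pd.DataFrame, exclusions=DEFAULT_EXCLUSIONS) -> pd.DataFrame:
    """Drop excluded columns (those absent are ignored); the target is protected."""
    if TARGET_COLUMN in exclusions:
        raise ValueError(f"cannot exclude the target column {TARGET_COLUMN!r}")
    present = [c for c in exclusions if c in table.columns]
    return table.drop(columns=present)


@dataclass
class SampleWeighting:
    """Per-sample training weights.

    ``inverse_class_frequency`` uses the balanced convention
    w_c = N / (K * n_c), so each class carries equal total weight and the
    weights sum to N.  ``visit_value`` weights each sample by its attendance
    count relative to the cohort mean, so clinically heavier patients weigh
    more regardless of class frequency.
    """

    strategy: str
    weights: np.ndarray
    class_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("sample weights must be non-negative")


def compute_sample_weights(
    labels=None,
    visit_counts=None,
    strategy: str = "inverse_class_frequency",
) -> SampleWeighting:
    if strategy == "inverse_class_frequency":
        if labels is None:
            raise ValueError("inverse_class_frequency weighting needs class labels")
        labels = np.asarray(labels)
        if labels.size == 0:
            raise ValueError("empty label array")
        n = labels.size
        class_weights = {}
        for c in range(N_CLASSES):
            n_c = int((labels == c).sum())
            if n_c == 0:
                raise ValueError(f"class {c} has no samples; cannot weight inversely")
            class_weights[c] = n / (N_CLASSES * n_c)
        w = np.array([class_weights[c] for c in labels], dtype=float)
        return SampleWeighting("inverse_class_frequency", w, class_weights)
    if strategy == "visit_value":
        if visit_counts is None:
            raise ValueError("visit_value weighting needs attendance counts")
        v = np.asarray(visit_counts, dtype=float)
        if v.size == 0:
            raise ValueError("empty visit-count array")
        return SampleWeighting("visit_value", v / v.mean())
    raise ValueError(f"unknown weighting strategy {strategy!r}")


def split_train_test(
    table: pd.DataFrame,
    test_fraction: float = 0.30,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint train/test partition.

    The test set takes ``floor(n * test_fraction)`` rows overall; with
    ``stratified=True`` the floor is applied per attendance class, so each
    class's test share is within one record of the fraction.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(table)
    if stratified:
        classes = bin_attendance(table[TARGET_COLUMN].to_numpy())
        test_idx = []
        for c in range(N_CLASSES):
            idx = np.flatnonzero(classes == c)
            perm = rng.permutation(idx)
            test_idx.append(perm[: int(np.floor(len(idx) * test_fraction))])
        test_idx = np.sort(np.concatenate(test_idx))
    else:
        perm = rng.permutation(n)
        test_idx = np.sort(perm[: int(np.floor(n * test_fraction))])
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    train = table.iloc[~mask].reset_index(drop=True)
    test = table.iloc[mask].reset_index(drop=True)
    return train, test


@dataclass
class EncodedDesign:
    """A design matrix together with its (train-fitted) standardization.

    ``raw`` keeps the unstandardized values: the Shapley zero-substitution
    semantics operate in raw feature space before re-encoding.
    """

    raw: pd.DataFrame
    matrix: np.ndarray
    columns: list
    center: np.ndarray
    scale: np.ndarray

    def transform(self, raw: pd.DataFrame) -> np.ndarray:
        return (raw[self.columns].to_numpy(dtype=float) - self.center) / self.scale

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        return matrix * self.scale + self.center


def encode_features(
    train: pd.DataFrame,
    test: pd.DataFrame,
    columns=None,
) -> tuple[EncodedDesign, EncodedDesign]:
    """Standardize feature columns with parameters fitted on training rows only.

    Zero-variance columns get scale 1 (with a warning), leaving them centred
    but unscaled.  The test table is transformed with the train parameters, so
    its columns need not have zero mean — there is no information leakage.
    """
    if columns is None:
        columns = [c for c in train.columns if c != TARGET_COLUMN]
    if list(train.columns) != list(test.columns):
        raise ValueError("train and test tables must share an identical schema")
    scaler = StandardScaler()
    x_train = scaler.fit_transform(train[columns].to_numpy(dtype=float))
    zero_var = np.flatnonzero(scaler.var_ == 0)
    if len(zero_var):
        warnings.warn(
            f"zero-variance columns scaled by 1: {[columns[i] for i in zero_var]}"
        )
    x_test = scaler.transform(test[columns].to_numpy(dtype=float))
    center = scaler.mean_
    scale = scaler.scale_
    return (
        EncodedDesign(train[columns].copy(), x_train, list(columns), center, scale),
        EncodedDesign(test[columns].copy(), x_test, list(columns), center, scale),
    )
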