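"""Shapley-value feature importance: two fast approximations, an exact
oracle, and cohort-targeted risk-factor ranking.

The attribution target is a scalar risk score derived from the classifier's
class probabilities — by default the expected attendance class
sum_c c * p_c(x), which yields one signed value per feature (positive means
the feature's presence raises predicted attendance risk).

Three estimators share that value function:

- :func:`zero_input_importance` — occlusion: the mean change in score when a
  feature is set to 0 for every row, in raw feature space (re-encoding
  happens inside the model, so "absence" is a raw zero, not a cohort mean);
- :func:`permutation_shapley` — Monte-Carlo sampling of feature orderings
  with absent features drawn from a background distribution (empirical
  marginal resampling by default);
- :func:`exact_shapley` — full subset enumeration with the Shapley kernel
  weights, guarded to at most 12 features; the validation oracle, satisfying
  efficiency, symmetry and dummy exactly.

Ordinal features (age group, SIMD quintile) are zero-substituted as-is even
though 0 lies outside their coded range; the occlusion operation is applied
uniformly to every feature, and the resulting raw zero simply denotes
"feature absent".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceResult",
    "RiskFactorTable",
    "risk_score",
    "zero_input_importance",
    "permutation_shapley",
    "exact_shapley",
    "cohort_risk_factors",
]

CLASS_VALUES = np.array([0.0, 1.0, 2.0])

EXACT_FEATURE_GUARD = 12


def _score_fn(model, mode):
    """Build a vectorised score function ndarray/DataFrame -> 1-D scores."""
    if callable(model) and not hasattr(model, "predict_proba"):
        return lambda x: np.asarray(model(np.asarray(x, dtype=float)), dtype=float)
    if mode == "expected_class":
        return lambda x: model.predict_proba(x) @ CLASS_VALUES
    if isinstance(mode, tuple) and mode[0] == "class_probability":
        c = int(mode[1])
        return lambda x: model.predict_proba(x)[:, c]
    raise ValueError(
        f"unknown score mode {mode!r}; use 'expected_class' or "
        "('class_probability', c)"
    )


def _as_matrix(table) -> tuple[np.ndarray, list]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    x = np.asarray(table, dtype=float)
    return x, list(range(x.shape[1]))


@dataclass
class ImportanceResult:
    """Signed per-feature importance values with provenance."""

    method: str
    features: list
    values: np.ndarray
    model_id: str | None = None
    cohort: str = "all"
    mode: object = "expected_class"
    stderr: np.ndarray | None = None
    n_permutations: int | None = None
    seed: int | None = None
    background: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.features):
            raise ValueError("one value per feature required")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.features, name=self.method)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.features, "value": self.values})
        df["method"] = self.method
        df["model"] = self.model_id
        df["cohort"] = self.cohort
        return df


def risk_score(model, table, mode="expected_class") -> np.ndarray:
    """Scalar risk per row: expected class sum_c c * p_c(x) by default."""
    return _score_fn(model, mode)(table)


def zero_input_importance(
    model,
    table,
    feature=None,
    mode="expected_class",
    model_id=None,
    cohort="all",
):
    """Occlusion importance: mean score drop when a feature is zeroed.

    With ``feature`` given, returns the signed scalar for that feature;
    otherwise an :class:`ImportanceResult` over all columns.
    """
    x, columns = _as_matrix(table)
    score = _score_fn(model, mode)
    base = score(x)

    def one(j: int) -> float:
        xz = x.copy()
        xz[:, j] = 0.0
        return float(np.mean(base - score(xz)))

    if feature is not None:
        j = columns.index(feature) if feature in columns else int(feature)
        return one(j)
    values = np.array([one(j) for j in range(x.shape[1])])
    return ImportanceResult(
        "zero_input", columns, values, model_id=model_id, cohort=cohort, mode=mode
    )


def permutation_shapley(
    model,
    table,
    mode="expected_class",
    n_permutations: int = 200,
    seed: int = 0,
    background="marginal",
    model_id=None,
    cohort="all",
) -> ImportanceResult:
    """Monte-Carlo Shapley values over sampled feature orderings.

    For each sampled ordering, features not yet added take background values
    — drawn independently per column from the table's empirical marginals
    (``background="marginal"``) or from a fixed vector — and phi_j is the
    mean change in score when feature j is added, averaged over rows and
    orderings.  ``stderr`` is the Monte-Carlo standard error across
    orderings.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    x, columns = _as_matrix(table)
    n, d = x.shape
    score = _score_fn(model, mode)
    rng = np.random.default_rng(seed)
    fixed = None
    if not (isinstance(background, str) and background == "marginal"):
        fixed = np.asarray(background, dtype=float)
        if fixed.shape != (d,):
            raise ValueError("fixed background must have one value per feature")

    contrib = np.zeros((n_permutations, d))
    for t in range(n_permutations):
        order = rng.permutation(d)
        if fixed is None:
            cur = np.empty_like(x)
            for j in range(d):
                cur[:, j] = x[rng.integers(0, n, size=n), j]
        else:
            cur = np.tile(fixed, (n, 1))
        prev = score(cur)
        for j in order:
            cur[:, j] = x[:, j]
            s = score(cur)
            contrib[t, j] = np.mean(s - prev)
            prev = s
    values = contrib.mean(axis=0)
    stderr = (
        contrib.std(axis=0, ddof=1) / math.sqrt(n_permutations)
        if n_permutations > 1
        else np.full(d, np.nan)
    )
    return ImportanceResult(
        "permutation",
        columns,
        values,
        model_id=model_id,
        cohort=cohort,
        mode=mode,
        stderr=stderr,
        n_permutations=n_permutations,
        seed=seed,
        background="marginal" if fixed is None else "fixed",
    )


def exact_shapley(
    model,
    instance,
    background=None,
    mode="expected_class",
) -> np.ndarray:
    """Exact Shapley values by subset enumeration (<= 12 features).

    phi_j = sum over S not containing j of |S|!(d-|S|-1)!/d! times
    [v(S + j) - v(S)], where v(S) scores the instance with features outside
    S replaced by the background (all zeros by default, matching the
    zero-input notion of absence).
    """
    inst = np.asarray(instance, dtype=float).ravel()
    d = inst.size
    if d > EXACT_FEATURE_GUARD:
        raise ValueError(
            f"exact Shapley enumeration refused for {d} features "
            f"(guard: {EXACT_FEATURE_GUARD}); use permutation_shapley"
        )
    bg = np.zeros(d) if background is None else np.asarray(background, dtype=float).ravel()
    score = _score_fn(model, mode)

    # value of every coalition in one vectorised batch
    masks = (np.arange(2**d)[:, None] >> np.arange(d)) & 1
    points = np.where(masks.astype(bool), inst, bg)
    v = score(points)

    fact = [math.factorial(i) for i in range(d + 1)]
    phi = np.zeros(d)
    sizes = masks.sum(axis=1)
    for j in range(d):
        without_j = np.flatnonzero(masks[:, j] == 0)
        s = sizes[without_j]
        weights = np.array([fact[k] * fact[d - k - 1] / fact[d] for k in s])
        phi[j] = float(weights @ (v[without_j | (1 << j)] - v[without_j]))
    return phi


@dataclass
class RiskFactorTable:
    """Ranked risk factors above a reporting threshold on |phi|."""

    entries: pd.DataFrame
    threshold: float
    method: str
    model_id: str | None = None
    cohort: str = "all"

    def to_csv(self, path) -> None:
        df = self.entries.copy()
        df["method"] = self.method
        df["model"] = self.model_id
        df["cohort"] = self.cohort
        df.to_csv(path, index=False)


COHORT_SELECTORS = {
    "all": (0, 1, 2),
    "low_mid": (0, 1),
    "high": (2,),
}


def cohort_risk_factors(
    model,
    table,
    labels,
    selector: str = "low_mid",
    method: str = "zero_input",
    threshold: float = 0.01,
    mode="expected_class",
    n_permutations: int = 200,
    seed: int = 0,
    model_id=None,
) -> RiskFactorTable:
    """Rank risk factors on a targeted sub-cohort of the evaluation rows.

    ``low_mid`` restricts to actual classes {0, 1} (escalation risks among
    patients not yet high attenders); ``high`` to class {2} (targets for
    reducing attendance).  The model is probed, never refitted, per cohort.
    Features with |phi| <= ``threshold`` are dropped; the rest are ranked by
    phi descending, ties broken by feature name.
    """
    if selector not in COHORT_SELECTORS:
        raise ValueError(f"selector must be one of {sorted(COHORT_SELECTORS)}")
    labels = np.asarray(labels)
    keep = np.isin(labels, COHORT_SELECTORS[selector])
    if not keep.any():
        raise ValueError(f"no rows in cohort {selector!r}")
    sub = table.iloc[keep] if isinstance(table, pd.DataFrame) else table[keep]

    if method == "zero_input":
        result = zero_input_importance(
            model, sub, mode=mode, model_id=model_id, cohort=selector
        )
    elif method == "permutation":
        result = permutation_shapley(
            model, sub, mode=mode, n_permutations=n_permutations, seed=seed,
            model_id=model_id, cohort=selector,
        )
    else:
        raise ValueError("method must be 'zero_input' or 'permutation'")

    df = pd.DataFrame({"feature": result.features, "value": result.values})
    df = df[df["value"].abs() > threshold]
    df = df.sort_values(
        ["value", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return RiskFactorTable(df, threshold, method, model_id=model_id, cohort=selector)
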