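"""Synthetic A&E frequent-attendance cohort generator.

Produces seeded cohorts of patients with at least three emergency-department
attendances per year whose marginal statistics match the published cohort
(size, attendance-class counts, mean/SD of visit counts) and whose
feature-attendance relationships plant known signed effects, so that the full
modelling and risk-factor pipeline can be exercised and validated without any
access to patient-level NHS data.

Generation runs in four documented stages off a single seeded RNG stream:

1. feature draws from independent marginals (:func:`generate_features`),
2. rank-based class assignment from a latent linear risk
   (:func:`assign_classes`) — exact class counts by construction,
3. visit-count draws inside each class (:func:`draw_visit_counts`), with the
   low class fixed at the printed threes/fours composition and the mid/high
   class distributions solved to match the target moments
   (:func:`calibrate_count_distributions`),
4. assembly into a validated table (:func:`generate_cohort`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import (
    COHORT_COLUMNS,
    FEATURE_COLUMNS,
    LTC_COLUMNS,
    TARGET_COLUMN,
    ConfigurationError,
    GeneratorConfig,
    WithinClassCountParams,
)

__all__ = [
    "CalibrationError",
    "CohortValidationError",
    "CohortTable",
    "calibrate_count_distributions",
    "generate_features",
    "assign_classes",
    "draw_visit_counts",
    "generate_cohort",
    "load_cohort",
    "validate_cohort",
]


class CalibrationError(ValueError):
    """Raised when the requested visit-count moments are unattainable."""


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema or its invariants."""


@dataclass
class CohortTable:
    """A generated cohort with provenance."""

    table: pd.DataFrame
    seed: int | None = None
    config_hash: str | None = None

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def features(self) -> pd.DataFrame:
        return self.table.drop(columns=[TARGET_COLUMN])

    @property
    def visits(self) -> np.ndarray:
        return self.table[TARGET_COLUMN].to_numpy()


# ---------------------------------------------------------------------------
# moment calibration
# ---------------------------------------------------------------------------

def _truncated_geometric(lo: int, hi: int, q: float) -> tuple[np.ndarray, float, float]:
    """Probabilities p(k) ∝ q**(k-lo) on lo..hi with first two moments."""
    k = np.arange(lo, hi + 1, dtype=float)
    logw = (k - lo) * np.log(q)
    w = np.exp(logw - logw.max())
    p = w / w.sum()
    return p, float(p @ k), float(p @ k**2)


def calibrate_count_distributions(
    mean: float,
    sd: float,
    class_counts,
    class0_composition,
    max_visits: int = 60,
) -> WithinClassCountParams:
    """Solve the within-class visit-count distributions for target moments.

    The low class is pinned to its exact threes/fours composition; the mid
    (5-10 visits) and high (>10 visits) classes each take a truncated
    geometric distribution whose decay rates are solved numerically so that
    the full mixture's mean and standard deviation hit the targets.  The
    geometric family is one admissible choice for an under-determined problem;
    any family matching the moments would do.

    Deterministic — no random numbers are involved.
    """
    n0a, n0b = class0_composition
    n1, n2 = int(class_counts[1]), int(class_counts[2])
    n = int(sum(class_counts))
    if n == 0:
        raise CalibrationError("empty cohort: no counts to calibrate")

    target_sum = mean * n
    target_sumsq = (sd**2 + mean**2) * n
    rem_sum = target_sum - (3 * n0a + 4 * n0b)
    rem_sumsq = target_sumsq - (9 * n0a + 16 * n0b)

    uniform1 = np.full(6, 1 / 6)
    uniform2 = np.full(max_visits - 10, 1.0 / (max_visits - 10))

    if n1 == 0 and n2 == 0:
        # degenerate: the class-0 composition alone must realise the targets
        got_mean = (3 * n0a + 4 * n0b) / n
        got_var = (9 * n0a + 16 * n0b) / n - got_mean**2
        if abs(got_mean - mean) > 1e-9:
            raise CalibrationError(
                f"mean infeasible: class-0 composition forces mean {got_mean:.6g}, "
                f"target {mean:.6g}"
            )
        if abs(np.sqrt(max(got_var, 0.0)) - sd) > 1e-9:
            raise CalibrationError(
                f"sd infeasible: class-0 composition forces sd "
                f"{np.sqrt(max(got_var, 0.0)):.6g}, target {sd:.6g}"
            )
        return WithinClassCountParams(uniform1, uniform2, max_visits)

    lo_sum = 5 * n1 + 11 * n2
    hi_sum = 10 * n1 + max_visits * n2
    if not (lo_sum <= rem_sum <= hi_sum):
        raise CalibrationError(
            f"mean infeasible: classes 1-2 must contribute {rem_sum:.1f} visits, "
            f"achievable range is [{lo_sum}, {hi_sum}]"
        )

    def mean1_of(q1: float) -> float:
        return _truncated_geometric(5, 10, q1)[1]

    def solve_q1(target_m1: float) -> float:
        lo, hi = 1e-6, 1e6
        if not (mean1_of(lo) <= target_m1 <= mean1_of(hi)):
            raise CalibrationError(
                f"mean infeasible: class-1 mean {target_m1:.4f} outside (5, 10)"
            )
        return brentq(lambda q: mean1_of(q) - target_m1, lo, hi, xtol=1e-12)

    if n2 == 0:
        q1 = solve_q1(rem_sum / n1)
        p1, _, m2 = _truncated_geometric(5, 10, q1)
        params = WithinClassCountParams(p1, uniform2, max_visits)
    elif n1 == 0:
        q2 = brentq(
            lambda q: _truncated_geometric(11, max_visits, q)[1] - rem_sum / n2,
            1e-6, 1e6, xtol=1e-12,
        )
        p2 = _truncated_geometric(11, max_visits, q2)[0]
        params = WithinClassCountParams(uniform1, p2, max_visits)
    else:
        m1_lo, m1_hi = mean1_of(1e-6), mean1_of(1e6)

        def sumsq_residual(q2: float) -> float:
            p2, m1c2, m2c2 = _truncated_geometric(11, max_visits, q2)
            m1c1_req = float(np.clip((rem_sum - n2 * m1c2) / n1, m1_lo, m1_hi))
            q1 = solve_q1(m1c1_req)
            _, _, m2c1 = _truncated_geometric(5, 10, q1)
            return n1 * m2c1 + n2 * m2c2 - rem_sumsq

        # bracket the root over a wide grid of decay rates
        grid = np.geomspace(1e-4, 1e2, 400)
        vals = np.array([sumsq_residual(q) for q in grid])
        sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if len(sign_change) == 0:
            raise CalibrationError(
                f"sd infeasible: cannot reach second moment {rem_sumsq:.1f} for "
                f"classes 1-2 with max_visits={max_visits}"
            )
        i = sign_change[0]
        q2 = brentq(sumsq_residual, grid[i], grid[i + 1], xtol=1e-13)
        p2, m1c2, _ = _truncated_geometric(11, max_visits, q2)
        q1 = solve_q1((rem_sum - n2 * m1c2) / n1)
        p1 = _truncated_geometric(5, 10, q1)[0]
        params = WithinClassCountParams(p1, p2, max_visits)

    got_mean, got_sd = params.moments(class_counts, class0_composition)
    if abs(got_mean - mean) > 0.01:
        raise CalibrationError(
            f"mean infeasible: calibrated mixture mean {got_mean:.4f} vs target {mean}"
        )
    if abs(got_sd - sd) > 0.02:
        raise CalibrationError(
            f"sd infeasible: calibrated mixture sd {got_sd:.4f} vs target {sd}"
        )
    return params


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def generate_features(n: int, feature_marginals: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n independent patient feature rows; total_ltcs is computed."""
    cols: dict[str, np.ndarray] = {}
    for name in FEATURE_COLUMNS:
        spec = feature_marginals[name]
        family = spec[0]
        if family == "bernoulli":
            p = float(spec[1])
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}: bernoulli p={p} outside [0, 1]")
            cols[name] = (rng.random(n) < p).astype(np.int64)
        elif family == "categorical":
            probs = np.asarray(spec[1], dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
                raise ConfigurationError(f"{name}: invalid categorical probabilities")
            cols[name] = rng.choice(np.arange(1, len(probs) + 1), size=n, p=probs)
        elif family == "negbin":
            m, r = float(spec[1]), float(spec[2])
            if m < 0 or r <= 0:
                raise ConfigurationError(f"{name}: negbin needs mean >= 0, dispersion > 0")
            if m == 0:
                cols[name] = np.zeros(n, dtype=np.int64)
            else:
                # gamma-Poisson mixture: variance = m + m^2 / r
                lam = rng.gamma(shape=r, scale=m / r, size=n)
                cols[name] = rng.poisson(lam).astype(np.int64)
        else:
            raise ConfigurationError(f"{name}: unknown marginal family {family!r}")
    df = pd.DataFrame(cols, columns=FEATURE_COLUMNS)
    df["total_ltcs"] = df[LTC_COLUMNS].sum(axis=1)
    return df


def assign_classes(
    features: pd.DataFrame,
    effect_coefficients: dict,
    class_counts,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Assign exact class counts by ranking a noisy latent linear risk.

    Risk = sum of standardized features times their signed coefficients plus
    Gaussian noise; the ``class_counts[2]`` highest-risk rows become class 2,
    the next ``class_counts[1]`` class 1, the rest class 0.
    """
    n = len(features)
    if sum(class_counts) != n:
        raise ConfigurationError(
            f"class_counts sum {sum(class_counts)} != number of rows {n}"
        )
    risk = np.zeros(n)
    for name, beta in effect_coefficients.items():
        if beta == 0.0 or name not in features.columns:
            continue
        x = features[name].to_numpy(dtype=float)
        s = x.std()
        z = (x - x.mean()) / s if s > 0 else np.zeros(n)
        risk += beta * z
    risk += rng.normal(0.0, noise_sd, size=n)
    order = np.argsort(-risk, kind="stable")
    labels = np.zeros(n, dtype=np.int64)
    labels[order[: class_counts[2]]] = 2
    labels[order[class_counts[2]: class_counts[2] + class_counts[1]]] = 1
    return labels


def draw_visit_counts(
    labels: np.ndarray,
    class0_composition,
    params: WithinClassCountParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw attendance counts respecting the class boundaries.

    Class-0 rows receive exactly the configured number of threes and fours
    (assigned at random among class-0 rows); class-1 and class-2 rows draw
    from the calibrated within-class distributions.
    """
    labels = np.asarray(labels)
    v = np.zeros(len(labels), dtype=np.int64)
    idx0 = np.flatnonzero(labels == 0)
    n0a, n0b = class0_composition
    if n0a + n0b != len(idx0):
        raise ConfigurationError(
            f"class0_composition sums to {n0a + n0b} but there are {len(idx0)} "
            "class-0 rows"
        )
    shuffled = rng.permutation(idx0)
    v[shuffled[:n0a]] = 3
    v[shuffled[n0a:]] = 4
    idx1 = np.flatnonzero(labels == 1)
    if len(idx1):
        v[idx1] = _quota_draw(params.class1_support, params.class1_distribution, len(idx1), rng)
    idx2 = np.flatnonzero(labels == 2)
    if len(idx2):
        v[idx2] = _quota_draw(params.class2_support, params.class2_distribution, len(idx2), rng)
    return v


def _quota_draw(support: np.ndarray, probs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n values by stratified quota allocation, randomly ordered.

    Each value receives floor(n * p) guaranteed copies; the remaining few
    draws are sampled from the fractional remainders.  Expected per-value
    counts equal ``n * probs`` exactly, so the realised class moments are
    unbiased for the calibrated ones with far less noise than independent
    draws; which row receives which value stays random.
    """
    expected = probs * n
    counts = np.floor(expected).astype(np.int64)
    short = int(n - counts.sum())
    if short > 0:
        # systematic (probability-proportional) sampling of the fractional
        # remainders: each value gains at most one extra copy and the expected
        # gain equals its remainder exactly
        remainders = expected - counts
        cum = np.cumsum(remainders) * (short / remainders.sum())
        points = rng.random() + np.arange(short)
        extra = np.searchsorted(cum, points, side="right")
        np.add.at(counts, np.clip(extra, 0, len(counts) - 1), 1)
    return rng.permutation(np.repeat(support, counts))


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a full synthetic cohort from a validated config.

    All stochastic stages draw, in documented order (features, class noise,
    visit counts), from a single RNG seeded with ``config.seed``, so identical
    configs yield bit-identical tables.
    """
    config.validate()
    params = config.within_class_count_params
    if params is None:
        params = calibrate_count_distributions(
            config.mean_visits,
            config.sd_visits,
            config.class_counts,
            config.class0_composition,
            config.max_visits,
        )
    rng = np.random.default_rng(config.seed)
    features = generate_features(config.n_patients, config.feature_marginals, rng)
    labels = assign_classes(
        features, config.effect_coefficients, config.class_counts, rng, config.noise_sd
    )
    visits = draw_visit_counts(labels, config.class0_composition, params, rng)
    table = features.copy()
    table[TARGET_COLUMN] = visits
    return CohortTable(table, seed=config.seed, config_hash=config.config_hash())


# ---------------------------------------------------------------------------
# validation and IO
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly repair) a cohort table against the schema.

    Checks: column set, attendance >= 3 (the inclusion criterion), ordinal
    ranges, binary flags, and the LTC sum identity.  A missing ``total_ltcs``
    column is recomputed from the flags with a warning.
    """
    table = table.copy()
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing == {"total_ltcs"}:
        warnings.warn("total_ltcs column missing; recomputed from the LTC flags")
        table["total_ltcs"] = table[LTC_COLUMNS].sum(axis=1)
        missing = set()
    if missing:
        raise CohortValidationError(f"missing columns: {sorted(missing)}")
    extra = set(table.columns) - set(COHORT_COLUMNS)
    if extra:
        raise CohortValidationError(f"unexpected columns: {sorted(extra)}")
    table = table[COHORT_COLUMNS]

    v = table[TARGET_COLUMN].to_numpy()
    bad = np.flatnonzero(v < 3)
    if len(bad):
        raise CohortValidationError(
            f"attendance below the 3-visit inclusion criterion at rows {bad[:10].tolist()}"
        )
    for col, lo, hi in (("age_group", 1, 6), ("simd_quintile", 1, 5)):
        x = table[col].to_numpy()
        bad = np.flatnonzero((x < lo) | (x > hi))
        if len(bad):
            raise CohortValidationError(
                f"{col} outside {lo}..{hi} at rows {bad[:10].tolist()}"
            )
    for col in ["gender_male", "homeless_flag", "deceased_flag"] + LTC_COLUMNS:
        x = table[col].to_numpy()
        if not np.isin(x, (0, 1)).all():
            raise CohortValidationError(f"{col} must be a 0/1 flag")
    mismatch = np.flatnonzero(
        table["total_ltcs"].to_numpy() != table[LTC_COLUMNS].sum(axis=1).to_numpy()
    )
    if len(mismatch):
        raise CohortValidationError(
            f"total_ltcs does not equal the sum of LTC flags at rows {mismatch[:10].tolist()}"
        )
    return table


def load_cohort(path) -> CohortTable:
    """Read and validate a cohort CSV."""
    table = pd.read_csv(path)
    return CohortTable(validate_cohort(table))
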