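"""Configuration objects for the synthetic cohort generator.

The defaults encode the published marginal statistics of the study cohort
(17,437 patients with >= 3 A&E attendances in one year; attendance classes of
13,474 / 3,615 / 348 patients; 9,730 patients with exactly three visits) and a
set of signed latent-risk coefficients reproducing the cross-model consensus
effect directions (acute inpatient episodes, digestive/respiratory conditions,
alcohol, self-harm, mental-health episodes and male gender raising risk; age
group, SIMD quintile, deceased status, home care, cancer and cardiac conditions
lowering it).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Feature columns of a patient record, in generation order.  ``total_ltcs`` is
#: derived (sum of the ten LTC flags) and ``ae_attendances`` is the target.
FEATURE_COLUMNS = [
    "gender_male",
    "age_group",
    "simd_quintile",
    "homeless_flag",
    "deceased_flag",
    "home_care_episodes",
    "acute_inpatient_episodes",
    "mh_inpatient_episodes",
    "self_harm_episodes",
    "substance_misuse_episodes",
    "alcohol_episodes",
    "ltc_arthritis",
    "ltc_respiratory",
    "ltc_cardiac",
    "ltc_cancer",
    "ltc_cerebrovascular",
    "ltc_digestive",
    "ltc_neurological",
    "ltc_diabetes_endocrine",
    "ltc_renal",
    "ltc_other",
]

LTC_COLUMNS = [c for c in FEATURE_COLUMNS if c.startswith("ltc_")]

#: Full cohort-table schema: features, derived LTC total, attendance target.
COHORT_COLUMNS = FEATURE_COLUMNS + ["total_ltcs", "ae_attendances"]

TARGET_COLUMN = "ae_attendances"

#: Effects weaker than this are not guaranteed to be recoverable from a single
#: cohort realisation (see the sign-recovery property of the generator).
MIN_RELIABLE_EFFECT = 0.15


def default_feature_marginals() -> dict:
    """Marginal distribution per generated feature.

    Families: ``("bernoulli", p)``, ``("categorical", [p1..pk])`` for ordinals
    coded 1..k, and ``("negbin", mean, dispersion)`` for over-dispersed episode
    counts (gamma-Poisson with shape ``dispersion``).

    Values mimic the study cohort: predominantly male, young (the vast majority
    under 65), heavily skewed towards the most deprived SIMD quintiles (about
    three quarters in quintiles 1-2), with roughly 90% carrying at least one
    long-term condition.
    """
    return {
        "gender_male": ("bernoulli", 0.55),
        "age_group": ("categorical", [0.10, 0.19, 0.23, 0.21, 0.15, 0.12]),
        "simd_quintile": ("categorical", [0.52, 0.25, 0.10, 0.08, 0.05]),
        "homeless_flag": ("bernoulli", 0.03),
        "deceased_flag": ("bernoulli", 0.04),
        "home_care_episodes": ("negbin", 0.6, 0.4),
        "acute_inpatient_episodes": ("negbin", 0.9, 0.5),
        "mh_inpatient_episodes": ("negbin", 0.06, 0.3),
        "self_harm_episodes": ("negbin", 0.12, 0.3),
        "substance_misuse_episodes": ("negbin", 0.15, 0.3),
        "alcohol_episodes": ("negbin", 0.25, 0.3),
        "ltc_arthritis": ("bernoulli", 0.18),
        "ltc_respiratory": ("bernoulli", 0.30),
        "ltc_cardiac": ("bernoulli", 0.15),
        "ltc_cancer": ("bernoulli", 0.08),
        "ltc_cerebrovascular": ("bernoulli", 0.06),
        "ltc_digestive": ("bernoulli", 0.25),
        "ltc_neurological": ("bernoulli", 0.10),
        "ltc_diabetes_endocrine": ("bernoulli", 0.20),
        "ltc_renal": ("bernoulli", 0.05),
        "ltc_other": ("bernoulli", 0.12),
    }


def default_effect_coefficients() -> dict:
    """Signed latent-risk weights on standardized features.

    Signs follow the cross-model consensus of the study (positive raises
    attendance risk); magnitudes were fixed once so that every model family
    recovers the strong-effect signs, and are frozen here.  ``total_ltcs`` gets
    no weight of its own (it is collinear with the flags).
    """
    return {
        "acute_inpatient_episodes": 0.90,
        "age_group": -0.55,
        "simd_quintile": -0.45,
        "ltc_digestive": 0.40,
        "deceased_flag": -0.35,
        "gender_male": 0.30,
        "alcohol_episodes": 0.25,
        "ltc_respiratory": 0.20,
        "self_harm_episodes": 0.20,
        "mh_inpatient_episodes": 0.20,
        "home_care_episodes": -0.20,
        "ltc_cancer": -0.15,
        "ltc_cardiac": -0.15,
        "homeless_flag": 0.10,
        "ltc_diabetes_endocrine": 0.08,
        "ltc_neurological": 0.05,
        "substance_misuse_episodes": 0.0,
        "ltc_arthritis": 0.0,
        "ltc_cerebrovascular": 0.0,
        "ltc_renal": 0.0,
        "ltc_other": 0.0,
    }


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class WithinClassCountParams:
    """Visit-count distributions inside the mid and high attendance classes.

    ``class1_distribution`` is a probability vector over visit counts 5..10;
    ``class2_distribution`` over 11..``max_visits``.
    """

    class1_distribution: np.ndarray
    class2_distribution: np.ndarray
    max_visits: int = 60

    def __post_init__(self):
        self.class1_distribution = np.asarray(self.class1_distribution, dtype=float)
        self.class2_distribution = np.asarray(self.class2_distribution, dtype=float)
        if self.class1_distribution.shape != (6,):
            raise ConfigurationError(
                "class1_distribution must cover visit counts 5..10 (length 6)"
            )
        if self.class2_distribution.shape != (self.max_visits - 10,):
            raise ConfigurationError(
                "class2_distribution must cover visit counts 11..max_visits"
            )
        for name, p in (
            ("class1_distribution", self.class1_distribution),
            ("class2_distribution", self.class2_distribution),
        ):
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ConfigurationError(f"{name} must be a probability vector")

    @property
    def class1_support(self) -> np.ndarray:
        return np.arange(5, 11)

    @property
    def class2_support(self) -> np.ndarray:
        return np.arange(11, self.max_visits + 1)

    def moments(self, class_counts, class0_composition) -> tuple[float, float]:
        """Exact mean and SD of the full visit-count mixture."""
        n0a, n0b = class0_composition
        n1, n2 = class_counts[1], class_counts[2]
        n = n0a + n0b + n1 + n2
        m1c1 = float(self.class1_distribution @ self.class1_support)
        m2c1 = float(self.class1_distribution @ self.class1_support**2)
        m1c2 = float(self.class2_distribution @ self.class2_support)
        m2c2 = float(self.class2_distribution @ self.class2_support**2)
        total = 3 * n0a + 4 * n0b + n1 * m1c1 + n2 * m1c2
        total_sq = 9 * n0a + 16 * n0b + n1 * m2c1 + n2 * m2c2
        mean = total / n
        var = total_sq / n - mean**2
        return mean, float(np.sqrt(max(var, 0.0)))


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator."""

    n_patients: int = 17437
    seed: int = 0
    class_counts: tuple = (13474, 3615, 348)
    class0_composition: tuple = (9730, 3744)
    mean_visits: float = 4.14
    sd_visits: float = 2.81
    max_visits: int = 60
    noise_sd: float = 1.0
    effect_coefficients: dict = field(default_factory=default_effect_coefficients)
    feature_marginals: dict = field(default_factory=default_feature_marginals)
    within_class_count_params: WithinClassCountParams | None = None

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        if len(self.class_counts) != 3 or any(c < 0 for c in self.class_counts):
            raise ConfigurationError("class_counts must be three non-negative counts")
        if sum(self.class_counts) != self.n_patients:
            raise ConfigurationError(
                f"class_counts {self.class_counts} must sum to n_patients "
                f"({self.n_patients})"
            )
        if sum(self.class0_composition) != self.class_counts[0]:
            raise ConfigurationError(
                "class0_composition must sum to class_counts[0]"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        unknown = set(self.effect_coefficients) - set(FEATURE_COLUMNS) - {"total_ltcs"}
        if unknown:
            raise ConfigurationError(f"effect coefficients for unknown features: {sorted(unknown)}")
        missing = set(FEATURE_COLUMNS) - set(self.feature_marginals)
        if missing:
            raise ConfigurationError(f"missing marginals for features: {sorted(missing)}")

    def scaled(self, n_patients: int, seed: int | None = None) -> "GeneratorConfig":
        """Proportionally scaled copy (class counts rounded, sums preserved).

        Used for reduced-size runs; the within-class composition and effect
        structure are unchanged.
        """
        frac = n_patients / self.n_patients
        c1 = int(round(self.class_counts[1] * frac))
        c2 = max(int(round(self.class_counts[2] * frac)), 1)
        c0 = n_patients - c1 - c2
        c0a = int(round(self.class0_composition[0] * frac))
        c0a = min(c0a, c0)
        return dataclasses.replace(
            self,
            n_patients=n_patients,
            seed=self.seed if seed is None else seed,
            class_counts=(c0, c1, c2),
            class0_composition=(c0a, c0 - c0a),
            within_class_count_params=None,
        )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_patients": self.n_patients,
            "seed": self.seed,
            "class_counts": list(self.class_counts),
            "class0_composition": list(self.class0_composition),
            "mean_visits": self.mean_visits,
            "sd_visits": self.sd_visits,
            "max_visits": self.max_visits,
            "noise_sd": self.noise_sd,
            "effect_coefficients": dict(self.effect_coefficients),
            "feature_marginals": {k: list(v) for k, v in self.feature_marginals.items()},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d.pop("within_class_count_params", None)
        if "class_counts" in d:
            d["class_counts"] = tuple(d["class_counts"])
        if "class0_composition" in d:
            d["class0_composition"] = tuple(d["class0_composition"])
        if "feature_marginals" in d:
            d["feature_marginals"] = {
                k: tuple(v) for k, v in d["feature_marginals"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
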