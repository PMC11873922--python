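"""Synthetic cohort generator: calibration, exact counts, planted effects."""


import numpy as np
import pandas as pd
import pytest

from facohort.cohort import (
    CalibrationError,
    CohortValidationError,
    calibrate_count_distributions,
    generate_cohort,
    generate_features,
    assign_classes,
    draw_visit_counts,
    load_cohort,
    validate_cohort,
)
from facohort.config import (
    COHORT_COLUMNS,
    FEATURE_COLUMNS,
    LTC_COLUMNS,
    MIN_RELIABLE_EFFECT,
    ConfigurationError,
    GeneratorConfig,
    default_effect_coefficients,
    default_feature_marginals,
)

DEFAULT_COUNTS = (13474, 3615, 348)
DEFAULT_COMP = (9730, 3744)


class TestCalibration:
    def test_mixture_moments_hit_targets(self):
        params = calibrate_count_distributions(4.14, 2.81, DEFAULT_COUNTS, DEFAULT_COMP)
        mean, sd = params.moments(DEFAULT_COUNTS, DEFAULT_COMP)
        assert mean == pytest.approx(4.14, abs=0.01)
        assert sd == pytest.approx(2.81, abs=0.02)

    def test_upper_class_visit_total_matches_arithmetic_identity(self):
        # classes 1-2 must jointly contribute the visits the fixed class-0
        # composition cannot: 4.14 * 17,437 - (9,730 * 3 + 3,744 * 4)
        params = calibrate_count_distributions(4.14, 2.81, DEFAULT_COUNTS, DEFAULT_COMP)
        expected = 4.14 * 17437 - (9730 * 3 + 3744 * 4)
        got = (
            DEFAULT_COUNTS[1] * float(params.class1_distribution @ params.class1_support)
            + DEFAULT_COUNTS[2] * float(params.class2_distribution @ params.class2_support)
        )
        assert got == pytest.approx(expected, abs=0.5)
        assert expected == pytest.approx(28023, abs=1)

    def test_single_class_forced_count_is_degenerate(self):
        params = calibrate_count_distributions(3.0, 0.0, (100, 0, 0), (100, 0))
        mean, sd = params.moments((100, 0, 0), (100, 0))
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(0.0)

    def test_infeasible_mean_names_the_moment(self):
        with pytest.raises(CalibrationError, match="mean"):
            calibrate_count_distributions(20.0, 2.81, DEFAULT_COUNTS, DEFAULT_COMP)

    def test_infeasible_sd_names_the_moment(self):
        with pytest.raises(CalibrationError, match="sd"):
            calibrate_count_distributions(4.14, 9.0, DEFAULT_COUNTS, DEFAULT_COMP)

    def test_deterministic(self):
        a = calibrate_count_distributions(4.14, 2.81, DEFAULT_COUNTS, DEFAULT_COMP)
        b = calibrate_count_distributions(4.14, 2.81, DEFAULT_COUNTS, DEFAULT_COMP)
        np.testing.assert_array_equal(a.class1_distribution, b.class1_distribution)
        np.testing.assert_array_equal(a.class2_distribution, b.class2_distribution)


class TestGenerateFeatures:
    def test_empty_cohort_keeps_schema(self, rng):
        df = generate_features(0, default_feature_marginals(), rng)
        assert list(df.columns) == FEATURE_COLUMNS + ["total_ltcs"]
        assert len(df) == 0

    def test_degenerate_bernoulli_is_constant(self, rng):
        marginals = default_feature_marginals()
        marginals["homeless_flag"] = ("bernoulli", 1.0)
        df = generate_features(200, marginals, rng)
        assert (df["homeless_flag"] == 1).all()

    def test_total_ltcs_is_flag_sum(self, rng):
        df = generate_features(5000, default_feature_marginals(), rng)
        np.testing.assert_array_equal(
            df["total_ltcs"].to_numpy(), df[LTC_COLUMNS].sum(axis=1).to_numpy()
        )

    def test_invalid_marginal_rejected(self, rng):
        marginals = default_feature_marginals()
        marginals["gender_male"] = ("bernoulli", 1.5)
        with pytest.raises(ConfigurationError):
            generate_features(10, marginals, rng)


class TestAssignClasses:
    def test_exact_label_counts(self, rng):
        df = generate_features(1000, default_feature_marginals(), rng)
        labels = assign_classes(df, default_effect_coefficients(), (800, 150, 50), rng)
        assert [(labels == c).sum() for c in range(3)] == [800, 150, 50]

    def test_zero_coefficients_decouple_labels_from_features(self):
        rng = np.random.default_rng(0)
        df = generate_features(17437, default_feature_marginals(), rng)
        labels = assign_classes(df, {}, (13474, 3615, 348), rng)
        high = (labels == 2).astype(float)
        for col in ("acute_inpatient_episodes", "age_group", "gender_male"):
            r = np.corrcoef(df[col].to_numpy(dtype=float), high)[0, 1]
            assert abs(r) <= 0.03

    def test_planted_acute_effect_orders_class_means(self):
        # positive acute coefficient: class means strictly increase 0 < 1 < 2
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = generate_features(4000, default_feature_marginals(), rng)
            labels = assign_classes(
                df, default_effect_coefficients(), (3200, 650, 150), rng
            )
            means = [
                df["acute_inpatient_episodes"][labels == c].mean() for c in range(3)
            ]
            assert means[0] < means[1] < means[2]

    def test_count_mismatch_rejected(self, rng):
        df = generate_features(10, default_feature_marginals(), rng)
        with pytest.raises(ConfigurationError):
            assign_classes(df, {}, (5, 3, 3), rng)


class TestDrawVisitCounts:
    @pytest.fixture()
    def params(self):
        return calibrate_count_distributions(4.14, 2.81, DEFAULT_COUNTS, DEFAULT_COMP)

    def test_counts_respect_class_boundaries(self, params, rng):
        labels = np.repeat([0, 1, 2], [13474, 3615, 348])
        v = draw_visit_counts(labels, DEFAULT_COMP, params, rng)
        assert set(np.unique(v[labels == 0])) <= {3, 4}
        assert v[labels == 1].min() >= 5 and v[labels == 1].max() <= 10
        assert v[labels == 2].min() >= 11

    def test_class0_composition_exact(self, params, rng):
        labels = np.repeat([0, 1, 2], [13474, 3615, 348])
        v = draw_visit_counts(labels, DEFAULT_COMP, params, rng)
        assert (v == 3).sum() == 9730
        assert (v[labels == 0] == 4).sum() == 3744


class TestGenerateCohort:
    def test_default_cohort_shape_and_counts(self, default_cohort):
        v = default_cohort.visits
        assert len(default_cohort) == 17437
        assert (v > 10).sum() == 348
        assert ((v >= 5) & (v <= 10)).sum() == 3615
        assert (v == 3).sum() == 9730

    def test_binned_class_sizes_exact_for_any_seed(self):
        for seed in (0, 7, 99):
            v = generate_cohort(GeneratorConfig(seed=seed)).visits
            assert (v < 5).sum() == 13474
            assert ((v >= 5) & (v <= 10)).sum() == 3615
            assert (v > 10).sum() == 348

    def test_moment_calibration_across_seeds(self):
        means, sds = [], []
        for seed in range(20):
            v = generate_cohort(GeneratorConfig(seed=seed)).visits
            means.append(v.mean())
            sds.append(v.std(ddof=1))
        assert all(abs(m - 4.14) <= 0.05 for m in means)
        assert all(abs(s - 2.81) <= 0.10 for s in sds)

    def test_determinism_bit_identical(self):
        a = generate_cohort(GeneratorConfig(seed=5)).table
        b = generate_cohort(GeneratorConfig(seed=5)).table
        pd.testing.assert_frame_equal(a, b)

    def test_sign_recovery_of_reliable_effects(self):
        """Every planted effect at or above the reliability floor shows the
        planted sign in the class-2 minus class-0 mean difference in at
        least 19 of 20 seeds."""
        coefs = {
            k: b
            for k, b in default_effect_coefficients().items()
            if abs(b) >= MIN_RELIABLE_EFFECT
        }
        fails = {k: 0 for k in coefs}
        for seed in range(20):
            cohort = generate_cohort(GeneratorConfig(seed=seed))
            v = cohort.visits
            cls = np.where(v < 5, 0, np.where(v <= 10, 1, 2))
            t = cohort.table
            for k, b in coefs.items():
                diff = t[k][cls == 2].mean() - t[k][cls == 0].mean()
                if np.sign(diff) != np.sign(b):
                    fails[k] += 1
        assert all(f <= 1 for f in fails.values()), fails

    def test_scaled_config_preserves_structure(self):
        cfg = GeneratorConfig().scaled(4000, seed=1)
        assert sum(cfg.class_counts) == 4000
        assert sum(cfg.class0_composition) == cfg.class_counts[0]
        v = generate_cohort(cfg).visits
        assert abs(v.mean() - 4.14) < 0.1


class TestCohortIO:
    def test_csv_round_trip_bit_exact(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        small_cohort.to_csv(path)
        loaded = load_cohort(path)
        pd.testing.assert_frame_equal(loaded.table, small_cohort.table)

    def test_validation_rejects_subthreshold_attendance(self, small_cohort, tmp_path):
        bad = small_cohort.table.copy()
        bad.loc[3, "ae_attendances"] = 2
        with pytest.raises(CohortValidationError, match="rows \\[3\\]"):
            validate_cohort(bad)

    def test_missing_total_ltcs_recomputed_with_warning(self, small_cohort):
        table = small_cohort.table.drop(columns=["total_ltcs"])
        with pytest.warns(UserWarning, match="total_ltcs"):
            fixed = validate_cohort(table)
        assert list(fixed.columns) == COHORT_COLUMNS

    def test_ltc_sum_mismatch_rejected(self, small_cohort):
        bad = small_cohort.table.copy()
        bad.loc[0, "total_ltcs"] = bad.loc[0, "total_ltcs"] + 1
        with pytest.raises(CohortValidationError, match="total_ltcs"):
            validate_cohort(bad)


class TestGeneratorConfig:
    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_patients=100, class_counts=(90, 9, 2)).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=42, n_patients=100, class_counts=(80, 15, 5),
                              class0_composition=(60, 20))
        path = tmp_path / "gen.yaml"
        cfg.to_yaml(path)
        loaded = GeneratorConfig.from_yaml(path)
        assert loaded.to_dict() == cfg.to_dict()
        assert loaded.config_hash() == cfg.config_hash()
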