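"""Shapley approximations against the exact oracle, and risk-factor ranking."""

import numpy as np
import pandas as pd
import pytest

from facohort.shapley import (
    cohort_risk_factors,
    exact_shapley,
    permutation_shapley,
    risk_score,
    zero_input_importance,
)


def interaction_toy(x):
    """f(x1, x2) = x1 + 2 x2 + x1 x2."""
    return x[:, 0] + 2 * x[:, 1] + x[:, 0] * x[:, 1]


class TestRiskScore:
    def test_expected_class_endpoints(self):
        class Fixed:
            def __init__(self, proba):
                self.proba = np.asarray(proba)

            def predict_proba(self, x):
                return np.tile(self.proba, (len(x), 1))

        x = np.zeros((2, 3))
        assert risk_score(Fixed([1, 0, 0]), x)[0] == 0.0
        assert risk_score(Fixed([0, 0, 1]), x)[0] == 2.0
        assert risk_score(Fixed([1 / 3, 1 / 3, 1 / 3]), x)[0] == pytest.approx(1.0)
        assert risk_score(Fixed([0.5, 0.25, 0.25]), x)[0] == pytest.approx(0.75)


class TestExactOracle:
    def test_interaction_toy_hand_weighted_sum(self):
        # v(empty)=0, v({1})=1, v({2})=2, v({1,2})=4 -> phi = (1.5, 2.5)
        phi = exact_shapley(interaction_toy, [1.0, 1.0], background=[0.0, 0.0])
        np.testing.assert_allclose(phi, [1.5, 2.5], atol=1e-12)

    def test_efficiency_axiom(self, rng):
        f = lambda x: np.sin(x[:, 0]) + x[:, 1] * x[:, 2] + 0.5 * np.exp(-x[:, 3])
        inst = rng.normal(size=4)
        bg = rng.normal(size=4)
        phi = exact_shapley(f, inst, background=bg)
        total = f(inst[None])[0] - f(bg[None])[0]
        assert phi.sum() == pytest.approx(total, abs=1e-9)

    def test_dummy_axiom(self):
        f = lambda x: x[:, 0] ** 2  # ignores feature 1
        phi = exact_shapley(f, [2.0, 5.0], background=[0.0, 0.0])
        assert phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_axiom(self):
        f = lambda x: x[:, 0] * x[:, 1] + x[:, 0] + x[:, 1]
        phi = exact_shapley(f, [1.3, 1.3], background=[0.2, 0.2])
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_feature_guard(self):
        f = lambda x: x.sum(axis=1)
        with pytest.raises(ValueError, match="guard"):
            exact_shapley(f, np.ones(13))


class TestPermutationEstimator:
    def test_interaction_toy_within_mc_error(self):
        res = permutation_shapley(
            interaction_toy,
            np.array([[1.0, 1.0]]),
            n_permutations=2000,
            seed=1,
            background=[0.0, 0.0],
        )
        exact = np.array([1.5, 2.5])
        assert np.all(np.abs(res.values - exact) <= 3 * res.stderr + 1e-12)

    def test_additive_closed_form_with_marginal_background(self, rng):
        beta = np.array([0.5, -1.0, 2.0])
        f = lambda x: x @ beta
        x = rng.normal(size=(60, 3))
        res = permutation_shapley(f, x, n_permutations=400, seed=2)
        # per row phi_j = beta_j (x_ij - E[x_j]); averaged over the whole
        # cohort the deviations cancel, so the cohort-level phi is 0
        assert np.all(np.abs(res.values) <= 3 * res.stderr + 1e-3)

    def test_additive_per_instance_matches_beta_deviation(self, rng):
        beta = np.array([1.5, -2.0])
        f = lambda x: x @ beta
        x = rng.normal(size=(80, 2))
        inst = x[:1]
        res = permutation_shapley(f, inst, n_permutations=600, seed=3,
                                  background=x.mean(axis=0))
        expected = beta * (inst[0] - x.mean(axis=0))
        assert np.all(np.abs(res.values - expected) <= 3 * res.stderr + 1e-9)

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(size=(20, 3))
        f = lambda x: np.tanh(x).sum(axis=1)
        a = permutation_shapley(f, x, n_permutations=50, seed=9)
        b = permutation_shapley(f, x, n_permutations=50, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestMethodAgreement:
    def test_linear_agreement_with_zero_background(self, rng):
        """Additive score, zero background: occlusion, permutation and the
        exact oracle coincide per feature."""
        beta = np.array([0.3, -0.7, 1.2])
        f = lambda x: x @ beta
        inst = rng.normal(size=(1, 3))
        zero = zero_input_importance(f, inst)
        exact = exact_shapley(f, inst[0], background=np.zeros(3))
        perm = permutation_shapley(f, inst, n_permutations=200, seed=4,
                                   background=np.zeros(3))
        np.testing.assert_allclose(zero.values, exact, atol=1e-9)
        np.testing.assert_allclose(perm.values, exact, atol=1e-9)

    def test_constant_model_all_zero(self, rng):
        f = lambda x: np.full(len(x), 1.7)
        x = rng.normal(size=(30, 4))
        assert np.allclose(zero_input_importance(f, x).values, 0.0, atol=1e-12)
        assert np.allclose(
            permutation_shapley(f, x, n_permutations=20, seed=0).values, 0.0, atol=1e-12
        )
        assert np.allclose(exact_shapley(f, x[0]), 0.0, atol=1e-12)


class TestZeroInput:
    def test_feature_already_zero_gives_zero(self, rng):
        f = lambda x: x.sum(axis=1)
        x = rng.normal(size=(40, 3))
        x[:, 1] = 0.0
        assert zero_input_importance(f, x, feature=1) == pytest.approx(0.0, abs=1e-12)

    def test_ignored_feature_gives_zero(self):
        # the score provably does not depend on feature 1
        f = lambda x: x[:, 0] * 2.0
        x = np.random.default_rng(1).normal(size=(30, 2))
        assert zero_input_importance(f, x, feature=1) == pytest.approx(0.0, abs=1e-9)

    def test_linear_closed_form(self, rng):
        # beta_j = 0.2, cohort mean 1.5 -> importance 0.30
        f = lambda x: 0.2 * x[:, 0]
        x = np.zeros((100, 1))
        x[:, 0] = rng.normal(1.5, 0.5, 100)
        x[:, 0] += 1.5 - x[:, 0].mean()  # pin the cohort mean exactly
        assert zero_input_importance(f, x, feature=0) == pytest.approx(0.30, abs=1e-9)


class TestCohortRiskFactors:
    def test_threshold_excludes_weak_features(self, rng):
        f = lambda x: 0.5 * x[:, 0] + 0.004 * x[:, 1]
        x = pd.DataFrame(
            np.abs(rng.normal(1.0, 0.3, size=(200, 2))), columns=["strong", "weak"]
        )
        labels = np.zeros(200, dtype=int)
        table = cohort_risk_factors(f, x, labels, selector="low_mid")
        assert "strong" in table.entries["feature"].tolist()
        assert "weak" not in table.entries["feature"].tolist()

    def test_all_below_threshold_empty_table(self, rng):
        f = lambda x: np.full(len(x), 0.5)
        x = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        table = cohort_risk_factors(f, x, np.zeros(50, dtype=int), selector="low_mid")
        assert len(table.entries) == 0

    def test_empty_cohort_selection_rejected(self, rng):
        f = lambda x: x[:, 0]
        x = pd.DataFrame(rng.normal(size=(10, 1)), columns=["a"])
        with pytest.raises(ValueError, match="no rows"):
            cohort_risk_factors(f, x, np.zeros(10, dtype=int), selector="high")

    def test_planted_acute_effect_positive_for_every_family(
        self, fitted_suite, small_split
    ):
        """The planted positive acute-episode effect surfaces with phi > 0
        in every model family on the escalation-risk cohort."""
        for family, model in fitted_suite.items():
            table = cohort_risk_factors(
                model,
                small_split["x_test"],
                small_split["y_test"],
                selector="low_mid",
                model_id=family,
            )
            row = table.entries.set_index("feature")
            assert "acute_inpatient_episodes" in row.index, family
            assert row.loc["acute_inpatient_episodes", "value"] > 0, family
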