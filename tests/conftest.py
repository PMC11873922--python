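import numpy as np
import pytest

from facohort.cohort import generate_cohort
from facohort.config import TARGET_COLUMN, GeneratorConfig
from facohort.models import FrequentAttendanceClassifier
from facohort.prep import bin_attendance, split_train_test


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the published scale."""
    return generate_cohort(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def small_cohort():
    """A proportionally scaled cohort for model-fitting tests."""
    return generate_cohort(GeneratorConfig().scaled(2000, seed=11))


@pytest.fixture(scope="session")
def small_split(small_cohort):
    train, test = split_train_test(small_cohort.table, 0.30, seed=0)
    x_train = train.drop(columns=[TARGET_COLUMN])
    v_train = train[TARGET_COLUMN].to_numpy()
    x_test = test.drop(columns=[TARGET_COLUMN])
    v_test = test[TARGET_COLUMN].to_numpy()
    return {
        "x_train": x_train,
        "y_train": bin_attendance(v_train),
        "v_train": v_train,
        "x_test": x_test,
        "y_test": bin_attendance(v_test),
        "v_test": v_test,
    }


@pytest.fixture(scope="session")
def toy_blobs():
    """Well-separated three-class toy for convergence checks."""
    from sklearn.datasets import make_blobs

    x, y = make_blobs(n_samples=300, centers=3, cluster_std=0.8, random_state=0)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return x, y


@pytest.fixture(scope="session")
def fitted_suite(small_split):
    """All five families fitted on the small cohort split."""
    models = {}
    for family in ("lr", "rf", "svm", "knn", "mlp"):
        models[family] = FrequentAttendanceClassifier(
            family=family, random_state=0
        ).fit(
            small_split["x_train"],
            small_split["y_train"],
            visit_counts=small_split["v_train"],
        )
    return models


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
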