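"""The five-classifier suite for attendance-class prediction.

Families and their fixed hyperparameters:

- ``lr``  — multinomial logistic regression, LBFGS, iteration cap 100,000;
- ``rf``  — random forest, 100 trees, Gini impurity splits;
- ``svm`` — RBF-kernel SVC at default cost/width, probabilities via the
  built-in cross-validated Platt calibration (ROC needs scores);
- ``knn`` — k-nearest neighbours, k = 18, Euclidean distance (sklearn breaks
  voting ties by the smallest class index after distance ordering);
- ``mlp`` — :class:`~facohort.mlp.ValueHotFocalMLP`, trained on the
  value-hot focal loss.

:class:`FrequentAttendanceClassifier` wraps a family behind one contract:
it consumes raw feature tables, standardizes internally where the family is
scale-sensitive (all but the random forest), applies inverse-class-frequency
sample weights where the family's objective supports them (LR, RF, SVM), and
exposes calibrated class probabilities p_c(x) over classes {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .mlp import ValueHotFocalMLP
from .prep import compute_sample_weights

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "make_model",
    "FrequentAttendanceClassifier",
    "fit_family",
    "train_mlp",
    "predict_proba",
]

MODEL_FAMILIES = ("lr", "rf", "svm", "knn", "mlp")

#: Families whose objective takes per-sample weights.
_WEIGHTED_FAMILIES = {"lr", "rf", "svm"}
#: Families fitted on standardized features (the forest is scale-invariant).
_SCALED_FAMILIES = {"lr", "svm", "knn", "mlp"}


@dataclass
class ModelSpec:
    """A model family plus any hyperparameter overrides."""

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {MODEL_FAMILIES}"
            )


def make_model(spec: ModelSpec, random_state: int = 0):
    """Build the configured, unfitted estimator for a model spec."""
    hp = dict(spec.hyperparameters)
    if spec.family == "lr":
        return LogisticRegression(
            solver="lbfgs",
            max_iter=hp.pop("max_iterations", 100_000),
            **hp,
        )
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_trees", 100),
            criterion=hp.pop("split_criterion", "gini"),
            random_state=random_state,
            **hp,
        )
    if spec.family == "svm":
        # default cost 1 and kernel width 1 / (n_features * Var(X)); ROC needs
        # scores, so probabilities come from a cross-validated Platt
        # calibration of the decision values
        base = SVC(
            kernel="rbf",
            C=hp.pop("cost", 1.0),
            gamma=hp.pop("kernel_width", "scale"),
            random_state=random_state,
            **hp,
        )
        return CalibratedClassifierCV(base, ensemble=False)
    if spec.family == "knn":
        return KNeighborsClassifier(
            n_neighbors=hp.pop("k", 18),
            metric=hp.pop("metric", "euclidean"),
            **hp,
        )
    if spec.family == "mlp":
        return ValueHotFocalMLP(random_state=random_state, **hp)
    raise ValueError(f"unknown family {spec.family!r}")


class SchemaMismatchError(ValueError):
    """Prediction input columns do not match the training schema."""


class FrequentAttendanceClassifier(BaseEstimator, ClassifierMixin):
    """Family-agnostic attendance-class classifier on raw feature tables.

    Parameters
    ----------
    family : one of ``MODEL_FAMILIES``.
    hyperparameters : dict, optional
        Family-specific overrides passed to :func:`make_model`.
    weighting : {"inverse_class_frequency", None}
        Sample weighting applied where the family objective supports it
        (LR, RF, SVM).  The k-NN vote has no native weighting; the MLP is
        weighted by attendance values through its loss instead.
    random_state : int
        Seed for every stochastic component of the fit.
    """

    def __init__(
        self,
        family: str = "rf",
        hyperparameters: dict | None = None,
        weighting: str | None = "inverse_class_frequency",
        random_state: int = 0,
    ):
        self.family = family
        self.hyperparameters = hyperparameters
        self.weighting = weighting
        self.random_state = random_state

    def fit(self, X, y, visit_counts=None):
        """Fit on a raw feature table (DataFrame or array) and class labels.

        ``visit_counts`` feeds the MLP's value-hot loss; other families
        ignore it.
        """
        x, self.feature_names_in_ = self._coerce(X, fitting=True)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        spec = ModelSpec(self.family, self.hyperparameters or {})
        self.estimator_ = make_model(spec, self.random_state)

        if self.family in _SCALED_FAMILIES:
            self.scaler_ = StandardScaler().fit(x)
            self.scaler_.scale_[self.scaler_.var_ == 0] = 1.0
            x = self.scaler_.transform(x)
        else:
            self.scaler_ = None

        fit_kwargs = {}
        if self.weighting == "inverse_class_frequency" and self.family in _WEIGHTED_FAMILIES:
            fit_kwargs["sample_weight"] = compute_sample_weights(
                labels=y, strategy="inverse_class_frequency"
            ).weights
        elif self.weighting not in (None, "inverse_class_frequency"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.family == "mlp":
            fit_kwargs["sample_values"] = visit_counts

        self.estimator_.fit(x, y, **fit_kwargs)
        self.classes_ = self.estimator_.classes_
        return self

    def _coerce(self, X, fitting=False):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            if not fitting:
                known = getattr(self, "feature_names_in_", None)
                if known is not None and names != known:
                    missing = sorted(set(known) - set(names))
                    extra = sorted(set(names) - set(known))
                    if missing or extra:
                        raise SchemaMismatchError(
                            f"feature mismatch: missing {missing}, unexpected {extra}"
                        )
                    X = X[known]  # reorder
                    names = known
            return X.to_numpy(dtype=float), names
        x = np.asarray(X, dtype=float)
        known = getattr(self, "feature_names_in_", None)
        if not fitting and known is not None and x.shape[1] != len(known):
            raise SchemaMismatchError(
                f"expected {len(known)} feature columns, got {x.shape[1]}"
            )
        return x, None

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability matrix; rows are non-negative and sum to 1."""
        check_is_fitted(self, "estimator_")
        x, _ = self._coerce(X)
        if self.scaler_ is not None:
            x = self.scaler_.transform(x)
        return self.estimator_.predict_proba(x)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# -- thin functional layer ---------------------------------------------------

def fit_family(
    family: str,
    X,
    y,
    visit_counts=None,
    hyperparameters: dict | None = None,
    random_state: int = 0,
) -> FrequentAttendanceClassifier:
    """Fit one family with the study's weighting conventions."""
    model = FrequentAttendanceClassifier(
        family=family, hyperparameters=hyperparameters, random_state=random_state
    )
    return model.fit(X, y, visit_counts=visit_counts)


def train_mlp(X, y, visit_counts, hyperparameters=None, random_state=0):
    """Train the value-hot focal MLP on a raw feature table."""
    return fit_family(
        "mlp", X, y, visit_counts=visit_counts,
        hyperparameters=hyperparameters, random_state=random_state,
    )


def predict_proba(model: FrequentAttendanceClassifier, X) -> np.ndarray:
    return model.predict_proba(X)
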