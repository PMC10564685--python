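"""The six regression learner families behind one fit/predict contract.

All six minimise (or greedily reduce) squared error on continuous targets
and are backed by scikit-learn with its default hyperparameters unless
overridden: ordinary least squares, k-nearest neighbours (k=5, Euclidean),
support vector regression (RBF kernel), CART decision tree, random forest
(100 trees) and gradient boosted trees.  Stochastic learners receive an
explicit ``random_state`` so repeated fits are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ALGORITHMS",
    "DISPLAY_NAMES",
    "LearnerSpec",
    "make_estimator",
    "fit",
    "predict",
    "mse",
]

#: Canonical algorithm identifiers, in reporting order.
ALGORITHMS: tuple[str, ...] = (
    "linear_regression",
    "knn",
    "svm",
    "decision_tree",
    "random_forest",
    "gradient_boosting",
)

#: Column headers used in rendered importance tables.
DISPLAY_NAMES: dict[str, str] = {
    "linear_regression": "Regression",
    "knn": "KNN",
    "svm": "SVM",
    "decision_tree": "Decision tree",
    "random_forest": "Random forest",
    "gradient_boosting": "Gradient boost",
}

_FACTORIES = {
    "linear_regression": (LinearRegression, False),
    "knn": (KNeighborsRegressor, False),
    "svm": (SVR, False),
    "decision_tree": (DecisionTreeRegressor, True),
    "random_forest": (RandomForestRegressor, True),
    "gradient_boosting": (GradientBoostingRegressor, True),
}


@dataclass(frozen=True)
class LearnerSpec:
    """One learner family plus hyperparameter overrides.

    Unspecified hyperparameters take the backing implementation's
    documented defaults.
    """

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm not in _FACTORIES:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )

    @property
    def display_name(self) -> str:
        return DISPLAY_NAMES[self.algorithm]


def _as_spec(spec: "LearnerSpec | str") -> LearnerSpec:
    return spec if isinstance(spec, LearnerSpec) else LearnerSpec(str(spec))


def make_estimator(spec: LearnerSpec | str, seed: int | None = None,
                   standardize: bool = False) -> RegressorMixin:
    """Build an unfitted scikit-learn regressor for ``spec``.

    ``seed`` is passed as ``random_state`` to the stochastic learners
    (tree, forest, boosting).  With ``standardize`` the regressor is
    wrapped in a pipeline whose scaler is fitted on the training data only,
    so cross-validation remains leakage-free.
    """
    spec = _as_spec(spec)
    cls, stochastic = _FACTORIES[spec.algorithm]
    params = dict(spec.hyperparameters)
    if stochastic and "random_state" not in params:
        params["random_state"] = seed
    est = cls(**params)
    if standardize:
        est = Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def fit(spec: LearnerSpec | str, X_trn, y_trn, seed: int | None = None,
        standardize: bool = False) -> RegressorMixin:
    """Fit one learner, surfacing failures with the learner's name."""
    X = np.asarray(X_trn, dtype=float)
    y = np.asarray(y_trn, dtype=float)
    if X.ndim != 2:
        raise ValueError("X_trn must be 2-dimensional")
    if len(X) != len(y):
        raise ValueError(f"X_trn has {len(X)} rows but y_trn has {len(y)}")
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    est = make_estimator(spec, seed=seed, standardize=standardize)
    try:
        est.fit(X, y)
    except Exception as exc:  # re-raise with context; callers report fold/repeat
        raise RuntimeError(f"fitting {_as_spec(spec).algorithm} failed: {exc}") from exc
    return est


def predict(model: RegressorMixin, X) -> np.ndarray:
    """Predict one value per row; the input is not mutated."""
    X = np.asarray(X, dtype=float)
    n_expected = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != n_expected:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {n_expected}")
    return np.asarray(model.predict(X), dtype=float)


def mse(y_true, y_pred) -> float:
    """Mean squared error between two equal-length vectors."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("mse requires at least one observation")
    return float(mean_squared_error(y_true, y_pred))
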