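"""Repeated cross-validated aggregation of permutation importances.

The procedure, for one continuous outcome:

1. Build a split plan of ``n_reps`` independent shuffles of the rows, each
   cut into ``k_folds`` near-equal folds (``n_reps * k_folds`` train/test
   iterations in total; 10 x 10 = 100 by default).
2. For each learner family and each iteration k: fit the learner on the
   training rows, compute signed held-out permutation importance on the
   test fold, take absolute values (so opposite-signed runs cannot cancel)
   and normalise to unit sum within the run.
3. Average the normalised vectors over all iterations, giving one
   unit-sum importance column per learner, and add an ``Average`` column
   (row-wise mean over learners) which is unit-sum as well.

The result has the shape of a per-outcome importance table: 17 predictors
by six learner columns plus Average, every column summing to one.

``CVPermutationImportance`` is the scikit-learn style front end;
``run_repeated_cv_importance`` and the other module functions are thin wrappers kept
for scripted use.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._seeding import (
    STREAM_LEARNER,
    STREAM_PERMUTE,
    STREAM_SPLIT,
    child_int_seed,
    child_rng,
    child_sequence,
)
from .importance import RunImportance, permutation_importance
from .learners import ALGORITHMS, LearnerSpec, _as_spec, fit as fit_learner

logger = logging.getLogger(__name__)

__all__ = [
    "CVPermutationImportance",
    "make_split_plan",
    "abs_normalize",
    "run_repeated_cv_importance",
    "top_k",
    "aggregate_across_outcomes",
]


def make_split_plan(n: int, k_folds: int = 10, n_reps: int = 10,
                    seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Ordered (train, test) index pairs for ``n_reps`` repetitions of k-fold CV.

    Each repetition shuffles 0..n-1 independently and cuts the shuffled
    order into ``k_folds`` contiguous folds; the first ``n mod k_folds``
    folds receive one extra row, so fold sizes differ by at most one and
    the test folds of a repetition partition the rows exactly.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    if n < k_folds:
        raise ValueError(f"cannot split {n} rows into {k_folds} folds")
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    plan = []
    for rep in range(n_reps):
        order = child_rng(seed, STREAM_SPLIT, rep).permutation(n)
        folds = np.array_split(order, k_folds)
        for test in folds:
            train = np.setdiff1d(order, test)
            plan.append((np.sort(train), np.sort(test)))
    return plan


def abs_normalize(sig: RunImportance | Sequence[float]) -> np.ndarray:
    """Absolute values scaled to unit sum.

    If every entry is zero (e.g. a constant-prediction fit on a degenerate
    fold) the uniform vector 1/p is returned and a warning is logged, so a
    single degenerate fold cannot abort a long run.
    """
    values = sig.values if isinstance(sig, RunImportance) else np.asarray(sig, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty vector")
    absolute = np.abs(values)
    total = absolute.sum()
    if total == 0.0:
        logger.warning("all-zero importance vector; falling back to uniform 1/%d", values.size)
        return np.full(values.size, 1.0 / values.size)
    return absolute / total


class CVPermutationImportance(BaseEstimator):
    """Model-agnostic feature ranking via repeated-CV permutation importance.

    Fits each configured learner family on every train split of a repeated
    k-fold plan, measures signed permutation importance on the matching
    held-out fold, abs-normalises within each run and averages across all
    runs.  Learner families share one split plan and one set of permutation
    streams, so their columns are directly comparable.

    Parameters
    ----------
    learners : sequence of str or LearnerSpec, default all six families
        Learner families to aggregate (``linear_regression``, ``knn``,
        ``svm``, ``decision_tree``, ``random_forest``,
        ``gradient_boosting``).
    k_folds, n_reps : int, default 10 and 10
        Cross-validation geometry; ``n_reps * k_folds`` iterations.
    n_perm_repeats : int, default 10
        Shuffles per predictor per iteration.
    standardize : bool, default False
        Standardise features inside each training fold before fitting.
    random_state : int, default 0
        Master seed; fold shuffles, permutation shuffles and stochastic
        learners each draw from derived substreams.

    Attributes
    ----------
    importance_table_ : pandas.DataFrame
        Predictors x learner display names plus ``Average``; every column
        sums to one.
    feature_importances_ : ndarray
        The ``Average`` column.
    feature_names_in_, n_features_in_ : fitted input description.
    n_uniform_fallbacks_ : int
        Number of all-zero importance runs replaced by the uniform vector.
    """

    def __init__(self, learners: Sequence[LearnerSpec | str] | None = None,
                 k_folds: int = 10, n_reps: int = 10, n_perm_repeats: int = 10,
                 standardize: bool = False, random_state: int = 0):
        self.learners = learners
        self.k_folds = k_folds
        self.n_reps = n_reps
        self.n_perm_repeats = n_perm_repeats
        self.standardize = standardize
        self.random_state = random_state

    def _learner_specs(self) -> list[LearnerSpec]:
        names = ALGORITHMS if self.learners is None else self.learners
        specs = [_as_spec(s) for s in names]
        if not specs:
            raise ValueError("need at least one learner")
        return specs

    def fit(self, X, y):
        """Run the full aggregation on predictors ``X`` and outcome ``y``."""
        if isinstance(X, pd.DataFrame):
            feature_names = np.asarray(X.columns, dtype=object)
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.asarray(X, dtype=float)
            feature_names = np.asarray([f"x{i}" for i in range(X_arr.shape[1])], dtype=object)
        y_arr = np.asarray(y, dtype=float)
        if X_arr.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(X_arr) != len(y_arr):
            raise ValueError(f"X has {len(X_arr)} rows but y has {len(y_arr)}")
        if np.isnan(X_arr).any() or np.isnan(y_arr).any():
            raise ValueError("missing values are not supported")

        specs = self._learner_specs()
        seed = int(self.random_state)
        plan = make_split_plan(len(X_arr), self.k_folds, self.n_reps, seed=seed)
        n_features = X_arr.shape[1]

        self.n_uniform_fallbacks_ = 0
        columns: dict[str, np.ndarray] = {}
        for spec in specs:
            # Learner streams are keyed by algorithm identity (not list
            # position), so reordering the learners cannot change any column.
            alg_id = ALGORITHMS.index(spec.algorithm)
            acc = np.zeros(n_features)
            for k, (trn, tst) in enumerate(plan):
                try:
                    model = fit_learner(
                        spec, X_arr[trn], y_arr[trn],
                        seed=child_int_seed(seed, STREAM_LEARNER, alg_id, k),
                        standardize=self.standardize,
                    )
                except Exception as exc:
                    rep, fold = divmod(k, self.k_folds)
                    raise RuntimeError(
                        f"learner {spec.algorithm!r} failed at repetition {rep + 1}, "
                        f"fold {fold + 1}: {exc}"
                    ) from exc
                run = permutation_importance(
                    model, X_arr[tst], y_arr[tst],
                    n_repeats=self.n_perm_repeats,
                    random_state=child_sequence(seed, STREAM_PERMUTE, k),
                )
                if np.all(run.values == 0.0):
                    self.n_uniform_fallbacks_ += 1
                acc += abs_normalize(run)
            columns[spec.display_name] = acc / len(plan)

        table = pd.DataFrame(columns, index=pd.Index(feature_names, name="predictor"))
        table["Average"] = table.mean(axis=1)
        self.feature_names_in_ = feature_names
        self.n_features_in_ = n_features
        self.importance_table_ = table
        self.feature_importances_ = table["Average"].to_numpy()
        return self

    def top_k(self, k: int = 5, column: str = "Average") -> list[str]:
        """The k most important predictors in one table column."""
        check_is_fitted(self, "importance_table_")
        return top_k(self.importance_table_, column=column, k=k)


def run_repeated_cv_importance(X, y, learner_specs: Sequence[LearnerSpec | str] | None = None,
                   k_folds: int = 10, n_reps: int = 10, n_perm_repeats: int = 10,
                   seed: int = 0, standardize: bool = False) -> pd.DataFrame:
    """Functional front end returning the importance table directly."""
    est = CVPermutationImportance(
        learners=learner_specs, k_folds=k_folds, n_reps=n_reps,
        n_perm_repeats=n_perm_repeats, standardize=standardize, random_state=seed,
    )
    est.fit(X, y)
    table = est.importance_table_
    table.attrs["n_uniform_fallbacks"] = est.n_uniform_fallbacks_
    outcome = getattr(y, "name", None)
    if outcome:
        table.attrs["outcome"] = str(outcome)
    return table


def top_k(table: pd.DataFrame, column: str = "Average", k: int = 5) -> list[str]:
    """The k predictors with the largest importance in ``column``.

    Ties are broken by table (questionnaire) order, so the result is stable.
    """
    if column not in table.columns:
        raise KeyError(f"no column {column!r} in importance table")
    if k > len(table):
        raise ValueError(f"k={k} exceeds predictor count {len(table)}")
    values = table[column].to_numpy()
    order = np.argsort(-values, kind="stable")
    return [str(table.index[i]) for i in order[:k]]


def aggregate_across_outcomes(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Stack the Average columns of several outcome tables.

    Returns a predictors x outcomes matrix plus an ``Accumulated`` column
    (the row sum), the data behind a stacked-bar summary of overall factor
    significance; the grand total equals the number of outcomes because
    each Average column is unit-sum.
    """
    if not tables:
        raise ValueError("need at least one importance table")
    index = tables[0].index
    out = {}
    for pos, table in enumerate(tables):
        if not index.equals(table.index):
            raise ValueError("importance tables disagree on the predictor set")
        label = table.attrs.get("outcome", f"outcome_{pos + 1}")
        out[label] = table["Average"].to_numpy()
    summary = pd.DataFrame(out, index=index)
    summary["Accumulated"] = summary.sum(axis=1)
    return summary
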