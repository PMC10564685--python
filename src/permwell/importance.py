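"""Held-out permutation feature importance.

The importance of predictor i for a fitted model is the average increase in
held-out mean squared error when column i of the test fold is randomly
shuffled while the target and every other column stay in place.  Shuffling
breaks the predictor-target link but preserves the column's marginal
distribution, so the MSE increase measures how much the model's predictions
rely on that predictor.  The signed difference is kept: a negative value
means shuffling happened to improve the held-out fit.

This is the quantity the repeated-cross-validation pipeline aggregates; it
is computed natively here (not delegated) because the sign convention,
seeding scheme and within-fold shuffling are part of the method's contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeding import child_sequence
from .learners import mse, predict

__all__ = ["RunImportance", "shuffle_column", "permutation_importance"]


@dataclass(frozen=True)
class RunImportance:
    """Signed per-predictor importances from one train/test iteration."""

    values: np.ndarray
    baseline_mse: float
    n_repeats: int

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.baseline_mse < 0:
            raise ValueError("baseline_mse must be nonnegative")


def _column_view(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float, copy=False)
    return np.asarray(X, dtype=float)


def shuffle_column(X, i: int, rng: np.random.Generator | int | None = None):
    """Copy of ``X`` with column ``i`` uniformly permuted, all else identical.

    Accepts an array or DataFrame and returns the same type; the input is
    never mutated.
    """
    arr = _column_view(X)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if not 0 <= i < arr.shape[1]:
        raise IndexError(f"column index {i} out of range for {arr.shape[1]} columns")
    rng = np.random.default_rng(rng)
    out = arr.copy()
    out[:, i] = out[rng.permutation(arr.shape[0]), i]
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


def permutation_importance(model, X_tst, y_tst, n_repeats: int = 10,
                           random_state: int | np.random.SeedSequence | None = 0,
                           debug_stream=None) -> RunImportance:
    """Permutation importance of every predictor on one held-out fold.

    For each predictor i, importance_i is the mean over ``n_repeats``
    independent shuffles of ``mse(y_tst, model.predict(X_shuffled_i)) -
    baseline_mse`` where the baseline is the model's MSE on the unshuffled
    fold.  Shuffling happens within the test fold only.

    Randomness is drawn from one substream per predictor, derived from
    ``random_state`` (an int master seed or a ``numpy.random.SeedSequence``)
    with spawn key ``(i,)``; repeats consume that substream sequentially.
    Streams for different predictors are therefore independent and the
    result is reproducible from the master seed alone.

    ``debug_stream`` (a writable text stream, e.g. ``sys.stderr``) dumps the
    per-repeat permuted MSEs as TSV rows ``feature <tab> repeat <tab> mse``.
    """
    X = _column_view(X_tst)
    y = np.asarray(y_tst, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("test set must be a non-empty 2-d matrix")
    if len(X) != len(y):
        raise ValueError(f"X_tst has {len(X)} rows but y_tst has {len(y)}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be positive")

    if isinstance(random_state, np.random.SeedSequence):
        feature_seq = lambda i: np.random.SeedSequence(
            entropy=random_state.entropy,
            spawn_key=tuple(random_state.spawn_key) + (i,),
        )
    else:
        master = 0 if random_state is None else int(random_state)
        feature_seq = lambda i: child_sequence(master, i)

    n, p = X.shape
    baseline = mse(y, predict(model, X))
    values = np.empty(p)
    for i in range(p):
        rng = np.random.default_rng(feature_seq(i))
        # All repeats for one feature are stacked into a single predict
        # call; per-repeat MSEs are recovered by reshaping.
        stacked = np.tile(X, (n_repeats, 1))
        for r in range(n_repeats):
            stacked[r * n:(r + 1) * n, i] = X[rng.permutation(n), i]
        preds = predict(model, stacked).reshape(n_repeats, n)
        fold_mses = np.mean((preds - y) ** 2, axis=1)
        if debug_stream is not None:
            for r, m in enumerate(fold_mses):
                print(f"{i}\t{r}\t{m:.17g}", file=debug_stream)
        values[i] = float(np.mean(fold_mses - baseline))
    return RunImportance(values=values, baseline_mse=baseline, n_repeats=n_repeats)
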