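"""The conventional two-step questionnaire analysis used for comparison.

Step 1 screens each dichotomised predictor with a two-sample T-test of the
outcome between its two groups (Welch's unequal-variance variant by
default, two-sided, no multiplicity correction).  Step 2 regresses the
outcome on the predictors that passed the screen with ordinary least
squares and ranks them by absolute standardized coefficient.  The screen
can discard predictors that only matter jointly, which is exactly the
weakness the permutation-importance pipeline avoids; ``topk_overlap``
quantifies how much the two methods agree.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_is_fitted

__all__ = ["TwoStepBaseline", "ttest_screen", "regression_rank", "topk_overlap"]


def _frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def ttest_screen(X, y, alpha: float = 0.05, equal_var: bool = False) -> pd.DataFrame:
    """Per-predictor two-sided two-sample T-test of ``y`` between groups.

    Each screened column must be binary.  Columns where one group is empty
    cannot be screened; they are flagged ``screenable=False`` (t and p are
    NaN, never selected) with a warning rather than aborting the screen.

    Returns a DataFrame indexed by predictor with columns ``t``, ``p``,
    ``selected`` (p < alpha) and ``screenable``.
    """
    Xf = _frame(X)
    y = np.asarray(y, dtype=float)
    if len(Xf) != len(y):
        raise ValueError(f"X has {len(Xf)} rows but y has {len(y)}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for name in Xf.columns:
        col = Xf[name].to_numpy(dtype=float)
        levels = np.unique(col)
        if not set(levels).issubset({0.0, 1.0}):
            raise ValueError(f"column {name!r} is not binary 0/1")
        if len(levels) < 2:
            warnings.warn(f"column {name!r} has a single group; excluded from screen")
            rows.append((name, np.nan, np.nan, False, False))
            continue
        t, p = stats.ttest_ind(y[col == 1], y[col == 0], equal_var=equal_var)
        rows.append((name, float(t), float(p), bool(p < alpha), True))
    return pd.DataFrame(
        rows, columns=["predictor", "t", "p", "selected", "screenable"]
    ).set_index("predictor")


def regression_rank(X_selected, y, standardize: bool = True) -> pd.DataFrame:
    """OLS of ``y`` on the selected predictors, ranked by coefficient size.

    With ``standardize`` (default) ranking uses standardized coefficients
    (raw coefficient times predictor SD over outcome SD) so predictors on
    different codings are comparable.  A rank-deficient design aborts with
    the names of the collinear columns.

    Returns a DataFrame indexed by predictor with columns ``coefficient``,
    ``std_coefficient`` and ``rank`` (1 = largest), sorted by rank.
    """
    Xf = _frame(X_selected)
    y = np.asarray(y, dtype=float)
    if Xf.shape[1] < 1:
        raise ValueError("need at least one selected predictor")
    if len(Xf) != len(y):
        raise ValueError(f"X has {len(Xf)} rows but y has {len(y)}")
    arr = Xf.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(arr)), arr])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        culprits = _collinear_columns(Xf)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {culprits}"
        )
    ols = LinearRegression().fit(arr, y)
    coef = np.asarray(ols.coef_, dtype=float)
    y_sd = y.std(ddof=0)
    if y_sd == 0:
        std_coef = np.zeros_like(coef)
    else:
        std_coef = coef * arr.std(axis=0, ddof=0) / y_sd
    key = np.abs(std_coef) if standardize else np.abs(coef)
    order = np.argsort(-key, kind="stable")
    ranks = np.empty(len(coef), dtype=int)
    ranks[order] = np.arange(1, len(coef) + 1)
    out = pd.DataFrame(
        {"coefficient": coef, "std_coefficient": std_coef, "rank": ranks},
        index=Xf.columns.rename("predictor"),
    )
    return out.sort_values("rank")


def _collinear_columns(Xf: pd.DataFrame) -> list[str]:
    """Columns that add no rank to the design built from their predecessors."""
    n = len(Xf)
    basis = np.ones((n, 1))
    culprits = []
    for name in Xf.columns:
        candidate = np.column_stack([basis, Xf[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(candidate) == basis.shape[1]:
            culprits.append(str(name))
        else:
            basis = candidate
    return culprits


def topk_overlap(a: Sequence[str], b: Sequence[str]) -> int:
    """Size of the intersection of two predictor sets."""
    return len(set(a) & set(b))


class TwoStepBaseline(BaseEstimator):
    """T-test screening followed by OLS coefficient ranking.

    Parameters
    ----------
    alpha : float, default 0.05
        Screening significance level (uncorrected).
    equal_var : bool, default False
        Use Student's pooled-variance test instead of Welch's.
    standardize : bool, default True
        Rank survivors by standardized rather than raw coefficients.

    Attributes
    ----------
    screen_ : DataFrame with t, p, selected, screenable per predictor.
    ranking_ : DataFrame of the selected predictors with coefficients and
        ranks (empty if nothing passed the screen).
    selected_ : list of predictor names that passed the screen.
    """

    def __init__(self, alpha: float = 0.05, equal_var: bool = False,
                 standardize: bool = True):
        self.alpha = alpha
        self.equal_var = equal_var
        self.standardize = standardize

    def fit(self, X, y):
        Xf = _frame(X)
        self.screen_ = ttest_screen(Xf, y, alpha=self.alpha, equal_var=self.equal_var)
        self.selected_ = [str(n) for n in self.screen_.index[self.screen_["selected"]]]
        if self.selected_:
            self.ranking_ = regression_rank(Xf[self.selected_], y,
                                            standardize=self.standardize)
        else:
            self.ranking_ = pd.DataFrame(
                columns=["coefficient", "std_coefficient", "rank"],
                index=pd.Index([], name="predictor"),
            )
        self.n_features_in_ = Xf.shape[1]
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        return self

    def top_k(self, k: int = 5) -> list[str]:
        """The k best-ranked survivors (fewer if the screen kept fewer)."""
        check_is_fitted(self, "ranking_")
        return [str(n) for n in self.ranking_.index[:k]]
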