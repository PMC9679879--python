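"""Ensemble score combination, optionally augmented with the reader's call.

Each AI model emits one confidence score in [0, 1] per breast side; the
examination-level score of a model is the maximum over its sides (the most
suspicious finding drives recall).  The combiner is a weighted
maximum-likelihood logistic stacker over the per-model examination scores —
a transparent convex surrogate with the same input/output contract as
published challenge-ensemble combiners, whose fitted coefficients are not
public.  The reader-augmented variant adds the binarized BI-RADS call
(positive = {0, 3, 4, 5}) as one more input.

`LogisticScoreCombiner` is a scikit-learn-compatible estimator; the
module-level :func:`fit_combiner` / :func:`apply_combiner` helpers wrap it
with named model columns for pipeline use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .cohort import screen_positive


class LogisticScoreCombiner(BaseEstimator, ClassifierMixin):
    """Weighted maximum-likelihood logistic combination of model scores.

    The fit is unpenalized (the convex MLE is deterministic given the
    data).  If the optimizer fails to converge or the coefficients blow up
    — the signature of (quasi-)separation — the fit falls back to a small
    ridge penalty and flags it.

    Parameters
    ----------
    ridge_on_separation : float
        L2 penalty strength used by the fallback fit (default 1e-4).
    tol, max_iter : float, int
        Solver controls passed to the underlying optimizer.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Fitted input weights.
    intercept_ : float
    ridge_used_ : bool
        True when the separation fallback was taken.
    """

    def __init__(self, ridge_on_separation: float = 1e-4, tol: float = 1e-10,
                 max_iter: int = 5000):
        self.ridge_on_separation = ridge_on_separation
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"both outcome classes must be present; got classes {classes}"
            )
        base = dict(tol=self.tol, max_iter=self.max_iter, solver="lbfgs")
        lr = LogisticRegression(C=np.inf, **base)  # unpenalized MLE
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lr.fit(X, y, sample_weight=sample_weight)
        margin = X @ lr.coef_.ravel() + lr.intercept_[0]
        perfectly_split = np.all((margin > 0) == (y == lr.classes_[1])) and np.min(
            np.abs(margin)
        ) > 10.0
        separated = (
            lr.n_iter_[0] >= self.max_iter
            or np.max(np.abs(lr.coef_)) > 30.0
            or perfectly_split
        )
        if separated:
            lr = LogisticRegression(C=1.0 / self.ridge_on_separation, **base)
            lr.fit(X, y, sample_weight=sample_weight)
        self.ridge_used_ = bool(separated)
        self.classes_ = lr.classes_
        self.coef_ = lr.coef_.ravel().copy()
        self.intercept_ = float(lr.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


@dataclass(frozen=True)
class Combiner:
    """A fitted combination rule over named model inputs."""

    model_ids: tuple[str, ...]
    coefficients: dict[str, float]  # model id (and "reader") -> weight
    intercept: float
    includes_reader: bool
    ridge_used: bool = False

    @property
    def input_columns(self) -> tuple[str, ...]:
        cols = self.model_ids
        return cols + ("reader",) if self.includes_reader else cols


def aggregate_sides(panel: pd.DataFrame) -> pd.DataFrame:
    """Examination-level score matrix: max over breast sides per model.

    Parameters
    ----------
    panel : DataFrame
        Long score table with columns exam_id, model_id, side, score.

    Returns
    -------
    DataFrame
        Wide matrix indexed by exam_id with one column per model_id.
    """
    required = {"exam_id", "model_id", "side", "score"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"score panel missing columns: {sorted(missing)}")
    if len(panel) == 0:
        raise ValueError("empty score panel")
    wide = panel.pivot_table(
        index="exam_id", columns="model_id", values="score", aggfunc="max"
    )
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"exams with no sides scored for models: {bad}")
    wide.columns.name = None
    return wide


def binarize_reader(birads):
    """Reader input for the augmented combiner: 1 iff the call is positive."""
    pos = screen_positive(birads)
    return int(pos) if np.isscalar(pos) or isinstance(pos, bool) else pos.astype(int)


def fit_combiner(
    features: pd.DataFrame,
    cancer_12mo,
    weight=None,
    *,
    includes_reader: bool = False,
    seed: int | None = None,
) -> Combiner:
    """Fit the logistic stacker on an exam x input score matrix.

    When ``includes_reader`` is True the matrix must carry a ``reader``
    column (the binarized BI-RADS call).  The fit is convex and
    deterministic given the data; ``seed`` is accepted for interface
    symmetry but unused (no subsampling is performed).
    """
    features = pd.DataFrame(features)
    model_ids = tuple(c for c in features.columns if c != "reader")
    if includes_reader and "reader" not in features.columns:
        raise ValueError("includes_reader=True but feature matrix has no 'reader' column")
    cols = list(model_ids) + (["reader"] if includes_reader else [])
    if len(cols) < 1:
        raise ValueError("at least one input column required")
    X = features[cols].to_numpy(dtype=float)
    est = LogisticScoreCombiner().fit(
        X, np.asarray(cancer_12mo, dtype=int), sample_weight=weight
    )
    return Combiner(
        model_ids=model_ids,
        coefficients=dict(zip(cols, est.coef_.tolist())),
        intercept=est.intercept_,
        includes_reader=includes_reader,
        ridge_used=est.ridge_used_,
    )


def apply_combiner(combiner: Combiner, features: pd.DataFrame) -> np.ndarray:
    """Combined score per exam: logistic(intercept + sum coef * input)."""
    features = pd.DataFrame(features)
    for col in combiner.input_columns:
        if col not in features.columns:
            raise ValueError(f"feature matrix missing input column {col!r}")
    eta = np.full(len(features), combiner.intercept, dtype=float)
    for col in combiner.input_columns:
        eta += combiner.coefficients[col] * features[col].to_numpy(dtype=float)
    return expit(eta)


def logit_scores(scores, eps: float = 1e-6) -> np.ndarray:
    """Log-odds transform of probability-scale scores, clipped away from 0/1.

    The stacker is linear in its inputs; feeding it log-odds rather than raw
    probabilities makes the combination a weighted sum on the natural scale
    for probabilistic scores.
    """
    s = np.clip(np.asarray(scores, dtype=float), eps, 1.0 - eps)
    return logit(s)
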