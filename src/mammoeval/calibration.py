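"""Weighted calibration: binned reliability curves and logistic recalibration.

The calibration *slope* is the coefficient of a weighted logistic regression
of the 12-month cancer outcome on the log-odds of the predicted risk; slope
1 means risk differences are expressed on the right scale, slope < 1 means
the scores are too extreme.  The *intercept* is calibration-in-the-large:
a second weighted logistic fit with the score's log-odds entering as a fixed
offset (slope pinned at 1), so intercept 0 means risk is right on average.
Both are 0/1 for a perfectly calibrated model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit


@dataclass(frozen=True)
class CalibrationResult:
    """Logistic recalibration coefficients plus the binned curve."""

    intercept: float
    slope: float
    bins: pd.DataFrame  # bin_mean_pred, bin_obs_rate, bin_weight
    ridge_used: bool = False


def _clip_scores(score, eps: float = 1e-6) -> np.ndarray:
    s = np.asarray(score, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("scores must lie in [0, 1]")
    return np.clip(s, eps, 1.0 - eps)


def _weights(weight, n) -> np.ndarray:
    if weight is None:
        return np.ones(n)
    w = np.asarray(weight, dtype=float)
    if w.shape != (n,):
        raise ValueError("weight length mismatch")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w


def calibration_curve(score, cancer_12mo, weight=None, n_bins: int = 10) -> pd.DataFrame:
    """Reliability curve over weighted-quantile bins of the predicted risk.

    Examinations are sorted by score and split into ``n_bins`` bins of
    (nearly) equal total weight; each bin reports its weighted mean
    prediction, weighted observed cancer rate and total weight.  If all
    scores are identical a single bin is returned with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    s = np.asarray(score, dtype=float)
    y = np.asarray(cancer_12mo, dtype=float)
    w = _weights(weight, s.size)

    if np.all(s == s[0]):
        warnings.warn("all scores identical; returning a single calibration bin")
        bin_ids = np.zeros(s.size, dtype=int)
    else:
        order = np.argsort(s, kind="stable")
        cum_before = np.cumsum(w[order]) - w[order]
        ids_sorted = np.floor(cum_before / w.sum() * n_bins).astype(int)
        ids_sorted = np.clip(ids_sorted, 0, n_bins - 1)
        bin_ids = np.empty(s.size, dtype=int)
        bin_ids[order] = ids_sorted

    rows = []
    for b in np.unique(bin_ids):
        m = bin_ids == b
        wb = w[m].sum()
        rows.append(
            {
                "bin_mean_pred": float(np.average(s[m], weights=w[m])),
                "bin_obs_rate": float(np.average(y[m], weights=w[m])),
                "bin_weight": float(wb),
            }
        )
    return pd.DataFrame(rows)


def _fit_glm(endog, exog, weights, offset=None, ridge: float = 1e-4):
    """Weighted binomial GLM with a ridge-stabilized fallback on separation."""
    model = sm.GLM(
        endog, exog, family=sm.families.Binomial(), freq_weights=weights, offset=offset
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        params = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 30.0:
            return params, False
    except Exception:
        pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_regularized(alpha=ridge, L1_wt=0.0)
    return np.asarray(res.params, dtype=float), True


def calibration_slope_intercept(score, cancer_12mo, weight=None):
    """Calibration intercept and slope of predicted risks.

    Returns a :class:`CalibrationResult` whose ``bins`` frame is the default
    10-bin reliability curve.  Scores of exactly 0 or 1 are clipped to
    [1e-6, 1-1e-6] before the log-odds transform.
    """
    s = _clip_scores(score)
    y = np.asarray(cancer_12mo, dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both outcome classes must be present")
    w = _weights(weight, s.size)
    lo = logit(s)

    slope_params, ridge_a = _fit_glm(y, sm.add_constant(lo), w)
    slope = float(slope_params[1])
    int_params, ridge_b = _fit_glm(y, np.ones((s.size, 1)), w, offset=lo)
    intercept = float(int_params[0])

    bins = calibration_curve(np.asarray(score, dtype=float), y, w)
    return CalibrationResult(
        intercept=intercept, slope=slope, bins=bins, ridge_used=ridge_a or ridge_b
    )
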