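"""Weighted screening-performance metrics, ROC/PR curves and operating points.

All metrics act on weighted pseudo-counts: each examination contributes its
inverse-probability-of-selection weight to the confusion cell it falls in,
so subsample metrics estimate full-cohort performance.  The ROC machinery is
implemented directly (rather than delegated to a library) because weighted
curves, a fixed tie convention and operating-point matching against a human
reader are the substance of the evaluation:

* an exam is model-positive when its score is strictly greater than the
  threshold; ties at the threshold count as negative;
* tied scores are grouped, giving one curve vertex per distinct value, and
  the trapezoidal area then equals the weighted pairwise concordance with
  half-credit for ties;
* operating points are the achievable empirical vertices nearest the
  reader's sensitivity or specificity, with ties broken in favour of the
  better value on the other axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_METRIC_NAMES = ("sensitivity", "specificity", "ppv", "air", "cdr", "fnr")


@dataclass(frozen=True)
class WeightedConfusion:
    """Weighted confusion-cell totals for a screening rule."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"confusion cell {name} is negative")

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Screening metrics derived from a weighted confusion table.

    Metrics whose denominator is zero are NaN and listed in ``undefined``
    rather than silently reported as 0.
    """

    sensitivity: float
    specificity: float
    ppv: float
    air: float
    cdr: float
    fnr: float
    undefined: frozenset = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _METRIC_NAMES}


def _as_weights(weight, n: int) -> np.ndarray:
    if weight is None:
        return np.ones(n)
    w = np.asarray(weight, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weight length {w.shape} does not match {n} examinations")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return w


def weighted_confusion(positive_call, cancer_12mo, weight=None) -> WeightedConfusion:
    """Accumulate weights into TP/FP/FN/TN cells.

    Parameters
    ----------
    positive_call, cancer_12mo : array-like of bool
        The screening rule's call and the 12-month cancer outcome, aligned.
    weight : array-like of positive float, optional
        Inverse-probability weights; defaults to 1 (ordinary counts).
    """
    call = np.asarray(positive_call, dtype=bool)
    cancer = np.asarray(cancer_12mo, dtype=bool)
    if call.shape != cancer.shape:
        raise ValueError(
            f"positive_call and cancer_12mo lengths differ: {call.shape} vs {cancer.shape}"
        )
    w = _as_weights(weight, call.size)
    return WeightedConfusion(
        tp=float(w[call & cancer].sum()),
        fp=float(w[call & ~cancer].sum()),
        fn=float(w[~call & cancer].sum()),
        tn=float(w[~call & ~cancer].sum()),
    )


def _ratio(num: float, den: float, name: str, undefined: set) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def performance_metrics(c: WeightedConfusion) -> PerformanceMetrics:
    """Sensitivity, specificity, PPV, AIR, CDR and FN rate from a table.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); ppv = TP/(TP+FP);
    air = (TP+FP)/N (abnormal interpretation rate); cdr = TP/N (cancer
    detection rate); fnr = FN/N.
    """
    undefined: set = set()
    metrics = PerformanceMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity", undefined),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity", undefined),
        ppv=_ratio(c.tp, c.tp + c.fp, "ppv", undefined),
        air=_ratio(c.tp + c.fp, c.n, "air", undefined),
        cdr=_ratio(c.tp, c.n, "cdr", undefined),
        fnr=_ratio(c.fn, c.n, "fnr", undefined),
        undefined=frozenset(undefined),
    )
    return metrics


@dataclass(frozen=True)
class WeightedROC:
    """Weighted ROC curve over the distinct score values.

    ``thresholds`` are the distinct scores in descending order; the vertex
    at index ``i`` is the operating point calling exams with score >=
    ``thresholds[i]`` positive (equivalently, any cut strictly below that
    value).  A leading +inf threshold anchors the curve at (0, 0); it ends
    at (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _check_two_class(cancer: np.ndarray) -> None:
    if not cancer.any():
        raise ValueError("no cancer-positive examinations in input")
    if cancer.all():
        raise ValueError("no cancer-negative examinations in input")


def _roc_vertices(score, cancer_12mo, weight):
    """Shared sweep: descending distinct scores with cumulative weights."""
    s = np.asarray(score, dtype=float)
    cancer = np.asarray(cancer_12mo, dtype=bool)
    if s.shape != cancer.shape:
        raise ValueError("score and cancer_12mo lengths differ")
    w = _as_weights(weight, s.size)
    _check_two_class(cancer)

    order = np.argsort(-s, kind="stable")
    s, cancer, w = s[order], cancer[order], w[order]
    # one vertex per distinct score value
    last_of_group = np.r_[s[1:] != s[:-1], True]
    cum_pos = np.cumsum(w * cancer)[last_of_group]
    cum_neg = np.cumsum(w * ~cancer)[last_of_group]
    thresholds = s[last_of_group]
    w_pos = float(cum_pos[-1])
    w_neg = float(cum_neg[-1])
    return thresholds, cum_pos / w_pos, cum_neg / w_neg, w_pos, w_neg


def weighted_roc(score, cancer_12mo, weight=None) -> WeightedROC:
    """Weighted ROC curve and trapezoidal AUROC.

    The area equals the weighted probability that a random cancer exam
    outscores a random non-cancer exam, with half credit for ties.
    """
    thresholds, tpr, fpr, _, _ = _roc_vertices(score, cancer_12mo, weight)
    thresholds = np.r_[np.inf, thresholds]
    tpr = np.r_[0.0, tpr]
    fpr = np.r_[0.0, fpr]
    auc = float(np.trapezoid(tpr, fpr))
    return WeightedROC(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


@dataclass(frozen=True)
class WeightedPRCurve:
    """Weighted precision-recall curve with step-interpolated area."""

    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    area: float


def weighted_pr_curve(score, cancer_12mo, weight=None) -> WeightedPRCurve:
    """Weighted precision-recall curve.

    Precision at a vertex is the weighted PPV of calling scores >= the
    threshold positive; the area is the step sum
    sum_i (recall_i - recall_{i-1}) * precision_i (average-precision form).
    """
    thresholds, tpr, fpr, w_pos, w_neg = _roc_vertices(score, cancer_12mo, weight)
    tp = tpr * w_pos
    fp = fpr * w_neg
    precision = tp / (tp + fp)
    recall = tpr
    # stop once full recall is first achieved; later vertices only repeat
    # recall 1 at lower precision
    stop = int(np.argmax(recall >= 1.0)) + 1
    thresholds, recall, precision = thresholds[:stop], recall[:stop], precision[:stop]
    area = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return WeightedPRCurve(
        thresholds=thresholds, recall=recall, precision=precision, area=area
    )


@dataclass(frozen=True)
class OperatingPoint:
    """A threshold matched to a target on one ROC axis."""

    threshold: float
    metrics: PerformanceMetrics
    matched_axis: str
    target: float
    achieved: float
    interpolated: bool = False


def match_operating_point(
    score,
    cancer_12mo,
    weight=None,
    *,
    axis: str,
    target: float,
    interpolate: bool = False,
) -> OperatingPoint:
    """Select the threshold whose sensitivity or specificity is nearest a target.

    Candidate thresholds are +inf (call nothing positive) and every distinct
    score value, under the convention that an exam is positive when its
    score is strictly greater than the threshold, plus -inf (call everything
    positive).  Among candidates equidistant from the target on the matched
    axis, the one with the higher value on the other axis wins.

    With ``interpolate=True`` the sensitivity/specificity pair is linearly
    interpolated between the two bracketing vertices instead (the threshold
    reported is the lower vertex's); secondary metrics are interpolated on
    the confusion-cell scale.
    """
    if axis not in ("sensitivity", "specificity"):
        raise ValueError(f"axis must be 'sensitivity' or 'specificity', got {axis!r}")
    if not (0.0 <= target <= 1.0):
        raise ValueError(f"target must be in [0, 1], got {target}")
    s = np.asarray(score, dtype=float)
    if s.size == 0:
        raise ValueError("empty score input")
    cancer = np.asarray(cancer_12mo, dtype=bool)
    w = _as_weights(weight, s.size)
    _check_two_class(cancer)

    vert_thresh, tpr, fpr, w_pos, w_neg = _roc_vertices(s, cancer, w)
    # positive iff score > t: the vertex at distinct value v is realized by
    # any t in [next lower value, v); report t = the next lower value, with
    # -inf below the minimum.  Leading vertex (nothing positive) is t = max.
    realized_t = np.r_[vert_thresh[1:], -np.inf]
    thresholds = np.r_[vert_thresh[0], realized_t]
    sens = np.r_[0.0, tpr]
    spec = 1.0 - np.r_[0.0, fpr]

    ax = sens if axis == "sensitivity" else spec
    other = spec if axis == "sensitivity" else sens
    dist = np.abs(ax - target)
    best = np.flatnonzero(dist == dist.min())
    i = best[np.argmax(other[best])]

    if interpolate and dist[i] > 0:
        j = i + 1 if (i + 1 < ax.size and (ax[i] - target) * (ax[i + 1] - target) < 0) else i
        if j == i and i > 0 and (ax[i] - target) * (ax[i - 1] - target) < 0:
            i, j = i - 1, i
        if j != i:
            lam = (target - ax[i]) / (ax[j] - ax[i])
            tp = w_pos * (sens[i] + lam * (sens[j] - sens[i]))
            tn = w_neg * (spec[i] + lam * (spec[j] - spec[i]))
            c = WeightedConfusion(tp=tp, fp=w_neg - tn, fn=w_pos - tp, tn=tn)
            m = performance_metrics(c)
            achieved = m.sensitivity if axis == "sensitivity" else m.specificity
            return OperatingPoint(
                threshold=float(thresholds[i]),
                metrics=m,
                matched_axis=axis,
                target=target,
                achieved=float(achieved),
                interpolated=True,
            )

    tp = w_pos * sens[i]
    tn = w_neg * spec[i]
    c = WeightedConfusion(tp=tp, fp=w_neg - tn, fn=w_pos - tp, tn=tn)
    return OperatingPoint(
        threshold=float(thresholds[i]),
        metrics=performance_metrics(c),
        matched_axis=axis,
        target=target,
        achieved=float(ax[i]),
    )
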