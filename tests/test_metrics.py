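"""Weighted confusion metrics, ROC/PR curves and operating-point matching."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from mammoeval import (
    WeightedConfusion,
    match_operating_point,
    performance_metrics,
    weighted_confusion,
    weighted_pr_curve,
    weighted_roc,
)
from tests.conftest import FULL_COUNTS, SUBSET_COUNTS, confusion_from_counts


def brute_force_auc(s, y, w):
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    num = sum(
        w[i] * w[j] * ((s[i] > s[j]) + 0.5 * (s[i] == s[j]))
        for i in pos
        for j in neg
    )
    return num / (w[pos].sum() * w[neg].sum())


class TestWeightedConfusion:
    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(1)
        call = rng.random(50) < 0.4
        cancer = rng.random(50) < 0.3
        w = rng.uniform(0.5, 4.0, 50)
        c = weighted_confusion(call, cancer, w)
        cells = {"tp": 0.0, "fp": 0.0, "fn": 0.0, "tn": 0.0}
        for ci, yi, wi in zip(call, cancer, w):
            key = ("t" if ci == yi else "f") + ("p" if ci else "n")
            cells[key] += wi
        for k, v in cells.items():
            assert getattr(c, k) == pytest.approx(v)

    def test_unit_weights_are_counts(self):
        c = weighted_confusion([True, True, False], [True, False, False])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            weighted_confusion([True], [True, False])


class TestPerformanceMetrics:
    def test_degenerate_two_exam_table(self):
        m = performance_metrics(WeightedConfusion(tp=1, fp=0, fn=0, tn=1))
        assert (m.sensitivity, m.specificity, m.ppv) == (1, 1, 1)
        assert (m.air, m.cdr, m.fnr) == (0.5, 0.5, 0)

    def test_random_cells_against_direct_arithmetic(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tp, fp, fn, tn = rng.uniform(1, 100, 4)
            m = performance_metrics(WeightedConfusion(tp=tp, fp=fp, fn=fn, tn=tn))
            n = tp + fp + fn + tn
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))
            assert m.ppv == pytest.approx(tp / (tp + fp))
            assert m.air == pytest.approx((tp + fp) / n)
            assert m.cdr == pytest.approx(tp / n)
            assert m.fnr == pytest.approx(fn / n)
            assert m.cdr <= m.air and m.cdr <= m.sensitivity

    def test_undefined_metrics_flagged_not_zeroed(self):
        m = performance_metrics(WeightedConfusion(tp=0, fp=2, fn=0, tn=5))
        assert np.isnan(m.sensitivity)
        assert "sensitivity" in m.undefined
        assert m.specificity == pytest.approx(5 / 7)


class TestWeightedROC:
    def test_perfect_separation_and_chance_line(self):
        y = np.array([True, True, False, False])
        assert weighted_roc([0.9, 0.8, 0.2, 0.1], y).auc == pytest.approx(1.0)
        assert weighted_roc([0.5] * 4, y).auc == pytest.approx(0.5)

    def test_single_class_rejected_with_named_class(self):
        with pytest.raises(ValueError, match="cancer-positive"):
            weighted_roc([0.1, 0.2], [False, False])
        with pytest.raises(ValueError, match="cancer-negative"):
            weighted_roc([0.1, 0.2], [True, True])

    def test_equals_pairwise_concordance(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(4, 40))
            s = rng.choice(np.linspace(0, 1, 7), size=n)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            w = rng.uniform(0.2, 5.0, n)
            assert weighted_roc(s, y, w).auc == pytest.approx(
                brute_force_auc(s, y, w), abs=1e-12
            )

    def test_unit_weights_match_reference_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            s = rng.random(n)
            y = rng.random(n) < 0.3
            if y.all() or not y.any():
                continue
            assert weighted_roc(s, y).auc == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )

    def test_invariances(self):
        rng = np.random.default_rng(5)
        s = rng.random(100)
        y = rng.random(100) < 0.3
        w = rng.uniform(0.5, 3.0, 100)
        base = weighted_roc(s, y, w).auc
        assert weighted_roc(s, y, 7.3 * w).auc == pytest.approx(base, abs=1e-12)
        assert weighted_roc(np.exp(3 * s), y, w).auc == pytest.approx(base, abs=1e-12)

    def test_curve_shape(self):
        rng = np.random.default_rng(6)
        roc = weighted_roc(rng.random(50), rng.random(50) < 0.5, rng.uniform(1, 2, 50))
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)


class TestWeightedPR:
    def test_perfect_separation_precision_one(self):
        pr = weighted_pr_curve([0.9, 0.8, 0.2], [True, True, False])
        assert np.all(pr.precision == 1.0)
        assert pr.area == pytest.approx(1.0)

    def test_identical_scores_precision_is_prevalence(self):
        w = np.array([2.0, 1.0, 1.0, 1.0])
        y = np.array([True, False, False, False])
        pr = weighted_pr_curve([0.5] * 4, y, w)
        assert pr.precision[-1] == pytest.approx(2 / 5)

    def test_pointwise_brute_force(self):
        rng = np.random.default_rng(7)
        s = rng.choice([0.1, 0.4, 0.4, 0.8], size=25)
        y = rng.random(25) < 0.4
        w = rng.uniform(0.5, 2.0, 25)
        pr = weighted_pr_curve(s, y, w)
        for t, rec, prec in zip(pr.thresholds, pr.recall, pr.precision):
            called = s >= t
            tp = w[called & y].sum()
            assert prec == pytest.approx(tp / w[called].sum(), abs=1e-12)
            assert rec == pytest.approx(tp / w[y].sum(), abs=1e-12)


class TestOperatingPoint:
    def test_separable_data_full_specificity(self):
        op = match_operating_point(
            [0.9, 0.8, 0.2, 0.1],
            [True, True, False, False],
            axis="specificity",
            target=1.0,
        )
        assert op.metrics.sensitivity == pytest.approx(1.0)
        assert op.achieved == pytest.approx(1.0)

    def test_ties_broken_toward_better_other_axis(self):
        # thresholds achieving specificity 0.5 twice; sensitivities 1.0 and 0.5
        s = np.array([0.9, 0.8, 0.85, 0.1])
        y = np.array([True, True, False, False])
        op = match_operating_point(s, y, axis="specificity", target=0.5)
        assert op.achieved == pytest.approx(0.5)
        assert op.metrics.sensitivity == pytest.approx(1.0)

    @pytest.mark.parametrize("axis", ["specificity", "sensitivity"])
    def test_binormal_closed_form(self, axis):
        """Matched operating points agree with the binormal closed form:
        sens = Phi(sqrt(2) * Phi^-1(AUC) - Phi^-1(spec))."""
        rng = np.random.default_rng(8)
        auc_target = 0.85
        mu = np.sqrt(2) * ndtri(auc_target)
        n_pos, n_neg = 2000, 100_000
        s = np.r_[rng.normal(mu, 1, n_pos), rng.normal(0, 1, n_neg)]
        y = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
        sens_cf = norm.cdf(mu - ndtri(0.930))
        if axis == "specificity":
            op = match_operating_point(s, y, axis=axis, target=0.930)
            assert op.achieved == pytest.approx(0.930, abs=2e-3)
            assert op.metrics.sensitivity == pytest.approx(sens_cf, abs=0.03)
        else:
            op = match_operating_point(s, y, axis=axis, target=sens_cf)
            assert op.achieved == pytest.approx(sens_cf, abs=0.02)
            assert op.metrics.specificity == pytest.approx(0.930, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            match_operating_point([], [], axis="sensitivity", target=0.5)


def test_printed_counts_reproduce_reader_performance():
    call, cancer, w = confusion_from_counts(FULL_COUNTS)
    m = performance_metrics(weighted_confusion(call, cancer, w))
    assert round(m.sensitivity, 3) == 0.826
    assert round(m.specificity, 3) == 0.930


def test_weighted_metrics_scale_free(study_subset_counts, study_full_counts):
    weights = {g: study_full_counts[g] / n for g, n in study_subset_counts.items()}
    call, cancer, w = confusion_from_counts(SUBSET_COUNTS, weights)
    m1 = performance_metrics(weighted_confusion(call, cancer, w))
    m2 = performance_metrics(weighted_confusion(call, cancer, 0.01 * w))
    for name in ("sensitivity", "specificity", "ppv", "air", "cdr", "fnr"):
        assert getattr(m1, name) == pytest.approx(getattr(m2, name), abs=1e-12)
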