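"""Patient-level stratified bootstrap, paired tests and subgroup analysis."""

import numpy as np
import pandas as pd
import pytest

from mammoeval import (
    SimulationConfig,
    SubgroupSpec,
    add_outcome_groups,
    assign_patient_stratum,
    paired_difference_test,
    performance_metrics,
    screen_positive,
    simulate_study,
    stratified_patient_bootstrap,
    subgroup_evaluate,
    weighted_confusion,
)


def weighted_sensitivity(d: pd.DataFrame) -> float:
    m = performance_metrics(
        weighted_confusion(
            screen_positive(d["birads"].to_numpy()),
            d["cancer_12mo"].to_numpy(),
            d["weight"].to_numpy() if "weight" in d.columns else None,
        )
    )
    return m.sensitivity


@pytest.mark.parametrize(
    "groups,expected",
    [
        (["TN"], "TN"),
        (["TN", "FP"], "FP"),
        (["TP", "FN"], "FN"),
        (["TN", "TP", "FP"], "TP"),
    ],
)
def test_patient_stratum_is_most_severe_group(groups, expected):
    assert assign_patient_stratum(groups) == expected


def test_patient_stratum_rejects_bad_input():
    with pytest.raises(ValueError, match="no examinations"):
        assign_patient_stratum([])
    with pytest.raises(ValueError, match="unknown"):
        assign_patient_stratum(["XX"])


def _toy_cohort(seed=0, n_women=400):
    exams, _ = simulate_study(
        SimulationConfig(n_women=n_women, exam_prevalence=0.05), seed
    )
    exams = add_outcome_groups(exams)
    exams["weight"] = 1.0
    return exams


class TestStratifiedBootstrap:
    def test_constant_statistic_zero_width(self):
        exams = _toy_cohort()
        s = stratified_patient_bootstrap(exams, lambda d: 3.14, B=100, seed=0)
        assert s.estimate == 3.14
        assert s.ci_low == s.ci_high == 3.14

    def test_fixed_seed_reproducible(self):
        exams = _toy_cohort()
        a = stratified_patient_bootstrap(exams, weighted_sensitivity, B=150, seed=42)
        b = stratified_patient_bootstrap(exams, weighted_sensitivity, B=150, seed=42)
        assert np.array_equal(a.replicates, b.replicates)

    def test_replicates_preserve_stratum_counts(self):
        """With one exam per woman and unmerged strata, every resample keeps
        the four group sizes exactly."""
        exams = _toy_cohort().drop_duplicates("woman_id").reset_index(drop=True)
        base = exams["group"].value_counts().to_dict()

        def counts(d):
            vc = d["group"].value_counts()
            return {g: float(vc.get(g, 0)) for g in base}

        res = stratified_patient_bootstrap(
            exams, counts, B=100, seed=1, resampling_strata="outcome_group"
        )
        for g, n in base.items():
            assert np.all(res[g].replicates == n)

    def test_cancer_status_strata_preserve_both_totals(self):
        exams = _toy_cohort().drop_duplicates("woman_id").reset_index(drop=True)
        n_cancer = int(exams["group"].isin(["TP", "FN"]).sum())

        def totals(d):
            cancers = d["group"].isin(["TP", "FN"]).sum()
            return {"cancer": float(cancers), "noncancer": float(len(d) - cancers)}

        res = stratified_patient_bootstrap(exams, totals, B=100, seed=1)
        assert np.all(res["cancer"].replicates == n_cancer)
        assert np.all(res["noncancer"].replicates == len(exams) - n_cancer)

    def test_single_exam_women_match_exam_level_bootstrap(self):
        """On a one-exam-per-woman cohort the patient bootstrap reduces to a
        stratified exam-level bootstrap: replicate spread agrees."""
        exams = _toy_cohort(seed=3).drop_duplicates("woman_id").reset_index(drop=True)
        res = stratified_patient_bootstrap(exams, weighted_sensitivity, B=600, seed=7)

        rng = np.random.default_rng(8)
        cancer_rows = np.flatnonzero(exams["group"].isin(["TP", "FN"]))
        noncancer_rows = np.flatnonzero(exams["group"].isin(["FP", "TN"]))
        naive = []
        for _ in range(600):
            idx = np.concatenate(
                [rng.choice(m, size=m.size, replace=True)
                 for m in [cancer_rows, noncancer_rows]]
            )
            naive.append(weighted_sensitivity(exams.iloc[idx]))
        assert np.std(res.replicates) == pytest.approx(np.std(naive), rel=0.2)
        assert np.mean(res.replicates) == pytest.approx(np.mean(naive), abs=0.02)

    def test_too_many_undefined_replicates_is_hard_error(self):
        exams = _toy_cohort()

        def bad(d):
            raise ValueError("undefined")

        with pytest.raises((RuntimeError, ValueError)):
            stratified_patient_bootstrap(exams, bad, B=100, seed=0)


class TestPairedDifference:
    def test_identical_statistics_give_p_one(self):
        r = np.full(500, 0.7)
        assert paired_difference_test(r, r) == 1.0

    def test_floor_when_all_differences_positive(self):
        a = np.linspace(0.6, 0.9, 499)
        b = a - 0.1
        assert paired_difference_test(a, b) == pytest.approx(2 / 500)

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(30)
        a = rng.normal(0.1, 1, 301)
        b = rng.normal(0.0, 1, 301)
        assert paired_difference_test(a, b) == pytest.approx(
            paired_difference_test(b, a)
        )

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            paired_difference_test(np.ones(10), np.ones(11))


class TestSubgroups:
    def test_whole_cohort_single_level_reproduces_unstratified(self):
        exams = _toy_cohort(seed=5)
        exams["all"] = "everyone"
        table = subgroup_evaluate(
            exams,
            SubgroupSpec(variable="all"),
            {"sens": weighted_sensitivity},
            B=100,
            seed=9,
        )
        assert len(table) == 1
        assert table.loc[0, "estimate"] == pytest.approx(weighted_sensitivity(exams))
        assert table.loc[0, "n_exams"] == len(exams)

    def test_generated_density_gap_recovered_within_cis(self):
        """A built-in dense-breast sensitivity deficit shows up in the
        subgroup table, with each level's CI covering its generating value."""
        config = SimulationConfig(n_women=8000, exam_prevalence=0.03)
        exams, _ = simulate_study(config, seed=31)
        exams = add_outcome_groups(exams)
        exams["weight"] = 1.0
        table = subgroup_evaluate(
            exams,
            SubgroupSpec(variable="density", levels=("dense", "nondense")),
            {"sens": weighted_sensitivity},
            B=300,
            seed=32,
        ).set_index("level")

        # generating values: intercept calibrated on the cancer exams so the
        # marginal hits the target, dense offset log(0.36)
        from mammoeval.simulate import _calibrate_intercept, _log_odds_offsets
        from scipy.special import expit

        cancers = exams[exams.cancer_12mo]
        off = _log_odds_offsets(cancers, config.subgroup_effects, "sensitivity")
        c = _calibrate_intercept(off, config.reader_sensitivity)
        truth = {
            lv: float(np.mean(expit(c + off[(cancers.density == lv).to_numpy()])))
            for lv in ("dense", "nondense")
        }
        assert truth["nondense"] - truth["dense"] > 0.1
        for lv in ("dense", "nondense"):
            assert table.loc[lv, "ci_low"] <= truth[lv] <= table.loc[lv, "ci_high"]
        assert table.loc["dense", "estimate"] < table.loc["nondense", "estimate"]

    def test_missing_own_level_conserves_exams(self):
        exams = _toy_cohort(seed=6)
        exams.loc[exams.sample(frac=0.2, random_state=0).index, "density"] = pd.NA
        table = subgroup_evaluate(
            exams,
            SubgroupSpec(variable="density", missing_policy="own_level"),
            {"sens": weighted_sensitivity},
            B=100,
            seed=10,
        )
        assert set(table["level"]) == {"dense", "nondense", "missing"}
        assert table.groupby("level")["n_exams"].first().sum() == len(exams)

    def test_paired_comparison_column_present(self):
        exams = _toy_cohort(seed=7)
        table = subgroup_evaluate(
            exams,
            SubgroupSpec(variable="density"),
            {
                "sens": weighted_sensitivity,
                "sens_again": weighted_sensitivity,
            },
            B=100,
            seed=11,
            comparisons=[("sens", "sens_again")],
        )
        p = table.loc[table.statistic == "sens", "p_vs_sens_again"]
        assert np.allclose(p, 1.0)  # identical statistics differ nowhere
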