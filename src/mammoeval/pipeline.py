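"""End-to-end evaluation pipeline and report bundle.

Stages: load or simulate the cohort -> outcome-group partition -> designed
subsample with inverse-probability weights -> weighted reader metrics ->
per-model weighted ROC and operating points matched to the reader -> fit
and evaluate the ensemble combiner (score-only and reader-augmented) ->
weighted calibration -> patient-level stratified bootstrap CIs and paired
comparisons -> optional subgroup analyses -> write the bundle.

Every numeric cell written by this module is produced by one operation of
the underlying modules; the reporting layer only assembles.

The combiner is fitted once on the analysis sample and then held fixed
during bootstrap inference, mirroring evaluation of a pre-trained ensemble;
matched operating points are re-derived on every bootstrap resample from
that resample's reader performance.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import (
    SubgroupSpec,
    paired_difference_test,
    stratified_patient_bootstrap,
    subgroup_evaluate,
)
from .calibration import calibration_slope_intercept
from .cohort import add_outcome_groups, group_counts, screen_positive
from .ensemble import (
    aggregate_sides,
    apply_combiner,
    binarize_reader,
    fit_combiner,
    logit_scores,
)
from .io import read_exam_table, read_score_table, write_exam_table
from .metrics import (
    match_operating_point,
    performance_metrics,
    weighted_confusion,
    weighted_pr_curve,
    weighted_roc,
)
from .sampling import SamplingDesign, draw_designed_subsample
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger("mammoeval")

#: Sampling fractions of the designed oversampling study this pipeline
#: reproduces; used as the default design in simulation mode.
STUDY_FRACTIONS = {"TN": 0.295, "FP": 0.412, "TP": 0.779, "FN": 0.881}


@dataclass
class PipelineConfig:
    """Configuration of one evaluation run."""

    exam_path: str | None = None
    score_path: str | None = None
    simulation: SimulationConfig | None = None
    sampling_fractions: dict | None = field(default_factory=lambda: dict(STUDY_FRACTIONS))
    bootstrap_reps: int = 1000
    seed: int = 0
    subgroups: Sequence[str] = ()
    calibration_bins: int = 10
    outdir: str | None = None

    def __post_init__(self):
        have_paths = self.exam_path is not None
        if have_paths == (self.simulation is not None):
            raise ValueError(
                "exactly one of (exam_path [+ score_path], simulation) must be supplied"
            )
        if have_paths and self.score_path is None:
            raise ValueError("score_path required alongside exam_path")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)


def _weighted_statistics(
    sub: pd.DataFrame, score_cols: Sequence[str]
) -> dict[str, float]:
    """All headline metrics of one (re)sample, computed together.

    Reader sensitivity/specificity, each score column's weighted AUROC, and
    the matched operating points of the ensemble columns against the
    reader's performance *on this sample*.
    """
    call = screen_positive(sub["birads"].to_numpy())
    cancer = sub["cancer_12mo"].to_numpy()
    w = sub["weight"].to_numpy()
    m = performance_metrics(weighted_confusion(call, cancer, w))
    out = {"reader_sensitivity": m.sensitivity, "reader_specificity": m.specificity,
           "reader_ppv": m.ppv, "reader_air": m.air, "reader_cdr": m.cdr,
           "reader_fnr": m.fnr}
    for col in score_cols:
        s = sub[col].to_numpy()
        out[f"{col}:auroc"] = weighted_roc(s, cancer, w).auc
        if "ensemble" in col:
            at_spec = match_operating_point(
                s, cancer, w, axis="specificity", target=m.specificity
            )
            at_sens = match_operating_point(
                s, cancer, w, axis="sensitivity", target=m.sensitivity
            )
            out[f"{col}:sens_at_reader_spec"] = at_spec.metrics.sensitivity
            out[f"{col}:spec_at_reader_sens"] = at_sens.metrics.specificity
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full evaluation; return (and optionally write) the bundle."""
    rng_seed = np.random.SeedSequence(config.seed)
    s_sim, s_design, s_boot, s_subgroup = (s.generate_state(1)[0] % 2**31
                                           for s in rng_seed.spawn(4))

    if config.simulation is not None:
        logger.info("simulating cohort: n_women=%d", config.simulation.n_women)
        exams, panel = simulate_study(config.simulation, s_sim)
    else:
        logger.info("reading %s and %s", config.exam_path, config.score_path)
        exams = read_exam_table(config.exam_path)
        panel = read_score_table(config.score_path)

    exams = add_outcome_groups(exams)
    counts = group_counts(exams)
    logger.info("outcome groups: %s", counts)

    if config.sampling_fractions:
        sub, design = draw_designed_subsample(
            exams, config.sampling_fractions, s_design
        )
    else:
        sub = exams.copy()
        sub["weight"] = 1.0
        design = SamplingDesign(fractions={g: 1.0 for g, n in counts.items() if n})
    logger.info("analysis sample: %d exams (of %d)", len(sub), len(exams))

    # examination-level model scores, aligned to the analysis sample
    wide = aggregate_sides(panel)
    missing = set(sub["exam_id"]) - set(wide.index)
    if missing:
        raise ValueError(f"{len(missing)} sampled exams have no model scores")
    model_ids = list(wide.columns)
    scores = wide.loc[sub["exam_id"]].reset_index(drop=True)
    for mid in model_ids:
        sub[f"score:{mid}"] = scores[mid].to_numpy()

    cancer = sub["cancer_12mo"].to_numpy()
    weight = sub["weight"].to_numpy()

    # ensemble combiners on log-odds features, weighted by the design
    features = pd.DataFrame(
        {mid: logit_scores(sub[f"score:{mid}"]) for mid in model_ids}
    )
    combiner = fit_combiner(features, cancer, weight, includes_reader=False)
    features_r = features.copy()
    features_r["reader"] = binarize_reader(sub["birads"].to_numpy())
    combiner_r = fit_combiner(features_r, cancer, weight, includes_reader=True)
    sub["score:ensemble"] = apply_combiner(combiner, features)
    sub["score:ensemble_reader"] = apply_combiner(combiner_r, features_r)

    score_cols = [f"score:{mid}" for mid in model_ids] + [
        "score:ensemble", "score:ensemble_reader",
    ]
    point = _weighted_statistics(sub, score_cols)

    curves = {}
    for col in score_cols:
        roc = weighted_roc(sub[col].to_numpy(), cancer, weight)
        pr = weighted_pr_curve(sub[col].to_numpy(), cancer, weight)
        curves[col] = {
            "roc": pd.DataFrame(
                {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
            ),
            "pr": pd.DataFrame(
                {"threshold": pr.thresholds, "recall": pr.recall,
                 "precision": pr.precision}
            ),
        }

    calibration = {}
    for col in ("score:ensemble", "score:ensemble_reader"):
        calibration[col] = calibration_slope_intercept(
            sub[col].to_numpy(), cancer, weight
        )

    logger.info("bootstrap: B=%d", config.bootstrap_reps)
    summaries = stratified_patient_bootstrap(
        sub,
        lambda d: _weighted_statistics(d, score_cols),
        B=config.bootstrap_reps,
        seed=s_boot,
    )
    p_values = {}
    for col in ("score:ensemble", "score:ensemble_reader"):
        p_values[f"{col}:sens_at_reader_spec"] = paired_difference_test(
            summaries[f"{col}:sens_at_reader_spec"].replicates,
            summaries["reader_sensitivity"].replicates,
        )
        p_values[f"{col}:spec_at_reader_sens"] = paired_difference_test(
            summaries[f"{col}:spec_at_reader_sens"].replicates,
            summaries["reader_specificity"].replicates,
        )
    p_values["ensemble_reader_vs_ensemble:auroc"] = paired_difference_test(
        summaries["score:ensemble_reader:auroc"].replicates,
        summaries["score:ensemble:auroc"].replicates,
    )

    results_long = pd.DataFrame(
        [
            {
                "statistic": name,
                "estimate": s.estimate,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "p_vs_reader": p_values.get(name, np.nan),
            }
            for name, s in summaries.items()
        ]
    )

    subgroup_tables = []
    for variable in config.subgroups:
        spec = SubgroupSpec(variable=variable)
        stats = {
            "reader_sensitivity": lambda d: _sub_metric(d, "sensitivity"),
            "reader_specificity": lambda d: _sub_metric(d, "specificity"),
            "ensemble_reader_auroc": lambda d: weighted_roc(
                d["score:ensemble_reader"].to_numpy(),
                d["cancer_12mo"].to_numpy(),
                d["weight"].to_numpy(),
            ).auc,
        }
        subgroup_tables.append(
            subgroup_evaluate(
                sub, spec, stats, B=config.bootstrap_reps, seed=s_subgroup
            )
        )
    subgroup_table = (
        pd.concat(subgroup_tables, ignore_index=True)
        if subgroup_tables
        else pd.DataFrame()
    )

    bundle = {
        "counts": counts,
        "design": design,
        "analysis_sample": sub,
        "combiner": combiner,
        "combiner_reader": combiner_r,
        "point_estimates": point,
        "curves": curves,
        "calibration": calibration,
        "bootstrap": summaries,
        "p_values": p_values,
        "results_long": results_long,
        "subgroups": subgroup_table,
        "seed": config.seed,
    }
    if config.outdir is not None:
        write_results(bundle, config.outdir, config)
    return bundle


def _sub_metric(d: pd.DataFrame, which: str) -> float:
    m = performance_metrics(
        weighted_confusion(
            screen_positive(d["birads"].to_numpy()),
            d["cancer_12mo"].to_numpy(),
            d["weight"].to_numpy(),
        )
    )
    return getattr(m, which)


def write_results(bundle: dict, outdir, config: PipelineConfig | None = None) -> None:
    """Write the report bundle as CSV/JSON files plus a run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    (out / "design.json").write_text(bundle["design"].to_json(seed=bundle["seed"]))
    write_exam_table(bundle["analysis_sample"], out / "analysis_sample.csv")

    metrics = {
        "group_counts": bundle["counts"],
        "point_estimates": bundle["point_estimates"],
        "p_values": bundle["p_values"],
        "combiner": {
            "model_ids": list(bundle["combiner"].model_ids),
            "coefficients": bundle["combiner"].coefficients,
            "intercept": bundle["combiner"].intercept,
            "includes_reader": False,
        },
        "combiner_reader": {
            "model_ids": list(bundle["combiner_reader"].model_ids),
            "coefficients": bundle["combiner_reader"].coefficients,
            "intercept": bundle["combiner_reader"].intercept,
            "includes_reader": True,
        },
        "calibration": {
            col: {"intercept": c.intercept, "slope": c.slope}
            for col, c in bundle["calibration"].items()
        },
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))

    bundle["results_long"].to_csv(out / "results_long.csv", index=False)
    if len(bundle["subgroups"]):
        bundle["subgroups"].to_csv(out / "subgroups.csv", index=False)
    for col, cv in bundle["curves"].items():
        stem = col.replace("score:", "").replace(":", "_")
        cv["roc"].to_csv(out / f"roc_{stem}.csv", index=False)
        cv["pr"].to_csv(out / f"pr_{stem}.csv", index=False)
    for col, c in bundle["calibration"].items():
        stem = col.replace("score:", "")
        c.bins.to_csv(out / f"calibration_{stem}.csv", index=False)

    log_lines = [
        f"mammoeval {__version__}",
        f"python {platform.python_version()}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {bundle['seed']}",
        f"bootstrap_reps {config.bootstrap_reps if config else 'n/a'}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
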