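# mammoeval

Inverse-probability-weighted evaluation of screening-mammography AI against
radiologist performance.

## The problem

External validation of a mammography AI model on a screening cohort faces a
practical obstacle: cancers are rare (~6 per 1000 examinations) and running
models on every examination is expensive, so analysis sets are built by
**designed oversampling** — keep most or all of the cancers and reader
false positives, subsample the vast pool of true negatives. Raw statistics
on such a set are biased; attaching each examination's
**inverse probability of selection weight** (the reciprocal of its outcome
group's sampling fraction) makes weighted statistics estimate full-cohort
performance again.

`mammoeval` implements that evaluation methodology end to end, for
biostatisticians and imaging-AI teams validating black-box cancer scores
against the interpreting radiologist:

- **Outcome-group partitioning** — an examination is screen positive when
  its BI-RADS assessment is in {0, 3, 4, 5}; crossing the reader call with
  the 12-month cancer outcome yields the TP / FP / FN / TN groups.
- **Designed subsampling** with per-group fractions and empirical IPW
  weights, built so weighted group totals reproduce full-cohort counts
  exactly.
- **Weighted screening metrics and ROC analysis** — sensitivity
  TP/(TP+FN), specificity TN/(TN+FP), PPV, abnormal interpretation rate
  (TP+FP)/N, cancer detection rate TP/N, FN rate FN/N; weighted ROC / PR
  curves and AUROC; and **operating points matched to the reader**
  (model sensitivity at the radiologist's specificity and vice versa).
- **Ensemble combination** — a weighted logistic stacker over per-model
  examination scores (max over breast sides), optionally augmented with
  the binarized reader call; a scikit-learn-compatible estimator
  (`LogisticScoreCombiner`) underneath.
- **Weighted calibration** — reliability curves over weighted-quantile
  bins plus the calibration intercept (offset fit, slope pinned at 1) and
  slope (weighted logistic regression of outcome on the score's log-odds).
- **Patient-level stratified bootstrap** — women, not examinations, are
  resampled (repeat screens of one woman are correlated), stratified so
  the rare cancer stratum is preserved; percentile CIs, paired
  model-vs-reader p-values, and subgroup analyses (density,
  race/ethnicity, personal history, ...).
- **Synthetic cohorts** — a generator that emulates the cohort structure
  the method assumes (~2.9 screens/woman, 0.6% exam-level cancer rate,
  reader at sensitivity 0.826 / specificity 0.930, correlated model scores
  with binormal AUROC targets, subgroup-varying accuracy), so the whole
  pipeline is testable without access to restricted imaging data.

## Worked example

```python
import mammoeval as me

# a synthetic screening programme at the default study conditions
cfg = me.SimulationConfig(n_women=40_000)
exams, panel = me.simulate_study(cfg, seed=1)
exams = me.add_outcome_groups(exams)
print(me.group_counts(exams))
# {'TP': 590, 'FP': 8051, 'FN': 135, 'TN': 106794}

# designed oversampling + IPW weights
sub, design = me.draw_designed_subsample(
    exams, {"TN": 0.295, "FP": 0.412, "TP": 0.779, "FN": 0.881}, seed=2
)
m = me.performance_metrics(me.weighted_confusion(
    me.screen_positive(sub["birads"].to_numpy()),
    sub["cancer_12mo"].to_numpy(), sub["weight"].to_numpy(),
))
print(round(m.sensitivity, 3), round(m.specificity, 3))
# 0.814 0.93          <- weighted subsample == full-cohort reader performance

# one model's weighted AUROC on the subsample
wide = me.aggregate_sides(panel)
roc = me.weighted_roc(
    wide.loc[sub["exam_id"], "model_03"].to_numpy(),
    sub["cancer_12mo"].to_numpy(), sub["weight"].to_numpy(),
)
print(round(roc.auc, 3))
# 0.8               <- generator target for model_03 was 0.80
```

The weighted sensitivity/specificity equal the full-cohort values exactly
(the IPW round-trip identity); the weighted AUROC recovers the generating
binormal target within Monte-Carlo error.

The full pipeline — metrics, ensembles, calibration, bootstrap CIs,
subgroup tables, CSV/JSON report bundle — runs from one config:

```sh
mammoeval report --config config.yaml --outdir results/
```

with a config such as

```yaml
simulation:            # or: exam_path: exams.csv / score_path: scores.csv
  n_women: 40000
sampling_fractions: {TN: 0.295, FP: 0.412, TP: 0.779, FN: 0.881}
bootstrap_reps: 1000
seed: 1
subgroups: [density]
```

Other subcommands (`simulate`, `partition`, `design`, `evaluate`,
`calibrate`, `bootstrap`) expose the individual stages.

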