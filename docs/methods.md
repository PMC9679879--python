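# Methods

This note documents the statistical machinery in `mammoeval`: the model of
the screening process, the weighted estimators, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Screening model and outcome groups

The atomic record is a screening examination of one woman: a BI-RADS
assessment by the interpreting radiologist, a binary cancer outcome
(diagnosis within 12 months of the examination), and covariates (age, BMI,
breast density, race/ethnicity, personal history of breast cancer).
A call is *screen positive* for BI-RADS in {0, 3, 4, 5} and negative for
{1, 2}; note the small number of 3/4/5 assessments fold into the positive
groups under this rule. Crossing call × outcome gives the four outcome
groups TP, FP, FN, TN. The 12-month window is applied upstream: the
package takes `cancer_12mo` as a boolean, performs no date arithmetic, and
treats the longitudinal reading of "true negative" (no cancer between
consecutive negative screens) as equivalent to the per-exam rule — which
it is for any cohort, like the simulated ones, where a cancer never falls
between two negative examinations of the same woman.

## Designed subsampling and IPW

Let n_g and N_g be subsample and full-cohort counts of group g. The
*empirical* design uses realized fractions f_g = n_g/N_g and weights
w_g = 1/f_g, so the weighted group totals Σ w_g over the subsample equal
N_g identically — the round-trip identity on which the whole weighting
scheme rests. Draws are uniform without replacement within group;
`round(f·N)` (half away from zero, minimum one exam per nonempty group)
fixes the subsample size. Sampling is at the examination level — a woman
may contribute some but not all of her exams — with her identity retained
for the clustered bootstrap.

A consequence worth stating: weighted *confusion-based* metrics
(sensitivity, specificity, PPV, AIR, CDR, FN rate) computed on the
subsample with empirical weights equal the full-cohort unweighted values
*exactly* whenever the classification rule is group-consistent (as the
reader's call is, by construction). Weighted AUROC of a continuous score
is not exactly preserved — the subsample loses some exams — but is an
unbiased estimate; tests verify agreement within Monte-Carlo error.

## Weighted ROC machinery

All curve operations share one sweep: scores sorted descending, tied
scores grouped into a single vertex, cumulative weighted true/false
positive rates. The ROC curve is anchored at (0,0) and ends at (1,1); the
AUROC is the trapezoidal area, which equals the weighted probability that
a random cancer exam outscores a random non-cancer exam with half credit
for ties (verified against the exhaustive pair sum to 1e-12). A single
convention is fixed throughout: an exam is model-positive when its score
is *strictly greater* than the threshold; ties at the threshold count as
negative, matching the half-credit tie treatment.

Operating points matched to the reader pick the achievable empirical
vertex whose sensitivity (or specificity) is nearest the target — the
reader's value *estimated from the same sample* — with ties broken in
favour of the higher value on the other axis (the convention that favours
the model, mirroring "at least as good as" reporting). No interpolation is
performed by default; an optional linear-interpolation mode exists for
closed-form large-sample checks. The matching target is the weighted
reader estimate (weighted and unweighted coincide under the round-trip
identity above).

The precision-recall curve reports weighted precision at each vertex and
stops once full recall is first achieved; its area is the step sum
Σ (r_i − r_{i−1})·p_i (average-precision form).

## Ensemble combiner

Each model emits a confidence score in [0,1] per breast side; the
examination score is the maximum over sides (the most suspicious finding
drives recall — the standard screening reduction; the per-breast-to-exam
reduction is not uniquely determined by the evaluation contract, so the
conventional one is used). The combiner is a weighted maximum-likelihood
logistic stacker; the pipeline feeds it the *log-odds* of the model scores
(clipped to [1e-6, 1−1e-6]), the natural linear scale for probabilistic
scores. The reader-augmented variant appends the binarized call
(1 iff screen positive). The fit is convex, hence deterministic given the
data; if the optimizer fails to converge, a coefficient exceeds 30, or the
data are perfectly separated with wide margin, the fit falls back to a
small ridge penalty (1e-4 on the coefficients) and flags it in the result.
The published ensembles whose contract this mirrors do not publish their
reweighting scheme or coefficients; this transparent convex surrogate has
the same inputs and outputs and is fitted on the analysis sample itself.
During bootstrap inference the combiner is fitted once and held fixed —
the position a pre-trained ensemble would be in — while matched operating
points *are* re-derived on every resample from that resample's reader
performance.

## Calibration

The calibration *slope* is the coefficient of a weighted logistic
regression of the outcome on logit(score). The *intercept* is
calibration-in-the-large: a second weighted fit of outcome on a constant
with logit(score) as a fixed offset (slope pinned at 1) — the
offset-based convention of the calibration-hierarchy literature, chosen
over joint fitting because it makes "risk right on average" interpretable
independently of the slope. Reliability curves use 10 weighted-quantile
bins by default (equal total weight per bin); degenerate all-equal scores
return a single bin with a warning. Scores of exactly 0 or 1 are clipped
to [1e-6, 1−1e-6] before the log-odds transform so degenerate inputs give
finite estimates. Separation falls back to a ridge-stabilized GLM and is
flagged.

## Bootstrap inference

Confidence intervals are percentile intervals from a nonparametric
bootstrap that resamples *women* with replacement — repeat screens of one
woman are correlated — carrying all exams and weights of each drawn woman.
Each woman is labelled by her most severe outcome group
(FN > TP > FP > TN).

Resampling strata deserve a note, because the obvious scheme is wrong.
Holding each of the four groups fixed as a separate patient stratum pins
the number of TP women and FN women in every replicate; since a woman
rarely has more than one cancer examination, the bootstrap distribution of
sensitivity then collapses to a point, and specificity loses nearly all of
its variance the same way (FP-woman count pinned). The default therefore
stratifies by *cancer status*: cancer women (any TP/FN exam) form one
stratum, non-cancer women the other. This still preserves the rare cancer
stratum exactly in every replicate — the purpose of stratifying — while
letting the TP/FN and FP/TN splits vary binomially, which is the variation
the estimators actually have. The literal four-group scheme remains
available (`resampling_strata="outcome_group"`) for variance
decomposition, not for inference. Simulation shows the default attains
~94% empirical coverage for weighted sensitivity at nominal 95%
(the acceptance suite re-runs this check).

Paired comparisons (ensemble vs reader, between subgroup levels) compute
all statistics on the *same* resamples; the two-sided percentile p-value
is 2·min(prop(diff ≤ 0), prop(diff ≥ 0)), floored at 2/(B+1) and capped
at 1, and is symmetric in its arguments. A statistic undefined on a
replicate (e.g. a subgroup level with no cancers drawn) is recorded as
missing; more than 10% missing is a hard error. B defaults to 1000. No
multiple-testing adjustment is applied — subgroup p-values are reported
raw, as exploratory.

BCa intervals are not implemented; percentile intervals are the simplest
method consistent with the reporting they support.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline's statistical claims are verified.

- **Structure**: each woman contributes k screens, k ~ zero-truncated
  Poisson with mean 2.9 (rate solved numerically); covariates are fixed
  per woman. Race/ethnicity frequencies default to
  asian 0.098 / black 0.085 / hispanic 0.106 / white 0.593 / other 0.118;
  personal history of breast cancer 6.1%; age ~ N(58.9, 11.6²) and
  BMI ~ N(28.4, 6.9²), clipped to plausible ranges.
- **Cancer**: at most one per woman, placed on her last examination with
  probability proportional to k, so the examination-level rate hits the
  0.6% target and no cancer ever lies between two negative screens.
  80% of cancers are invasive, the rest DCIS.
- **Reader**: cancer exams called positive with probability centred on
  sensitivity 0.826, non-cancer exams called negative around specificity
  0.930. Positive calls are BI-RADS 0 except a fraction 0.059 labelled
  3/4/5 (≈0.4% of all exams); negative calls split 60/40 between BI-RADS
  1 and 2.
- **Model scores**: a binormal latent construction — cancer exams shifted
  by d = √2·Φ⁻¹(AUROC target) per model, a shared noise component at the
  configured inter-model correlation (default 0.5, a stipulated default,
  not an estimate), squashed through a logistic so scores live in [0,1]
  (monotone, hence AUROC-preserving, and making closed-form oracle tests
  exact). The cancer-bearing side carries the examination score; the other
  side a uniformly shrunken copy, so the max-over-sides reduction returns
  the examination score identically. Default targets span 0.77–0.83
  across five models.
- **Subgroup effects** act as multiplicative odds modifiers (composable,
  sign-interpretable) on prevalence, reader sensitivity/specificity, or
  model discrimination (where the modifier multiplies d). After applying
  them, a global intercept is re-solved on the realized cohort
  (Brent root-finding) so the *marginal* rate still equals its target:
  subgroups vary around a pinned overall level, and discrimination
  modifiers are mean-normalized over cancer exams for the same reason.
  Defaults: dense breasts carry a 0.36 odds modifier on reader
  sensitivity (landing dense ≈ 0.69 vs nondense ≈ 0.86 at a 20% dense
  fraction — the dense fraction is itself implied by those three
  sensitivities rather than directly specified) and a 0.80 discrimination
  modifier; Asian women a 0.75 sensitivity modifier; prior breast cancer a
  0.80 discrimination modifier.

**What passing tests show — and do not.** The simulator reproduces the
*statistical* structure the estimators rely on: clustering, rare outcomes,
designed oversampling, correlated scores with known discrimination,
subgroup heterogeneity. It does not emulate real mammography scores'
distributional quirks (multimodality, vendor effects, drift), longitudinal
density/age progression, interval-cancer hazards beyond the 12-month flag,
missing-covariate mechanisms, or any image-level phenomenon. Tests passing
here certify the correctness of the estimators and the pipeline plumbing,
not the real-world performance of any particular AI model.

## Problem sizes and determinism

Acceptance-level checks run at 40 000 women (~116 000 exams) for the
end-to-end IPW identity, 50 outer replicates × B=200 for parameter
recovery, and 200 outer simulations × B=300 at 5 000 women for bootstrap
coverage — sizes chosen to keep Monte-Carlo error comfortably inside the
asserted tolerances while the whole suite stays quick. Every stochastic
step takes an explicit seed (NumPy `SeedSequence` spawning keeps stages
independent); fixed seeds give byte-identical outputs, including written
CSV/JSON bundles.

## Known limitations

- The combiner is fitted and evaluated on the same analysis sample
  (matching the evaluation-of-a-fixed-ensemble setting only
  approximately); no cross-fitting is implemented.
- Percentile CIs can under-cover slightly for AUROC at very small cancer
  counts.
- The with-replacement bootstrap ignores the finite-population correction
  of without-replacement subsampling, making CIs mildly conservative for
  heavily sampled groups.
- No DeLong variance, partial AUC, smoothed/binormal fitted curves,
  spline calibration, or decision-curve analysis.
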