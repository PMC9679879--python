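"""Synthetic screening cohorts with the structure the evaluation assumes.

The generator emulates a large screening programme: women contribute ~2.9
screens each (zero-truncated Poisson), the examination-level 12-month cancer
rate is ~0.6%, the reader operates near sensitivity 0.826 / specificity
0.930, and a panel of AI models produces correlated per-breast scores whose
examination-level discrimination hits configurable binormal AUROC targets.

Subgroup effects (breast density, race/ethnicity, personal history) act as
multiplicative odds modifiers on prevalence, reader sensitivity/specificity
or model discrimination; after applying them, a global intercept is
recalibrated on the realized cohort so the *marginal* rates still equal
their targets — subgroups vary around a pinned overall level.

A woman's cancer, when she has one, is placed on her last examination, so
no cancer ever falls between two negative screens of the same woman and the
per-exam outcome-group rules coincide with their longitudinal reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtri

DEFAULT_RACE_FREQUENCIES = {
    "asian": 0.098,
    "black": 0.085,
    "hispanic": 0.106,
    "white": 0.593,
    "other": 0.118,
}

#: Odds modifiers per covariate level.  "discrimination" multiplies the
#: binormal separation of the model scores rather than an odds ratio.
DEFAULT_SUBGROUP_EFFECTS = {
    "density": {"dense": {"sensitivity": 0.36, "discrimination": 0.80}},
    "race_ethnicity": {"asian": {"sensitivity": 0.75}},
    "prior_breast_cancer": {True: {"discrimination": 0.80}},
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screening cohort."""

    n_women: int = 40_000
    exams_per_woman_mean: float = 2.9
    exam_prevalence: float = 0.006
    invasive_fraction: float = 0.80
    reader_sensitivity: float = 0.826
    reader_specificity: float = 0.930
    model_aurocs: tuple[float, ...] = (0.77, 0.785, 0.80, 0.815, 0.83)
    inter_model_correlation: float = 0.5
    subgroup_effects: dict = field(
        default_factory=lambda: {k: {l: dict(m) for l, m in v.items()}
                                 for k, v in DEFAULT_SUBGROUP_EFFECTS.items()}
    )
    race_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_RACE_FREQUENCIES))
    prior_cancer_frequency: float = 0.061
    dense_frequency: float = 0.20
    age_mean: float = 58.9
    age_sd: float = 11.6
    bmi_mean: float = 28.4
    bmi_sd: float = 6.9
    birads1_fraction: float = 0.60
    suspicious_call_fraction: float = 0.059
    score_scale: float = 1.0
    score_loc: float = -3.0

    def __post_init__(self):
        if self.n_women < 1:
            raise ValueError("n_women must be positive")
        if self.exams_per_woman_mean <= 1.0:
            raise ValueError("exams_per_woman_mean must exceed 1 (minimum one exam)")
        if not (0.0 <= self.exam_prevalence < 1.0):
            raise ValueError("exam_prevalence must be in [0, 1)")
        for name in ("reader_sensitivity", "reader_specificity", "invasive_fraction",
                     "birads1_fraction", "suspicious_call_fraction",
                     "prior_cancer_frequency", "dense_frequency"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.inter_model_correlation < 1.0):
            raise ValueError("inter_model_correlation must be in [0, 1)")
        for a in self.model_aurocs:
            if a <= 0.5 or a >= 1.0:
                raise ValueError(f"model AUROC target must be in (0.5, 1), got {a}")
        total = sum(self.race_frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"race frequencies must sum to 1, got {total}")
        for var, levels in self.subgroup_effects.items():
            for level, mods in levels.items():
                for target, m in mods.items():
                    if m <= 0:
                        raise ValueError(
                            f"subgroup odds modifier must be positive: "
                            f"{var}={level} {target}={m}"
                        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_aurocs"] = list(self.model_aurocs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "model_aurocs" in d:
            d["model_aurocs"] = tuple(d["model_aurocs"])
        if "subgroup_effects" in d:
            d["subgroup_effects"] = _parse_effects(d["subgroup_effects"])
        return cls(**d)


def _parse_effects(effects: Mapping) -> dict:
    """Normalize JSON/YAML effect keys ('true'/'false' strings) to booleans."""
    out: dict = {}
    for var, levels in effects.items():
        out[var] = {}
        for level, mods in levels.items():
            if isinstance(level, str) and level.lower() in ("true", "false"):
                level = level.lower() == "true"
            out[var][level] = dict(mods)
    return out


def _zero_truncated_poisson_rate(mean: float) -> float:
    """lambda of a zero-truncated Poisson with the given mean (> 1)."""
    return brentq(lambda lam: lam / (1.0 - math.exp(-lam)) - mean, 1e-9, 50.0)


def _log_odds_offsets(exams: pd.DataFrame, effects: Mapping, target: str) -> np.ndarray:
    out = np.zeros(len(exams))
    for var, levels in effects.items():
        if var not in exams.columns:
            continue
        col = exams[var].to_numpy()
        for level, mods in levels.items():
            if target in mods:
                out[col == level] += math.log(mods[target])
    return out


def _calibrate_intercept(offsets: np.ndarray, target: float, weights=None) -> float:
    """Intercept c with weighted mean expit(c + offsets) equal to target."""
    base = logit(target)
    if np.allclose(offsets, 0.0):
        return float(base)

    def gap(c):
        return np.average(expit(c + offsets), weights=weights) - target

    span = float(np.max(np.abs(offsets))) + 12.0
    return float(brentq(gap, base - span, base + span))


def generate_cohort(config: SimulationConfig, seed) -> pd.DataFrame:
    """Generate the examination table (without reader calls).

    Each woman carries fixed covariates; her examinations share them.  At
    most one cancer per woman, placed on her last examination, with the
    per-woman probability proportional to her number of screens so the
    examination-level cancer rate matches ``exam_prevalence`` after
    subgroup adjustment.
    """
    rng = np.random.default_rng(seed)
    n = config.n_women

    lam = _zero_truncated_poisson_rate(config.exams_per_woman_mean)
    k = rng.poisson(lam, size=n)
    while (zero := k == 0).any():
        k[zero] = rng.poisson(lam, size=int(zero.sum()))

    races = list(config.race_frequencies)
    women = pd.DataFrame(
        {
            "woman_id": np.array([f"W{i:06d}" for i in range(n)]),
            "race_ethnicity": rng.choice(
                races, size=n, p=list(config.race_frequencies.values())
            ),
            "prior_breast_cancer": rng.random(n) < config.prior_cancer_frequency,
            "density": np.where(
                rng.random(n) < config.dense_frequency, "dense", "nondense"
            ),
            "age_years": np.clip(
                rng.normal(config.age_mean, config.age_sd, size=n), 30.0, 95.0
            ).round(1),
            "bmi": np.clip(
                rng.normal(config.bmi_mean, config.bmi_sd, size=n), 14.0, 65.0
            ).round(1),
            "n_exams": k,
        }
    )

    if config.exam_prevalence > 0:
        offsets = _log_odds_offsets(women, config.subgroup_effects, "prevalence")
        c = _calibrate_intercept(offsets, config.exam_prevalence, weights=k)
        p_exam = expit(c + offsets)
        q_woman = np.minimum(k * p_exam, 0.95)
        has_cancer = rng.random(n) < q_woman
    else:
        has_cancer = np.zeros(n, dtype=bool)
    invasive = rng.random(n) < config.invasive_fraction

    exams = women.loc[women.index.repeat(k)].reset_index(drop=True)
    seq = _expand_seq(k)
    exams["exam_seq"] = seq
    exams["exam_id"] = np.array([f"E{i:07d}" for i in range(len(exams))])
    is_last = exams["exam_seq"].to_numpy() == np.repeat(k, k)
    cancer_exam = is_last & np.repeat(has_cancer, k)
    exams["cancer_12mo"] = cancer_exam
    ctype = np.where(np.repeat(invasive, k), "invasive", "dcis")
    exams["cancer_type"] = np.where(cancer_exam, ctype, "none")
    cols = [
        "woman_id", "exam_id", "exam_seq", "cancer_12mo", "cancer_type",
        "age_years", "bmi", "density", "race_ethnicity", "prior_breast_cancer",
    ]
    return exams[cols]


def _expand_seq(counts: np.ndarray) -> np.ndarray:
    total = int(counts.sum())
    reps = np.repeat(np.cumsum(counts) - counts, counts)
    return np.arange(total) - reps + 1


def _bounded_bernoulli(rng, offsets, target, n):
    """Draw Bernoulli(p) with p subgroup-shifted around a pinned marginal."""
    if target <= 0.0:
        return np.zeros(n, dtype=bool)
    if target >= 1.0:
        return np.ones(n, dtype=bool)
    c = _calibrate_intercept(offsets, target)
    return rng.random(n) < expit(c + offsets)


def generate_reader_calls(exams: pd.DataFrame, config: SimulationConfig, seed) -> np.ndarray:
    """BI-RADS categories emulating the reference reader.

    Cancer exams are called positive with subgroup-adjusted probability
    around ``reader_sensitivity``; non-cancer exams negative around
    ``reader_specificity``.  Positive calls are BI-RADS 0 except for a
    small fraction labelled 3/4/5; negative calls split between BI-RADS 1
    and 2.
    """
    rng = np.random.default_rng(seed)
    n = len(exams)
    cancer = exams["cancer_12mo"].to_numpy(dtype=bool)
    positive = np.zeros(n, dtype=bool)

    if cancer.any():
        off = _log_odds_offsets(exams[cancer], config.subgroup_effects, "sensitivity")
        positive[cancer] = _bounded_bernoulli(
            rng, off, config.reader_sensitivity, int(cancer.sum())
        )
    if (~cancer).any():
        off = _log_odds_offsets(exams[~cancer], config.subgroup_effects, "specificity")
        called_negative = _bounded_bernoulli(
            rng, off, config.reader_specificity, int((~cancer).sum())
        )
        positive[~cancer] = ~called_negative

    birads = np.empty(n, dtype=int)
    u = rng.random(n)
    suspicious = rng.random(n) < config.suspicious_call_fraction
    birads[positive] = np.where(
        suspicious[positive], rng.integers(3, 6, size=int(positive.sum())), 0
    )
    birads[~positive] = np.where(u[~positive] < config.birads1_fraction, 1, 2)
    return birads


def generate_model_scores(exams: pd.DataFrame, config: SimulationConfig, seed) -> pd.DataFrame:
    """Per-breast confidence scores for each model as a long panel.

    A standard-normal disease signal separates cancer from non-cancer exams
    by the binormal distance of each model's target AUROC; models share a
    common noise component at ``inter_model_correlation``.  Scores are a
    logistic squash of the latent signal, which leaves AUROC unchanged.
    The cancer-bearing side carries the examination score; the other side a
    uniformly shrunken copy, so the per-exam maximum equals the
    examination score exactly.
    """
    rng = np.random.default_rng(seed)
    n = len(exams)
    cancer = exams["cancer_12mo"].to_numpy(dtype=bool)
    rho = config.inter_model_correlation

    disc = np.exp(_log_odds_offsets(exams, config.subgroup_effects, "discrimination"))
    if cancer.any():
        disc = disc / disc[cancer].mean()  # pin the marginal AUROC at its target

    z_shared = rng.standard_normal(n)
    cancer_side = np.where(rng.random(n) < 0.5, "left", "right")
    other_side = np.where(cancer_side == "left", "right", "left")

    frames = []
    for m, auc in enumerate(config.model_aurocs):
        d = math.sqrt(2.0) * ndtri(auc)
        latent = d * disc * cancer + math.sqrt(rho) * z_shared \
            + math.sqrt(1.0 - rho) * rng.standard_normal(n)
        s = expit(config.score_scale * latent + config.score_loc)
        shrink = rng.random(n)
        model_id = f"model_{m + 1:02d}"
        frames.append(pd.DataFrame({
            "exam_id": exams["exam_id"].to_numpy(),
            "model_id": model_id,
            "side": cancer_side,
            "score": s,
        }))
        frames.append(pd.DataFrame({
            "exam_id": exams["exam_id"].to_numpy(),
            "model_id": model_id,
            "side": other_side,
            "score": s * shrink,
        }))
    panel = pd.concat(frames, ignore_index=True)
    return panel.sort_values(["exam_id", "model_id", "side"], kind="stable").reset_index(
        drop=True
    )


def simulate_study(config: SimulationConfig, seed) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: examination table with BI-RADS, plus score panel."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cohort, s_reader, s_scores = ss.spawn(3)
    exams = generate_cohort(config, s_cohort)
    exams["birads"] = generate_reader_calls(exams, config, s_reader)
    panel = generate_model_scores(exams, config, s_scores)
    cols = [
        "woman_id", "exam_id", "exam_seq", "birads", "cancer_12mo", "cancer_type",
        "age_years", "bmi", "density", "race_ethnicity", "prior_breast_cancer",
    ]
    return exams[cols], panel
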