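"""Patient-level, outcome-group-stratified nonparametric bootstrap.

Women contribute correlated repeat screens, so resampling is at the patient
level: each replicate draws women with replacement, carrying all of a drawn
woman's examinations and weights.  Resampling is stratified by outcome
group to keep the rare cancer strata intact; a woman whose exams span
several groups is assigned to her most severe one (FN > TP > FP > TN).
Confidence intervals are percentile; paired comparisons reuse the same
resamples for both statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Stratum priority, most severe first.
SEVERITY_ORDER: tuple[str, ...] = ("FN", "TP", "FP", "TN")


@dataclass(frozen=True)
class BootstrapSummary:
    """Point estimate with percentile CI and the replicate distribution."""

    estimate: float
    ci_low: float
    ci_high: float
    n_replicates: int
    replicates: np.ndarray
    n_missing: int = 0
    p_value: float | None = None


def assign_patient_stratum(groups: Iterable[str]) -> str:
    """Most severe outcome group among one woman's examinations."""
    seen = set(groups)
    if not seen:
        raise ValueError("woman has no examinations")
    unknown = seen - set(SEVERITY_ORDER)
    if unknown:
        raise ValueError(f"unknown outcome groups: {sorted(unknown)}")
    for g in SEVERITY_ORDER:
        if g in seen:
            return g
    raise AssertionError("unreachable")


def _patient_blocks(exams: pd.DataFrame):
    """Per-woman exam row indices and stratum, for fast resampling.

    Returns (row_order, starts, counts, strata) where ``row_order`` sorts
    exams by woman, woman ``i`` owns rows
    ``row_order[starts[i]:starts[i]+counts[i]]`` and ``strata[i]`` is her
    most severe group.
    """
    woman = exams["woman_id"].to_numpy()
    order = np.argsort(woman, kind="stable")
    sorted_women = woman[order]
    boundary = np.r_[True, sorted_women[1:] != sorted_women[:-1]]
    starts = np.flatnonzero(boundary)
    counts = np.diff(np.r_[starts, sorted_women.size])

    groups = exams["group"].to_numpy()[order]
    severity_rank = {g: r for r, g in enumerate(SEVERITY_ORDER)}
    ranks = np.array([severity_rank[g] for g in groups])
    strata = np.empty(starts.size, dtype=int)
    for i, (s, c) in enumerate(zip(starts, counts)):
        strata[i] = ranks[s : s + c].min()
    return order, starts, counts, strata


def _expand_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate ranges start_i .. start_i+count_i without a Python loop."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=int)
    reps = np.repeat(np.cumsum(counts) - counts, counts)
    return np.repeat(starts, counts) + np.arange(total) - reps


def stratified_patient_bootstrap(
    exams: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float | Mapping[str, float]],
    *,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    max_missing_frac: float = 0.10,
    resampling_strata: str = "cancer_status",
):
    """Bootstrap a statistic of an examination table at the patient level.

    Parameters
    ----------
    exams : DataFrame
        Must carry ``woman_id`` and ``group`` columns (plus whatever the
        statistic reads, e.g. ``weight``).
    statistic : callable
        Maps a resampled examination table to a float, or to a mapping of
        named floats — all computed on the *same* resample, so named
        replicates are paired across statistics.
    B : int
        Number of replicates (>= 100).
    seed : int or Generator
        Fixed seed gives bit-identical replicate index sequences.
    alpha : float
        1 - confidence level (default 95% percentile interval).
    max_missing_frac : float
        A replicate on which the statistic is undefined (NaN or raises
        ValueError/ZeroDivisionError) is recorded as missing; more than
        this fraction missing is a hard error.
    resampling_strata : {"cancer_status", "outcome_group"}
        With "cancer_status" (default) women are resampled within two
        strata: cancer women (any TP/FN exam, by severity priority) and
        non-cancer women.  This preserves the rare cancer stratum exactly
        while letting the TP/FN and FP/TN splits vary binomially across
        replicates — the variation sensitivity and specificity estimates
        actually have.  "outcome_group" keeps the four severity strata
        separate, which pins the TP, FN and FP counts in every replicate
        and collapses the bootstrap variance of sensitivity (and most of
        specificity's) to zero when women carry at most one cancer exam;
        it is retained for variance decomposition, not for inference.

    Returns
    -------
    BootstrapSummary, or dict[str, BootstrapSummary] when the statistic
    returns a mapping.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    for col in ("woman_id", "group"):
        if col not in exams.columns:
            raise ValueError(f"exams must carry a {col!r} column")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if resampling_strata not in ("cancer_status", "outcome_group"):
        raise ValueError(f"unknown resampling_strata {resampling_strata!r}")
    order, starts, counts, strata = _patient_blocks(exams)
    if resampling_strata == "cancer_status":
        strata = (strata >= 2).astype(int)  # {FN, TP} women vs {FP, TN} women
    exams_sorted = exams.iloc[order].reset_index(drop=True)

    point = statistic(exams_sorted)
    named = isinstance(point, Mapping)
    names = list(point.keys()) if named else [None]
    point_vals = dict(point) if named else {None: float(point)}

    stratum_members = [np.flatnonzero(strata == r) for r in range(len(SEVERITY_ORDER))]
    stratum_members = [m for m in stratum_members if m.size > 0]

    reps = {name: np.full(B, np.nan) for name in names}
    n_missing = 0
    for b in range(B):
        picked = [m[rng.integers(0, m.size, size=m.size)] for m in stratum_members]
        women = np.concatenate(picked)
        idx = _expand_ranges(starts[women], counts[women])
        resample = exams_sorted.iloc[idx]
        try:
            val = statistic(resample)
        except (ValueError, ZeroDivisionError):
            n_missing += 1
            continue
        if named:
            for name in names:
                reps[name][b] = val[name]
        else:
            reps[None][b] = float(val)
            if np.isnan(reps[None][b]):
                n_missing += 1

    if named:
        n_missing = int(max(np.isnan(reps[name]).sum() for name in names))
    if n_missing > max_missing_frac * B:
        raise RuntimeError(
            f"statistic undefined on {n_missing}/{B} bootstrap replicates"
        )

    def summarize(name) -> BootstrapSummary:
        r = reps[name]
        good = r[~np.isnan(r)]
        if good.size == 0:
            lo = hi = np.nan
        else:
            lo, hi = np.percentile(good, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return BootstrapSummary(
            estimate=point_vals[name],
            ci_low=float(lo),
            ci_high=float(hi),
            n_replicates=B,
            replicates=r,
            n_missing=int(B - good.size),
        )

    if named:
        return {name: summarize(name) for name in names}
    return summarize(None)


def paired_difference_test(replicates_a, replicates_b=None, *, diffs=None) -> float:
    """Two-sided percentile bootstrap p-value for a paired difference.

    The two replicate vectors must come from the same resamples (e.g. a
    mapping-valued statistic in :func:`stratified_patient_bootstrap`).
    p = 2 * min(prop(diff <= 0), prop(diff >= 0)), floored at 2/(B+1) and
    capped at 1; symmetric in A and B.
    """
    if diffs is None:
        a = np.asarray(replicates_a, dtype=float)
        if replicates_b is None:
            diffs = a
        else:
            b = np.asarray(replicates_b, dtype=float)
            if a.shape != b.shape:
                raise ValueError(
                    f"paired replicate vectors differ in length: {a.shape} vs {b.shape}"
                )
            diffs = a - b
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no usable replicate differences")
    p = 2.0 * min(np.mean(d <= 0), np.mean(d >= 0))
    return float(min(1.0, max(p, 2.0 / (d.size + 1))))


@dataclass(frozen=True)
class SubgroupSpec:
    """A covariate to stratify performance by."""

    variable: str
    levels: tuple = ()
    missing_policy: str = "drop"  # or "own_level"

    def __post_init__(self):
        if self.missing_policy not in ("drop", "own_level"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


def subgroup_evaluate(
    exams: pd.DataFrame,
    spec: SubgroupSpec,
    statistics: Mapping[str, Callable[[pd.DataFrame], float]],
    *,
    B: int = 1000,
    seed: int | None = None,
    comparisons: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Bootstrap each statistic within every level of a covariate.

    Within a level, all statistics are computed on the same patient-level
    resamples, so ``comparisons`` — pairs of statistic names, e.g.
    ``[("model_sens", "reader_sens")]`` — are paired tests; their p-values
    are reported on the first-named statistic's rows as ``p_vs_<other>``.

    Returns a long-format frame: variable, level, statistic, estimate,
    ci_low, ci_high, n_exams (+ any p-value columns).
    """
    if spec.variable not in exams.columns:
        raise ValueError(f"covariate {spec.variable!r} not in examination table")
    col = exams[spec.variable]
    missing = col.isna()
    levels = list(spec.levels) if spec.levels else sorted(
        col.dropna().unique().tolist(), key=str
    )
    frames = []
    rng = np.random.default_rng(seed)
    level_iter: list[tuple[object, pd.DataFrame]] = [
        (lv, exams[col == lv]) for lv in levels
    ]
    if spec.missing_policy == "own_level" and missing.any():
        level_iter.append(("missing", exams[missing]))

    def bundle(sub: pd.DataFrame) -> Mapping[str, float]:
        return {name: f(sub) for name, f in statistics.items()}

    for lv, sub in level_iter:
        if len(sub) == 0:
            continue
        summaries = stratified_patient_bootstrap(
            sub, bundle, B=B, seed=rng, max_missing_frac=1.0
        )
        pvals: dict[str, float] = {}
        for a, b in comparisons:
            pvals[a] = paired_difference_test(
                summaries[a].replicates, summaries[b].replicates
            )
        for name, s in summaries.items():
            row = {
                "variable": spec.variable,
                "level": lv,
                "statistic": name,
                "estimate": s.estimate,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "n_exams": len(sub),
                "n_missing_replicates": s.n_missing,
            }
            for a, b in comparisons:
                if name == a:
                    row[f"p_vs_{b}"] = pvals[a]
            frames.append(row)
    return pd.DataFrame(frames)
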