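"""Designed subsampling with inverse-probability-of-selection weights.

Rare outcome groups (cancers, reader false positives) are oversampled so the
analysis set keeps them at workable sizes, and each drawn examination carries
the reciprocal of its group's realized sampling fraction as a weight.
Weighted statistics on the subsample then estimate the corresponding
full-cohort quantities; with weights formed from the realized counts the
weighted group totals reproduce the full-cohort group counts exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import GROUPS


@dataclass(frozen=True)
class SamplingDesign:
    """Per-group sampling fractions and their inverse-probability weights."""

    fractions: dict[str, float]
    weights: dict[str, float] = field(init=False)

    def __post_init__(self):
        for g, f in self.fractions.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"sampling fraction for {g} must be in (0, 1], got {f}")
        object.__setattr__(
            self, "weights", {g: 1.0 / f for g, f in self.fractions.items()}
        )

    def to_json(self, seed: int | None = None) -> str:
        payload = {"fractions": self.fractions, "weights": self.weights}
        if seed is not None:
            payload["seed"] = seed
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SamplingDesign":
        return cls(fractions=json.loads(text)["fractions"])


def empirical_fractions(
    subset_counts: Mapping[str, int], full_counts: Mapping[str, int]
) -> SamplingDesign:
    """Sampling design implied by realized subset counts over full counts.

    fraction[g] = subset_counts[g] / full_counts[g]; weight[g] is its
    reciprocal.  Groups absent from ``subset_counts`` (or with zero full
    count) are omitted from the design.
    """
    fractions = {}
    for g, n_full in full_counts.items():
        if n_full == 0:
            continue
        n_sub = subset_counts.get(g, 0)
        if n_sub <= 0:
            raise ValueError(f"zero examinations sampled from nonempty group {g}: weight undefined")
        if n_sub > n_full:
            raise ValueError(f"subset count {n_sub} exceeds full count {n_full} for group {g}")
        fractions[g] = n_sub / n_full
    return SamplingDesign(fractions=fractions)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def draw_designed_subsample(
    exams: pd.DataFrame,
    target_fractions: Mapping[str, float],
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, SamplingDesign]:
    """Draw a designed subsample and attach inverse-probability weights.

    Within each outcome group, ``round(fraction * count)`` examinations
    (half away from zero, minimum 1 in a nonempty group) are drawn uniformly
    without replacement.  Weights come from :func:`empirical_fractions` on
    the realized counts, so weighted group totals reproduce the full counts
    exactly.

    Parameters
    ----------
    exams : DataFrame
        Examination table carrying a ``group`` column
        (see :func:`mammoeval.cohort.add_outcome_groups`).
    target_fractions : mapping
        Group label -> sampling fraction in (0, 1].  Groups not present in
        the data are ignored.
    seed : int or numpy Generator
        Source of randomness; the draw is reproducible under a fixed seed.

    Returns
    -------
    (DataFrame, SamplingDesign)
        The subsample with a ``weight`` column, and the realized design.
    """
    if "group" not in exams.columns:
        raise ValueError("exams must carry a 'group' column; run add_outcome_groups first")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    full_counts: dict[str, int] = {}
    pieces = []
    for g in GROUPS:
        members = np.flatnonzero((exams["group"] == g).to_numpy())
        n_full = len(members)
        if n_full == 0:
            continue
        full_counts[g] = n_full
        frac = float(target_fractions.get(g, 1.0))
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"target fraction for {g} must be in (0, 1], got {frac}")
        n_draw = max(1, _round_half_away(frac * n_full))
        if n_draw == 0:
            raise ValueError(f"fraction {frac} draws no examinations from nonempty group {g}")
        chosen = rng.choice(members, size=min(n_draw, n_full), replace=False)
        pieces.append(np.sort(chosen))

    taken = np.concatenate(pieces)
    sub = exams.iloc[taken].copy()
    subset_counts = sub["group"].value_counts().to_dict()
    design = empirical_fractions(subset_counts, full_counts)
    sub["weight"] = sub["group"].map(design.weights).astype(float)
    return sub.reset_index(drop=True), design


def weighted_group_totals(sample: pd.DataFrame) -> dict[str, float]:
    """Sum of weights per outcome group; estimates full-cohort group counts.

    The returned mapping carries one entry per group present plus
    ``"total"``, the estimated full-cohort size.
    """
    if "weight" not in sample.columns or "group" not in sample.columns:
        raise ValueError("sample must carry 'group' and 'weight' columns")
    totals = sample.groupby("group", observed=True)["weight"].sum().to_dict()
    totals["total"] = float(sample["weight"].sum())
    return totals
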