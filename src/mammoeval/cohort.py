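"""Outcome-group partitioning of screening examinations.

A screening mammogram is *screen positive* when the interpreting
radiologist's BI-RADS assessment is 0 (incomplete, recall), 3, 4 or 5
(increasing suspicion), and negative for BI-RADS 1 or 2.  Crossing the
reader call with whether a breast cancer was diagnosed within 12 months of
the examination partitions a cohort into the four outcome groups that drive
both the sampling design and the bootstrap strata:

====== ================ =====================
group  reader call      cancer within 12 mo
====== ================ =====================
TP     positive         yes
FP     positive         no
FN     negative         yes
TN     negative         no
====== ================ =====================
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Valid BI-RADS categories for a screening assessment.
BIRADS_CATEGORIES: frozenset[int] = frozenset(range(6))

#: BI-RADS categories counted as a positive (recall) screening call.
POSITIVE_BIRADS: frozenset[int] = frozenset({0, 3, 4, 5})

#: Outcome-group labels in canonical order.
GROUPS: tuple[str, ...] = ("TP", "FP", "FN", "TN")

#: Groups containing screen-positive examinations.
POSITIVE_GROUPS: frozenset[str] = frozenset({"TP", "FP"})


def screen_positive(birads):
    """Return whether a BI-RADS assessment is a positive screening call.

    Parameters
    ----------
    birads : int or array-like of int
        BI-RADS category in {0, 1, 2, 3, 4, 5}.

    Returns
    -------
    bool or ndarray of bool
        True for BI-RADS 0, 3, 4 or 5; False for 1 or 2.  Scalar in,
        scalar out.

    Raises
    ------
    ValueError
        If any value is not one of the six BI-RADS categories; the message
        names the offending value.
    """
    arr = np.asarray(birads)
    scalar = arr.ndim == 0
    flat = np.atleast_1d(arr)
    if flat.dtype.kind not in "iu":
        # reject floats that are not whole numbers, strings, etc.
        try:
            as_int = flat.astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = next(
                (v for v in flat.ravel() if not str(v).lstrip("-").isdigit()),
                flat.ravel()[0],
            )
            raise ValueError(f"unknown BI-RADS category: {bad!r}") from exc
        if flat.dtype.kind == "f" and not np.all(as_int == flat):
            bad = flat[as_int != flat][0]
            raise ValueError(f"unknown BI-RADS category: {bad!r}")
        flat = as_int
    valid = np.isin(flat, list(BIRADS_CATEGORIES))
    if not valid.all():
        bad = flat[~valid].ravel()[0]
        raise ValueError(f"unknown BI-RADS category: {bad!r}")
    pos = np.isin(flat, list(POSITIVE_BIRADS))
    return bool(pos[0]) if scalar else pos.reshape(arr.shape)


def classify_exam(birads: int, cancer_12mo: bool) -> str:
    """Classify one examination into its TP/FP/FN/TN outcome group."""
    pos = screen_positive(birads)
    if pos:
        return "TP" if cancer_12mo else "FP"
    return "FN" if cancer_12mo else "TN"


def classify_exams(birads, cancer_12mo) -> np.ndarray:
    """Vectorised :func:`classify_exam`; returns an array of group labels."""
    pos = np.atleast_1d(screen_positive(birads))
    cancer = np.atleast_1d(np.asarray(cancer_12mo, dtype=bool))
    if pos.shape != cancer.shape:
        raise ValueError(
            f"birads and cancer_12mo lengths differ: {pos.shape} vs {cancer.shape}"
        )
    out = np.where(pos, np.where(cancer, "TP", "FP"), np.where(cancer, "FN", "TN"))
    return out.astype("<U2")


def add_outcome_groups(exams: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of an examination table with a ``group`` column."""
    out = exams.copy()
    out["group"] = classify_exams(
        exams["birads"].to_numpy(), exams["cancer_12mo"].to_numpy()
    )
    return out


def partition_cohort(exams: pd.DataFrame) -> dict[str, list]:
    """Partition an examination table into the four outcome groups.

    Parameters
    ----------
    exams : DataFrame
        Must carry ``exam_id``, ``birads`` and ``cancer_12mo`` columns.

    Returns
    -------
    dict
        Mapping group label -> list of exam ids.  Every exam appears in
        exactly one group; groups with no exams map to an empty list.
    """
    if len(exams) == 0:
        raise ValueError("cannot partition an empty cohort")
    groups = classify_exams(exams["birads"].to_numpy(), exams["cancer_12mo"].to_numpy())
    ids = exams["exam_id"].to_numpy()
    return {g: list(ids[groups == g]) for g in GROUPS}


def group_counts(exams_or_partition) -> dict[str, int]:
    """Outcome-group counts, from an exam table or a partition mapping."""
    if isinstance(exams_or_partition, Mapping):
        return {g: len(exams_or_partition.get(g, [])) for g in GROUPS}
    part = partition_cohort(exams_or_partition)
    return {g: len(part[g]) for g in GROUPS}
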