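"""Strict CSV readers/writers for examination and score tables.

Missing covariates are encoded as empty fields.  Readers validate schema
and value ranges and report offending rows; ``read(write(x)) == x`` on
valid tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

EXAM_COLUMNS = [
    "woman_id", "exam_id", "exam_seq", "birads", "cancer_12mo", "cancer_type",
    "age_years", "bmi", "density", "race_ethnicity", "prior_breast_cancer",
]
SCORE_COLUMNS = ["exam_id", "model_id", "side", "score"]

CANCER_TYPES = {"invasive", "dcis", "none"}
DENSITY_LEVELS = {"dense", "nondense"}
RACE_LEVELS = {"asian", "black", "hispanic", "white", "other"}
SIDES = {"left", "right"}

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _rows(mask: np.ndarray, limit: int = 5) -> str:
    """1-based data row numbers (excluding header) for an offence mask."""
    idx = np.flatnonzero(mask) + 1
    head = ", ".join(map(str, idx[:limit]))
    more = f" (+{idx.size - limit} more)" if idx.size > limit else ""
    return head + more


def _parse_bool(col: pd.Series, name: str, allow_missing: bool = False) -> pd.Series:
    s = col.astype("string").str.strip().str.lower()
    missing = s.isna() | (s == "")
    bad = ~missing & ~s.isin(_BOOL_MAP)
    if bad.any():
        raise ValueError(f"column {name!r}: non-boolean values at rows {_rows(bad.to_numpy())}")
    if missing.any() and not allow_missing:
        raise ValueError(f"column {name!r}: missing values at rows {_rows(missing.to_numpy())}")
    out = s.map(_BOOL_MAP)
    return out.astype(object) if allow_missing else out.astype(bool)


def read_exam_table(path) -> pd.DataFrame:
    """Read and validate an examination table CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in EXAM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"exam table missing required columns: {missing_cols}")
    out = pd.DataFrame(index=df.index)
    out["woman_id"] = df["woman_id"]
    out["exam_id"] = df["exam_id"]

    dup = df.duplicated(subset=["woman_id", "exam_id"]).to_numpy()
    if dup.any():
        raise ValueError(f"duplicate (woman_id, exam_id) pairs at rows {_rows(dup)}")

    seq = pd.to_numeric(df["exam_seq"], errors="coerce")
    if seq.isna().any():
        raise ValueError(f"column 'exam_seq': non-integer at rows {_rows(seq.isna().to_numpy())}")
    out["exam_seq"] = seq.astype(int)

    birads = pd.to_numeric(df["birads"], errors="coerce")
    bad = birads.isna() | ~birads.isin(range(6))
    if bad.any():
        vals = df.loc[bad, "birads"].unique().tolist()
        raise ValueError(
            f"column 'birads': values outside BI-RADS 0-5 ({vals}) at rows {_rows(bad.to_numpy())}"
        )
    out["birads"] = birads.astype(int)

    out["cancer_12mo"] = _parse_bool(df["cancer_12mo"], "cancer_12mo")

    ctype = df["cancer_type"].str.strip().str.lower()
    bad = ~ctype.isin(CANCER_TYPES)
    if bad.any():
        raise ValueError(f"column 'cancer_type': unknown values at rows {_rows(bad.to_numpy())}")
    out["cancer_type"] = ctype
    inconsistent = (out["cancer_type"] == "none") != ~out["cancer_12mo"]
    if inconsistent.any():
        raise ValueError(
            "cancer_type and cancer_12mo inconsistent at rows "
            f"{_rows(inconsistent.to_numpy())}"
        )

    for col in ("age_years", "bmi"):
        num = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = num.isna() & (df[col].str.strip() != "")
        if bad.any():
            raise ValueError(f"column {col!r}: non-numeric at rows {_rows(bad.to_numpy())}")
        out[col] = num

    for col, levels in (("density", DENSITY_LEVELS), ("race_ethnicity", RACE_LEVELS)):
        vals = df[col].str.strip().str.lower()
        empty = vals == ""
        bad = ~empty & ~vals.isin(levels)
        if bad.any():
            raise ValueError(f"column {col!r}: unknown levels at rows {_rows(bad.to_numpy())}")
        out[col] = vals.where(~empty, other=pd.NA)

    out["prior_breast_cancer"] = _parse_bool(
        df["prior_breast_cancer"], "prior_breast_cancer", allow_missing=True
    )
    if "weight" in df.columns:
        out["weight"] = pd.to_numeric(df["weight"])
    return out


def write_exam_table(exams: pd.DataFrame, path) -> None:
    """Write an examination table CSV with missing covariates as empty fields."""
    cols = EXAM_COLUMNS + (["weight"] if "weight" in exams.columns else [])
    out = exams[cols].copy()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, na_rep="")


def read_score_table(path) -> pd.DataFrame:
    """Read and validate a per-breast model score table CSV."""
    df = pd.read_csv(path, dtype={"exam_id": str, "model_id": str, "side": str})
    missing_cols = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"score table missing required columns: {missing_cols}")
    side = df["side"].str.strip().str.lower()
    bad = ~side.isin(SIDES)
    if bad.any():
        raise ValueError(f"column 'side': values not left/right at rows {_rows(bad.to_numpy())}")
    score = pd.to_numeric(df["score"], errors="coerce")
    bad = score.isna() | (score < 0) | (score > 1)
    if bad.any():
        raise ValueError(
            f"column 'score': values outside [0, 1] at rows {_rows(bad.to_numpy())}"
        )
    dup = df.duplicated(subset=["exam_id", "model_id", "side"]).to_numpy()
    if dup.any():
        raise ValueError(f"duplicate (exam_id, model_id, side) rows at {_rows(dup)}")
    return pd.DataFrame(
        {"exam_id": df["exam_id"], "model_id": df["model_id"], "side": side, "score": score}
    )


def write_score_table(panel: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    panel[SCORE_COLUMNS].to_csv(path, index=False)
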