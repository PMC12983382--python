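"""Cohort table schema, validation and delimited-text I/O.

A cohort is a pandas DataFrame with one row per patient. The column
dictionary below is the package-wide contract; ``validate_cohort`` reports
every malformed column rather than stopping at the first.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COLUMN_DICTIONARY",
    "CATEGORICAL_LEVELS",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
]

COLUMN_DICTIONARY: dict[str, str] = {
    "patient_id": "unique case label",
    "age": "age at diagnosis, years",
    "age_group": "age bracket: <=30, 31-40, 41-50, 51-60, >60",
    "gender": "male / female",
    "site": "primary tumor subsite (6 oral-cavity levels)",
    "c_stage": "clinical AJCC stage, 1-4",
    "p_stage": "pathological AJCC stage, 1-4",
    "c_n": "clinical nodal status, N0-N3",
    "p_n": "pathological nodal status, N0-N3",
    "grade": "WHO differentiation: well / moderate / poor",
    "wpoi5": "worst pattern of invasion grade 5: present / absent",
    "pni": "perineural invasion: present / absent",
    "til_percent": "%stromal TILs, mean of 5 fields, 0-100",
    "til_category": "low (<= cohort median) / high (> median)",
    "doi": "depth of invasion, cm; may be missing",
    "survival_months": "follow-up time, months",
    "event": "1 = death observed, 0 = censored",
    "bg_score": "modified BG score 0-3 (appended by scoring)",
    "bg_risk": "low (score 0-1) / high (score 2-3) (appended by scoring)",
}

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("<=30", "31-40", "41-50", "51-60", ">60"),
    "gender": ("male", "female"),
    "site": (
        "lateral_tongue",
        "upper_alveolus_gingiva",
        "lower_alveolus_gingiva",
        "retromolar",
        "buccal_mucosa",
        "hard_palate",
    ),
    "c_stage": ("1", "2", "3", "4"),
    "p_stage": ("1", "2", "3", "4"),
    "c_n": ("N0", "N1", "N2", "N3"),
    "p_n": ("N0", "N1", "N2", "N3"),
    "grade": ("well", "moderate", "poor"),
    "wpoi5": ("absent", "present"),
    "pni": ("absent", "present"),
    "til_category": ("low", "high"),
    "bg_risk": ("low", "high"),
}

_REQUIRED = ("patient_id", "gender", "wpoi5", "pni")


def validate_cohort(cohort: pd.DataFrame, *, require_survival: bool = False) -> None:
    """Raise ValueError listing every column-level problem found."""
    problems: list[str] = []
    for col in _REQUIRED:
        if col not in cohort.columns:
            problems.append(f"{col}: required column missing")
    if require_survival:
        for col in ("survival_months", "event"):
            if col not in cohort.columns:
                problems.append(f"{col}: required for survival analysis")
    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in cohort.columns:
            continue
        vals = cohort[col].dropna().astype(str)
        bad = sorted(set(vals) - set(levels))
        if bad:
            problems.append(f"{col}: unrecognized level(s) {bad}; expected {levels}")
    if "til_percent" in cohort.columns:
        v = pd.to_numeric(cohort["til_percent"], errors="coerce")
        if ((v < 0) | (v > 100)).any():
            problems.append("til_percent: values outside [0, 100]")
    if "survival_months" in cohort.columns:
        v = pd.to_numeric(cohort["survival_months"], errors="coerce")
        if (v < 0).any():
            problems.append("survival_months: negative values")
    if "event" in cohort.columns:
        ev = set(pd.to_numeric(cohort["event"], errors="coerce").dropna())
        if not ev <= {0, 1}:
            problems.append(f"event: values {sorted(ev - {0, 1})} not in {{0, 1}}")
    if "patient_id" in cohort.columns and cohort["patient_id"].duplicated().any():
        problems.append("patient_id: duplicate labels")
    if problems:
        raise ValueError("invalid cohort table:\n  " + "\n  ".join(problems))


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in CATEGORICAL_LEVELS})
    validate_cohort(df)
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    # fixed float formatting keeps exports byte-identical across runs
    cohort.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def event_split(cohort: pd.DataFrame) -> tuple[int, int]:
    """(deaths, censored) counts."""
    e = pd.to_numeric(cohort["event"], errors="coerce")
    return int((e == 1).sum()), int((e == 0).sum())
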