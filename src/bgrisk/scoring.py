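"""Modified Brandwein-Gensler (BG) score and risk categorization.

The modified BG score replaces the original model's qualitative lymphocytic
host response with the quantitative %stromal-TIL dichotomy and drops WPOI
sub-grades, leaving three binary components scored 1 when adverse:

    score = [WPOI-5 present] + [PNI present] + [TILs low]

Score 0-1 is the low-risk category, 2-3 high-risk. A weak lymphocytic
response (low TILs) is the adverse state, consistent with the original BG
treatment of lymphocytic response; ``TIL_LOW_IS_ADVERSE`` makes the coding
explicit and testable in the opposite direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ModifiedBGResult",
    "modified_bg_score",
    "risk_category",
    "score_cohort",
    "TIL_LOW_IS_ADVERSE",
]

TIL_LOW_IS_ADVERSE = True

_PRESENT_ABSENT = {"present": True, "absent": False}
_LOW_HIGH = {"low", "high"}


@dataclass(frozen=True)
class ModifiedBGResult:
    score: int  # 0..3
    risk: str  # 'low' | 'high'
    components: tuple[int, int, int]  # (wpoi5, pni, til) indicator values


def _component(name: str, value: str | None, mapping: dict[str, bool]) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        raise ValueError(f"missing score component: {name}")
    v = str(value).strip().lower()
    if v not in mapping:
        raise ValueError(f"invalid value {value!r} for component {name}")
    return mapping[v]


def modified_bg_score(
    wpoi5: str,
    pni: str,
    til_category: str,
    *,
    til_low_is_adverse: bool = TIL_LOW_IS_ADVERSE,
) -> ModifiedBGResult:
    """Sum the three binary indicators and attach the risk category.

    ``wpoi5`` and ``pni`` are 'present'/'absent'; ``til_category`` is
    'low'/'high' as produced by the cohort median split.
    """
    w = int(_component("wpoi5", wpoi5, _PRESENT_ABSENT))
    p = int(_component("pni", pni, _PRESENT_ABSENT))
    cat = _component("til_category", til_category, {"low": True, "high": False})
    t = int(cat if til_low_is_adverse else not cat)
    score = w + p + t
    return ModifiedBGResult(score=score, risk=risk_category(score), components=(w, p, t))


def risk_category(score: int) -> str:
    """Map a modified BG score to its risk tier: 0-1 low, 2-3 high."""
    if score not in (0, 1, 2, 3):
        raise ValueError(f"modified BG score must be in 0..3, got {score!r}")
    return "low" if score <= 1 else "high"


def score_cohort(
    cohort: pd.DataFrame, *, til_low_is_adverse: bool = TIL_LOW_IS_ADVERSE
) -> pd.DataFrame:
    """Append ``bg_score`` and ``bg_risk`` columns to a cohort table.

    Requires ``wpoi5``, ``pni`` and ``til_category`` columns; raises naming
    the missing component otherwise.
    """
    for col in ("wpoi5", "pni", "til_category"):
        if col not in cohort.columns:
            raise ValueError(f"missing score component column: {col}")
    out = cohort.copy()
    results = [
        modified_bg_score(r.wpoi5, r.pni, r.til_category,
                          til_low_is_adverse=til_low_is_adverse)
        for r in cohort.itertuples()
    ]
    out["bg_score"] = [r.score for r in results]
    out["bg_risk"] = [r.risk for r in results]
    return out
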