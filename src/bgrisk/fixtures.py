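"""Packaged inputs transcribed from the source study's printed tables.

The study deposits no per-patient data, but its published cross-tabulations
(clinical variables against the modified BG score and against the risk
categories) and its per-group (n, mean, SD) summaries of %stromal TILs and
depth of invasion are complete, so the association statistics can be
recomputed exactly from these fixtures. One misprinted cell (a site-level
DOI mean printed as .075 with SE 0.25) is transcribed as 0.75; three
misprinted row totals in the published tables are ignored in favour of the
cell counts, which sum consistently.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import ContingencyTable, GroupSummary

__all__ = [
    "load_score_crosstabs",
    "load_risk_crosstabs",
    "load_group_summaries",
    "study_score_distribution",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("bgrisk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _tables(df: pd.DataFrame, value_cols: list[str]) -> dict[str, ContingencyTable]:
    out = {}
    for var, grp in df.groupby("variable", sort=False):
        out[var] = ContingencyTable(
            counts=grp[value_cols].to_numpy(),
            row_labels=tuple(grp["level"].astype(str)),
            col_labels=tuple(value_cols),
        )
    return out


def load_score_crosstabs() -> dict[str, ContingencyTable]:
    """Variable -> (levels x modified BG score 0-3) contingency table."""
    return _tables(
        _read("study_score_crosstabs.csv"),
        ["score0", "score1", "score2", "score3"],
    )


def load_risk_crosstabs() -> dict[str, ContingencyTable]:
    """Variable -> (levels x low/high risk) contingency table."""
    return _tables(
        _read("study_risk_crosstabs.csv"), ["low_risk", "high_risk"]
    )


def load_group_summaries() -> dict[tuple[str, str], list[GroupSummary]]:
    """(outcome, variable) -> ordered per-level GroupSummary list."""
    df = _read("study_group_summaries.csv")
    out: dict[tuple[str, str], list[GroupSummary]] = {}
    for (outcome, var), grp in df.groupby(["outcome", "variable"], sort=False):
        out[(outcome, var)] = [
            GroupSummary(n=int(r.n), mean=float(r.mean), sd=float(r.sd))
            for r in grp.itertuples()
        ]
    return out


def study_score_distribution() -> dict[int, int]:
    """Published modified-BG-score distribution (column totals: 19/20/11/8)."""
    tab = load_score_crosstabs()["gender"].counts  # any variable; same margins
    totals = tab.sum(axis=0).astype(int)
    return {s: int(t) for s, t in enumerate(totals)}
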