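"""End-to-end orchestration: cohort in, scored cohort + report tables out.

The report bundle mirrors the structure of the source study's results:

* a cohort-characteristics table (level counts per categorical variable);
* a continuous-variable association table (%stromal TILs and DOI against the
  clinical groupings, one-way ANOVA), plus the TIL-DOI correlation and the
  ROC of TILs against the survival endpoint;
* a categorical association table of every clinical variable against the
  modified BG score and against the risk categories — Pearson chi-square and
  the linear-by-linear trend statistic are reported side by side with
  explicit method labels (a single unlabelled p column would conflate them);
* Kaplan-Meier restricted means and (pairwise) log-rank tests by score and
  by risk category.

All numbers are carried at full precision; rounding happens only in the
presentation helpers (p-values to 3 decimals, with values below 0.0005
printed as "0.000").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures, scoring, stats, survival
from .cohort import read_cohort, validate_cohort, write_cohort
from .synthetic import SyntheticParams, generate_cohort
from .tilquant import (
    DEFAULT_FIELDS_PER_CASE,
    FieldAnnotation,
    case_til_percentage,
    dichotomize_by_median,
    read_mask,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "characteristics_table",
    "continuous_association_report",
    "categorical_association_report",
    "survival_report",
    "study_association_report",
    "quantify_tils_from_manifest",
    "format_p",
]

log = logging.getLogger("bgrisk")

# clinical groupings cross-tabulated against score/risk, and whether their
# levels carry a natural order (trend test applicable)
_CATEGORICAL_VARS: dict[str, bool] = {
    "age_group": True,
    "gender": False,
    "site": False,
    "p_stage": True,
    "p_n": True,
    "c_stage": True,
    "c_n": True,
    "grade": True,
}


@dataclass(frozen=True)
class PipelineConfig:
    """One-command pipeline settings; exactly one input mode is active."""

    mode: str  # 'cohort_csv' | 'synthetic'
    output_dir: Path
    cohort_csv: Path | None = None
    mask_manifest: Path | None = None
    seed: int | None = None
    n_patients: int = 58
    til_low_is_adverse: bool = scoring.TIL_LOW_IS_ADVERSE

    def __post_init__(self) -> None:
        if self.mode not in ("cohort_csv", "synthetic"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "cohort_csv" and self.cohort_csv is None:
            raise ValueError("cohort_csv mode requires a cohort path")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires an explicit seed")


def format_p(p: float) -> str:
    return "0.000" if p < 0.0005 else f"{p:.3f}"


def quantify_tils_from_manifest(
    manifest_path: str | Path,
    *,
    min_fields: int = DEFAULT_FIELDS_PER_CASE,
) -> pd.DataFrame:
    """Compute per-case %stromal TILs from a mask manifest.

    The manifest is a CSV with columns ``case_id, field_id, stroma_path,
    til_path, exclusion_path`` (exclusion optional/empty), paths relative to
    the manifest location. Cases with missing mask files are flagged and
    excluded with a warning rather than aborting the run.
    """
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    root = manifest_path.parent
    rows = []
    for case_id, grp in man.groupby("case_id", sort=False):
        try:
            fields = []
            for r in grp.itertuples():
                excl = getattr(r, "exclusion_path", None)
                fields.append(
                    FieldAnnotation(
                        field_id=str(r.field_id),
                        stroma_mask=read_mask(root / r.stroma_path),
                        til_mask=read_mask(root / r.til_path),
                        exclusion_mask=(
                            None
                            if excl is None or pd.isna(excl) or excl == ""
                            else read_mask(root / excl)
                        ),
                    )
                )
            meas = case_til_percentage(str(case_id), fields, min_fields=min_fields)
        except (FileNotFoundError, ValueError) as exc:
            warnings.warn(f"case {case_id!r} excluded from TIL stats: {exc}")
            continue
        row = {"case_id": meas.case_id, "til_percent": meas.case_percentage}
        row.update(
            {f"field_{i + 1}": p for i, p in enumerate(meas.field_percentages)}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def characteristics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Level counts for every categorical variable present, plus endpoints."""
    rows = []
    for var in list(_CATEGORICAL_VARS) + ["wpoi5", "pni", "bg_score", "bg_risk"]:
        if var not in cohort.columns:
            continue
        counts = cohort[var].astype(str).value_counts(sort=False)
        for level, n in counts.items():
            rows.append({"variable": var, "level": level, "n": int(n)})
    if "event" in cohort.columns:
        e = pd.to_numeric(cohort["event"], errors="coerce")
        rows.append({"variable": "endpoint", "level": "death", "n": int((e == 1).sum())})
        rows.append({"variable": "endpoint", "level": "censored", "n": int((e == 0).sum())})
    return pd.DataFrame(rows)


def _crosstab(cohort: pd.DataFrame, var: str, against: str) -> stats.ContingencyTable:
    ct = pd.crosstab(cohort[var].astype(str), cohort[against])
    return stats.ContingencyTable(
        counts=ct.to_numpy(),
        row_labels=tuple(map(str, ct.index)),
        col_labels=tuple(map(str, ct.columns)),
    )


def categorical_association_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Every clinical variable vs bg_score and vs bg_risk, both chi-square methods."""
    rows = []
    for against in ("bg_score", "bg_risk"):
        if against not in cohort.columns:
            continue
        for var, ordinal in _CATEGORICAL_VARS.items():
            if var not in cohort.columns:
                continue
            table = _crosstab(cohort, var, against)
            try:
                res = stats.pearson_chi_square(table)
                rows.append(_assoc_row(var, against, res))
            except ValueError as exc:
                log.warning("pearson %s x %s skipped: %s", var, against, exc)
            if ordinal:
                try:
                    res = stats.linear_by_linear(table)
                    rows.append(_assoc_row(var, against, res))
                except ValueError as exc:
                    log.warning("trend %s x %s skipped: %s", var, against, exc)
    return pd.DataFrame(rows)


def _assoc_row(var: str, against: str, res: stats.AssociationResult) -> dict:
    return {
        "variable": var,
        "against": against,
        "method": res.method,
        "statistic": res.statistic,
        "df": res.df,
        "p": res.p_value,
        "p_display": format_p(res.p_value),
    }


def continuous_association_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA of TILs and DOI across clinical groupings (raw data).

    Missing outcome values (e.g. DOI unavailable for some cases) are dropped
    pairwise; the number retained is logged per outcome.
    """
    rows = []
    groupings = list(_CATEGORICAL_VARS) + ["bg_score", "bg_risk"]
    for outcome in ("til_percent", "doi"):
        if outcome not in cohort.columns:
            continue
        vals = pd.to_numeric(cohort[outcome], errors="coerce")
        n_used = int(vals.notna().sum())
        if n_used < len(cohort):
            log.info(
                "%s: %d of %d cases with a value (missing dropped pairwise)",
                outcome, n_used, len(cohort),
            )
        for var in groupings:
            if var not in cohort.columns or var == outcome:
                continue
            sub = pd.DataFrame({"y": vals, "g": cohort[var].astype(str)}).dropna()
            groups = [grp["y"].to_numpy() for _, grp in sub.groupby("g", sort=False)]
            if len(groups) < 2 or sum(len(g) for g in groups) < len(groups) + 1:
                continue
            try:
                res = stats.one_way_anova_raw(groups)
            except ValueError as exc:
                log.warning("anova %s by %s skipped: %s", outcome, var, exc)
                continue
            row = _assoc_row(var, outcome, res)
            row["n"] = int(len(sub))
            rows.append(row)
    if {"til_percent", "doi"} <= set(cohort.columns):
        try:
            res = stats.pearson_correlation(
                pd.to_numeric(cohort["til_percent"], errors="coerce"),
                pd.to_numeric(cohort["doi"], errors="coerce"),
            )
            row = _assoc_row("doi", "til_percent", res)
            row["n"] = res.extra["n"]
            rows.append(row)
        except ValueError as exc:
            log.warning("TIL-DOI correlation skipped: %s", exc)
    if {"til_percent", "event"} <= set(cohort.columns):
        roc = stats.roc_auc(
            pd.to_numeric(cohort["til_percent"], errors="coerce"),
            pd.to_numeric(cohort["event"], errors="coerce").astype(int),
        )
        rows.append(
            {
                "variable": "event",
                "against": "til_percent",
                "method": "roc_auc",
                "statistic": roc.auc,
                "df": 0,
                "p": roc.p_value,
                "p_display": format_p(roc.p_value),
                "n": roc.n_positive + roc.n_negative,
            }
        )
    return pd.DataFrame(rows)


def survival_report(
    cohort: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(group restricted means, overall log-rank rows, pairwise p matrices).

    Restricted mean survival uses each group's largest observed time as its
    horizon — the convention behind the "mean survival" of standard packages.
    """
    t = pd.to_numeric(cohort["survival_months"], errors="coerce")
    e = pd.to_numeric(cohort["event"], errors="coerce").astype(int)
    mean_rows, test_rows, pairwise_frames = [], [], []
    for by in ("bg_score", "bg_risk"):
        if by not in cohort.columns:
            continue
        groups = {
            str(level): (t[idx].to_numpy(), e[idx].to_numpy())
            for level, idx in cohort.groupby(by, sort=True).groups.items()
        }
        for level, (gt, ge) in groups.items():
            mean_rows.append(
                {
                    "group_by": by,
                    "level": level,
                    "n": len(gt),
                    "events": int(ge.sum()),
                    "restricted_mean_months": survival.restricted_mean_survival(gt, ge),
                    "horizon_months": float(np.max(gt)),
                }
            )
        if len(groups) >= 2:
            res = survival.log_rank(groups)
            test_rows.append(
                {
                    "group_by": by,
                    "method": res.method,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                    "p_display": format_p(res.p_value),
                }
            )
            pw = survival.pairwise_log_rank(groups)
            pw.insert(0, "group_by", by)
            pairwise_frames.append(pw.reset_index(names="level"))
    pairwise = (
        pd.concat(pairwise_frames, ignore_index=True)
        if pairwise_frames
        else pd.DataFrame()
    )
    return pd.DataFrame(mean_rows), pd.DataFrame(test_rows), pairwise


def study_association_report() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute every association statistic from the packaged printed tables.

    Returns (categorical, continuous) tidy tables. Categorical rows carry both
    Pearson and (where levels are ordered) trend statistics for each variable
    against the score and against the risk categories; continuous rows are
    summary-statistics ANOVAs with the pooled total appended per block.
    """
    cat_rows = []
    for against, tables in (
        ("bg_score", fixtures.load_score_crosstabs()),
        ("bg_risk", fixtures.load_risk_crosstabs()),
    ):
        for var, table in tables.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sparse printed tables
                cat_rows.append(_assoc_row(var, against, stats.pearson_chi_square(table)))
                if _CATEGORICAL_VARS.get(var, False):
                    cat_rows.append(_assoc_row(var, against, stats.linear_by_linear(table)))
    cont_rows = []
    for (outcome, var), summaries in fixtures.load_group_summaries().items():
        res = stats.one_way_anova_summary(summaries)
        row = _assoc_row(var, outcome, res)
        total = stats.pooled_total_summary(summaries)
        row.update(n=total.n, pooled_mean=total.mean, pooled_sd=total.sd)
        cont_rows.append(row)
    return pd.DataFrame(cat_rows), pd.DataFrame(cont_rows)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle; returns the paths.

    Deterministic given the config (including seed): identical runs produce
    byte-identical files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.mode == "synthetic":
        cohort = generate_cohort(
            SyntheticParams(n_patients=config.n_patients, seed=config.seed)
        )
    else:
        cohort = read_cohort(config.cohort_csv)
        if config.mask_manifest is not None:
            tils = quantify_tils_from_manifest(config.mask_manifest)
            cohort = cohort.drop(
                columns=[c for c in ("til_percent",) if c in cohort], errors="ignore"
            ).merge(
                tils[["case_id", "til_percent"]],
                left_on="patient_id",
                right_on="case_id",
                how="left",
            ).drop(columns="case_id")
            n_missing = int(cohort["til_percent"].isna().sum())
            if n_missing:
                log.warning("%d case(s) without TIL measurement excluded", n_missing)
                cohort = cohort[cohort["til_percent"].notna()].reset_index(drop=True)
    if "til_category" not in cohort.columns:
        split = dichotomize_by_median(cohort["til_percent"])
        cohort["til_category"] = split.labels
        log.info("median %%stromal-TIL cutoff: %.4f", split.cutoff)
    if "bg_score" not in cohort.columns:
        cohort = scoring.score_cohort(
            cohort, til_low_is_adverse=config.til_low_is_adverse
        )
    validate_cohort(cohort)

    paths: dict[str, Path] = {}
    write_cohort(cohort, out / "cohort_scored.csv")
    paths["cohort"] = out / "cohort_scored.csv"
    _write(characteristics_table(cohort), out / "characteristics.csv")
    paths["characteristics"] = out / "characteristics.csv"
    _write(continuous_association_report(cohort), out / "continuous_assoc.csv")
    paths["continuous"] = out / "continuous_assoc.csv"
    _write(categorical_association_report(cohort), out / "categorical_assoc.csv")
    paths["categorical"] = out / "categorical_assoc.csv"
    if {"survival_months", "event"} <= set(cohort.columns):
        means, tests, pairwise = survival_report(cohort)
        _write(means, out / "survival_restricted_means.csv")
        _write(tests, out / "survival_logrank.csv")
        _write(pairwise, out / "survival_logrank_pairwise.csv")
        paths["survival"] = out / "survival_restricted_means.csv"
    return paths
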