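"""Association statistics for clinicopathological cross-tabulations and group summaries.

Implements the desk-scale statistics used to relate %stromal TILs, depth of
invasion and the modified Brandwein-Gensler score to clinical variables:

* Pearson chi-square on labelled contingency tables (no continuity correction);
* the linear-by-linear (ordinal trend) association statistic M2 = (N-1) r2;
* one-way fixed-effects ANOVA, both from raw observations and reconstructed
  from printed per-group (n, mean, SD) summaries;
* pooled-total reconstruction of a grand (n, mean, SD) from group summaries;
* Pearson correlation and rank-based ROC AUC with the Hanley-McNeil
  standard error.

Printed SDs are treated as sample SDs (n-1 denominator) throughout; that
convention reproduces published pooled totals exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "AssociationResult",
    "RocResult",
    "pearson_chi_square",
    "linear_by_linear",
    "one_way_anova_raw",
    "one_way_anova_summary",
    "pooled_total_summary",
    "pearson_correlation",
    "roc_auc",
]


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled R x C count matrix, optionally with ordinal scores per axis.

    Scores default to integer ranks 0, 1, 2, ... when a trend statistic is
    requested and none are supplied.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()
    row_scores: tuple[float, ...] | None = None
    col_scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() <= 0:
            raise ValueError("grand total must be positive")
        object.__setattr__(self, "counts", c.astype(float))
        if not self.row_labels:
            object.__setattr__(
                self, "row_labels", tuple(f"r{i}" for i in range(c.shape[0]))
            )
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels", tuple(f"c{j}" for j in range(c.shape[1]))
            )

    @property
    def n(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, sd) triple for one group; sd is the sample SD (n-1)."""

    n: int
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n == 1 and self.sd > 0:
            raise ValueError("sd requires n >= 2")


@dataclass(frozen=True)
class AssociationResult:
    method: str
    statistic: float
    df: int
    p_value: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    p_value: float
    orientation: str  # 'higher-predicts-positive' or 'lower-predicts-positive'
    n_positive: int
    n_negative: int


def _drop_empty_margins(table: ContingencyTable) -> ContingencyTable:
    c = table.counts
    keep_r = c.sum(axis=1) > 0
    keep_c = c.sum(axis=0) > 0
    if keep_r.all() and keep_c.all():
        return table
    dropped = [lab for lab, k in zip(table.row_labels, keep_r) if not k]
    dropped += [lab for lab, k in zip(table.col_labels, keep_c) if not k]
    warnings.warn(
        f"dropping empty level(s) {dropped}; degrees of freedom adjusted",
        stacklevel=3,
    )
    rs = table.row_scores
    cs = table.col_scores
    return ContingencyTable(
        counts=c[np.ix_(keep_r, keep_c)],
        row_labels=tuple(np.asarray(table.row_labels)[keep_r]),
        col_labels=tuple(np.asarray(table.col_labels)[keep_c]),
        row_scores=None if rs is None else tuple(np.asarray(rs)[keep_r]),
        col_scores=None if cs is None else tuple(np.asarray(cs)[keep_c]),
    )


def pearson_chi_square(table: ContingencyTable) -> AssociationResult:
    """Pearson chi-square test of independence, without continuity correction.

    Levels with a zero marginal total are dropped (with a warning) and the
    degrees of freedom adjusted. A warning is emitted when any expected count
    falls below 5; no exact test is substituted.
    """
    table = _drop_empty_margins(table)
    c = table.counts
    if c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and 2 non-empty columns")
    chi2, p, dof, expected = sps.chi2_contingency(c, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} cell(s) have expected count < 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    return AssociationResult("pearson_chi_square", float(chi2), int(dof), float(p))


def _axis_scores(scores, k: int) -> np.ndarray:
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, float)
    if len(s) != k:
        raise ValueError("scores length does not match table axis")
    if np.allclose(s, s[0]):
        raise ValueError("degenerate scores: all equal on an axis")
    return s


def linear_by_linear(table: ContingencyTable) -> AssociationResult:
    """Linear-by-linear (Mantel-Haenszel trend) test for ordinal x ordinal tables.

    With row scores u_i and column scores v_j, r is the Pearson correlation of
    (u, v) over the N expanded observations and M2 = (N - 1) r**2 is referred
    to chi-square on 1 df. Invariant to affine rescaling of either score set.
    """
    c = table.counts
    u = _axis_scores(table.row_scores, c.shape[0])
    v = _axis_scores(table.col_scores, c.shape[1])
    n = c.sum()
    mu = (c.sum(axis=1) * u).sum() / n
    mv = (c.sum(axis=0) * v).sum() / n
    cov = ((u[:, None] - mu) * (v[None, :] - mv) * c).sum()
    var_u = ((u - mu) ** 2 * c.sum(axis=1)).sum()
    var_v = ((v - mv) ** 2 * c.sum(axis=0)).sum()
    if var_u == 0 or var_v == 0:
        raise ValueError("degenerate scores: zero variance on an axis")
    r = cov / np.sqrt(var_u * var_v)
    m2 = (n - 1) * r * r
    p = float(sps.chi2.sf(m2, 1))
    return AssociationResult(
        "linear_by_linear", float(m2), 1, p, extra={"r": float(r)}
    )


def one_way_anova_raw(groups: Sequence[Sequence[float]]) -> AssociationResult:
    """Classical fixed-effects one-way ANOVA on raw observations."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    n = sum(a.size for a in arrays)
    k = len(arrays)
    if n < 3 or n - k < 1:
        raise ValueError("insufficient total observations for within-group df")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    return _anova_from_ss(ssb, ssw, k, n)


def _anova_from_ss(ssb: float, ssw: float, k: int, n: int) -> AssociationResult:
    df_b, df_w = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AssociationResult(
                "one_way_anova", 0.0, df_b, 1.0, extra={"df_within": df_w}
            )
        warnings.warn(
            "zero within-group variance with non-zero between-group variance; "
            "F unbounded, reporting p = 0",
            stacklevel=3,
        )
        return AssociationResult(
            "one_way_anova", float("inf"), df_b, 0.0, extra={"df_within": df_w}
        )
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AssociationResult(
        "one_way_anova", float(f), df_b, p, extra={"df_within": df_w}
    )


def one_way_anova_summary(summaries: Sequence[GroupSummary]) -> AssociationResult:
    """One-way ANOVA reconstructed from per-group (n, mean, sd) summaries.

    SSB = sum n_i (m_i - grand)^2, SSW = sum (n_i - 1) s_i^2; groups with
    n = 1 contribute nothing to SSW. Equivalent to ``one_way_anova_raw`` on
    any raw data realising the same summaries.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 group summaries")
    n = sum(s.n for s in summaries)
    k = len(summaries)
    if n < k + 1:
        raise ValueError("no within-group degrees of freedom (all n_i = 1?)")
    grand = sum(s.n * s.mean for s in summaries) / n
    ssb = sum(s.n * (s.mean - grand) ** 2 for s in summaries)
    ssw = sum((s.n - 1) * s.sd**2 for s in summaries)
    return _anova_from_ss(ssb, ssw, k, n)


def pooled_total_summary(summaries: Sequence[GroupSummary]) -> GroupSummary:
    """Pool group summaries into the (n, mean, sd) of the combined sample."""
    if not summaries:
        raise ValueError("need at least one summary")
    if len(summaries) == 1:
        return summaries[0]
    n = sum(s.n for s in summaries)
    if n < 2:
        raise ValueError("pooled n must be >= 2")
    mean = sum(s.n * s.mean for s in summaries) / n
    ssb = sum(s.n * (s.mean - mean) ** 2 for s in summaries)
    ssw = sum((s.n - 1) * s.sd**2 for s in summaries)
    return GroupSummary(n=n, mean=mean, sd=float(np.sqrt((ssb + ssw) / (n - 1))))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Pearson r with the two-sided t-based p-value; missing pairs dropped."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return AssociationResult(
        "pearson_correlation",
        float(res.statistic),
        int(x.size - 2),
        float(res.pvalue),
        extra={"n": int(x.size)},
    )


def roc_auc(predictor: Sequence[float], outcome: Sequence[int]) -> RocResult:
    """Rank (Mann-Whitney) AUC with mid-ranked ties and Hanley-McNeil SE.

    The AUC is oriented so that it is >= 0.5: if larger predictor values track
    the negative class the predictor is flipped and the orientation flag says
    so. The p-value tests AUC = 0.5 by a normal approximation.
    """
    x = np.asarray(predictor, float)
    y = np.asarray(outcome, int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must contain both classes, coded 0/1")
    auc = float(roc_auc_score(y, x))
    orientation = "higher-predicts-positive"
    if auc < 0.5:
        auc = 1.0 - auc
        orientation = "lower-predicts-positive"
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2 * sps.norm.sf(abs(auc - 0.5) / se))
    return RocResult(auc, se, min(p, 1.0), orientation, n1, n0)
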