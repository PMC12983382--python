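"""Synthetic cohorts and annotation-mask fields with known ground truth.

No per-patient data accompany the study this package reproduces, so every
downstream stage is exercised on simulated inputs that match the published
cohort structure: n = 58 oral squamous cell carcinoma patients, 48 M / 10 F,
WPOI-5 in 22/58, PNI in 15/58, right-skewed %stromal TILs with mean ~22.8
and SD ~12.7, and overall survival with multiplicative per-score-point
hazard calibrated to the printed group mean survivals (37/33/23/17 months
for scores 0-3).

Model choices (see docs/methods.md for rationale):

* %stromal TILs ~ log-normal, moment-matched to the target mean/SD and
  clipped to [0, 100] (the published mean 22.8 > median 18 implies right
  skew; the family itself is a modelling choice).
* survival time ~ exponential with hazard
  ``baseline_hazard * hazard_ratio_per_point ** bg_score``.
* censoring: administrative, C ~ Uniform(0, W) for every subject, with the
  window W solved so the expected censored fraction equals ``censor_rate``
  under the implied score mixture.
* covariates drawn independently from their marginals, except an optional
  score-nodal-status association knob for trend-test power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import scoring
from .tilquant import FieldAnnotation, dichotomize_by_median

__all__ = [
    "SyntheticParams",
    "STUDY_MARGINALS",
    "generate_cohort",
    "SyntheticField",
    "generate_field_masks",
]

# marginal counts of the published 58-patient cohort
_STUDY_COUNTS: dict[str, dict[str, int]] = {
    "age_group": {"<=30": 3, "31-40": 10, "41-50": 14, "51-60": 13, ">60": 18},
    "gender": {"male": 48, "female": 10},
    "site": {
        "lateral_tongue": 29,
        "upper_alveolus_gingiva": 2,
        "lower_alveolus_gingiva": 7,
        "retromolar": 1,
        "buccal_mucosa": 18,
        "hard_palate": 1,
    },
    "c_stage": {"1": 1, "2": 10, "3": 29, "4": 18},
    "p_stage": {"1": 2, "2": 10, "3": 18, "4": 28},
    "c_n": {"N0": 26, "N1": 22, "N2": 7, "N3": 3},
    "p_n": {"N0": 21, "N1": 19, "N2": 8, "N3": 10},
    "grade": {"well": 13, "moderate": 36, "poor": 9},
}

STUDY_MARGINALS: dict[str, dict[str, float]] = {
    var: {k: v / sum(cnt.values()) for k, v in cnt.items()}
    for var, cnt in _STUDY_COUNTS.items()
}

_AGE_BRACKETS = {
    "<=30": (28, 30),
    "31-40": (31, 40),
    "41-50": (41, 50),
    "51-60": (51, 60),
    ">60": (61, 76),
}


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults reproduce the published cohort structure."""

    n_patients: int = 58
    seed: int = 0
    p_wpoi5: float = 22 / 58
    p_pni: float = 15 / 58
    til_mean: float = 22.8  # target %stromal TILs mean
    til_sd: float = 12.7
    hazard_ratio_per_point: float = (37 / 17) ** (1 / 3)  # ~1.30 per score point
    baseline_hazard: float = 1 / 37.0  # per month, score-0 group
    censor_rate: float = 36 / 58  # expected censored fraction
    doi_mean: float = 1.13  # cm
    doi_sd: float = 0.67
    doi_missing_rate: float = 3 / 58
    score_node_association: float = 0.0  # >0 tilts pN upward with score
    covariate_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: STUDY_MARGINALS
    )

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in ("p_wpoi5", "p_pni", "censor_rate", "doi_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.hazard_ratio_per_point <= 0:
            raise ValueError("hazard_ratio_per_point must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.til_sd <= 0 or self.til_mean <= 0:
            raise ValueError("til_mean and til_sd must be positive")
        for var, marg in self.covariate_marginals.items():
            probs = np.array(list(marg.values()), float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"marginal for {var!r} must be non-negative and sum to 1 "
                    f"(sums to {probs.sum()!r})"
                )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def _score_pmf(params: SyntheticParams) -> np.ndarray:
    """Marginal pmf of the modified BG score under independent components.

    TIL-low has probability 1/2 by construction of the median split.
    """
    pmf = np.array([1.0])
    for p in (params.p_wpoi5, params.p_pni, 0.5):
        pmf = np.convolve(pmf, [1 - p, p])
    return pmf


def _censoring_window(params: SyntheticParams) -> float:
    """Solve the uniform-censoring window W for the target censored fraction.

    With T ~ Exp(lam) and C ~ U(0, W), P(censored) = (1 - exp(-lam W))/(lam W);
    averaged over the score mixture this is monotone decreasing in W.
    """
    pmf = _score_pmf(params)
    lam = params.baseline_hazard * params.hazard_ratio_per_point ** np.arange(4)

    def expected_censored(w: float) -> float:
        return float((pmf * -np.expm1(-lam * w) / (lam * w)).sum())

    target = params.censor_rate
    lo, hi = 1e-6, 1e7
    if expected_censored(hi) >= target:  # pragma: no cover - extreme settings
        return hi
    return float(brentq(lambda w: expected_censored(w) - target, lo, hi))


def generate_cohort(params: SyntheticParams) -> pd.DataFrame:
    """Simulate a cohort table; identical params (incl. seed) give identical output."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    df = pd.DataFrame({"patient_id": [f"P{i + 1:04d}" for i in range(n)]})

    for var, marg in params.covariate_marginals.items():
        levels = list(marg)
        df[var] = rng.choice(levels, size=n, p=[marg[k] for k in levels])
    if "age_group" in df.columns:
        lo = np.array([_AGE_BRACKETS[g][0] for g in df["age_group"]])
        hi = np.array([_AGE_BRACKETS[g][1] for g in df["age_group"]])
        df["age"] = rng.integers(lo, hi + 1)

    mu, sigma = _lognormal_params(params.til_mean, params.til_sd)
    df["til_percent"] = np.clip(rng.lognormal(mu, sigma, size=n), 0.0, 100.0)
    split = dichotomize_by_median(df["til_percent"])
    df["til_category"] = split.labels

    df["wpoi5"] = np.where(rng.random(n) < params.p_wpoi5, "present", "absent")
    df["pni"] = np.where(rng.random(n) < params.p_pni, "present", "absent")
    df = scoring.score_cohort(df)

    if params.score_node_association != 0.0 and "p_n" in df.columns:
        df["p_n"] = _tilted_nodal_status(df["bg_score"].to_numpy(), params, rng)

    dmu, dsigma = _lognormal_params(params.doi_mean, params.doi_sd)
    doi = rng.lognormal(dmu, dsigma, size=n)
    doi[rng.random(n) < params.doi_missing_rate] = np.nan
    df["doi"] = doi

    lam = params.baseline_hazard * params.hazard_ratio_per_point ** df[
        "bg_score"
    ].to_numpy(float)
    t_event = rng.exponential(1.0 / lam)
    if params.censor_rate > 0:
        c = rng.uniform(0.0, _censoring_window(params), size=n)
        df["survival_months"] = np.minimum(t_event, c)
        df["event"] = (t_event <= c).astype(int)
    else:
        df["survival_months"] = t_event
        df["event"] = 1
    return df


def _tilted_nodal_status(
    scores: np.ndarray, params: SyntheticParams, rng: np.random.Generator
) -> np.ndarray:
    """Redraw pN with odds tilted by exp(a * score * rank(level))."""
    marg = params.covariate_marginals["p_n"]
    levels = list(marg)
    base = np.array([marg[k] for k in levels])
    ranks = np.arange(len(levels))
    out = np.empty(len(scores), dtype=object)
    for i, s in enumerate(scores):
        w = base * np.exp(params.score_node_association * s * ranks)
        out[i] = rng.choice(levels, p=w / w.sum())
    return out


# ---------------------------------------------------------------------------
# mask-field synthesis


@dataclass(frozen=True)
class SyntheticField:
    """A generated field plus its exact ground-truth pixel areas."""

    annotation: FieldAnnotation
    stroma_area: int
    til_area: int
    exclusion_area: int
    target_til_fraction: float


def _blobby_region(
    rng: np.random.Generator,
    shape: tuple[int, int],
    target_px: int,
    inside: np.ndarray | None = None,
) -> np.ndarray:
    """Union of random discs (optionally confined to ``inside``), topped up or
    trimmed pixel-wise to exactly ``target_px`` pixels."""
    h, w = shape
    allowed = np.ones(shape, bool) if inside is None else inside
    mask = np.zeros(shape, bool)
    if target_px == 0:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    allowed_idx = np.flatnonzero(allowed)
    r_max = max(2, min(h, w) // 4)
    for _ in range(64):
        if mask.sum() >= target_px:
            break
        c = allowed_idx[rng.integers(len(allowed_idx))]
        cy, cx = divmod(c, w)
        r = rng.integers(2, r_max + 1)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        mask |= disc & allowed
    count = int(mask.sum())
    if count < target_px:  # top-up with random allowed pixels
        pool = np.flatnonzero(allowed & ~mask)
        pick = rng.choice(pool, size=target_px - count, replace=False)
        mask.flat[pick] = True
    elif count > target_px:  # trim random pixels back out
        pool = np.flatnonzero(mask)
        drop = rng.choice(pool, size=count - target_px, replace=False)
        mask.flat[drop] = False
    return mask


def generate_field_masks(
    width: int,
    height: int,
    stroma_fraction: float,
    til_fraction_of_stroma: float,
    seed: int,
    exclusion_fraction: float = 0.0,
) -> SyntheticField:
    """Generate one field's stroma/TIL/exclusion masks with exact known areas.

    The TIL region lies strictly inside the stroma region and occupies exactly
    ``round(til_fraction_of_stroma * stroma_area)`` pixels, so the measured
    field percentage equals the requested fraction to within quantisation of
    a single pixel (before any exclusion).
    """
    for name, v in (
        ("stroma_fraction", stroma_fraction),
        ("til_fraction_of_stroma", til_fraction_of_stroma),
        ("exclusion_fraction", exclusion_fraction),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    rng = np.random.default_rng(seed)
    shape = (height, width)
    total = height * width
    stroma_px = round(stroma_fraction * total)
    if stroma_px == 0 and til_fraction_of_stroma > 0:
        raise ValueError("cannot place TILs in a zero-area stroma region")
    stroma = _blobby_region(rng, shape, stroma_px)
    til_px = round(til_fraction_of_stroma * stroma_px)
    til = _blobby_region(rng, shape, til_px, inside=stroma)
    excl = _blobby_region(rng, shape, round(exclusion_fraction * total))
    ann = FieldAnnotation(
        field_id=f"synthetic-{seed}",
        stroma_mask=stroma,
        til_mask=til,
        exclusion_mask=excl,
    )
    return SyntheticField(
        annotation=ann,
        stroma_area=int(stroma.sum()),
        til_area=int(til.sum()),
        exclusion_area=int(excl.sum()),
        target_til_fraction=til_fraction_of_stroma,
    )
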