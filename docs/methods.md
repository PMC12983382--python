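# Methods

## TIL quantification

A field annotation consists of three equal-sized binary rasters: stroma,
TILs (mononuclear inflammatory cells) and an exclusion region
(granulocyte-rich, ulcerated, crushed or necrotic areas, which are not
evaluable). The field percentage is

    100 · |TIL ∩ stroma \ exclusion| / |stroma \ exclusion|

computed by pixel counting. Conventions:

* TIL pixels annotated outside the stroma are ignored rather than rejected —
  manual annotations overlap imperfectly, and the quantity is defined as a
  fraction of stroma. The intersection is taken silently.
* The exclusion region is subtracted from numerator and denominator alike:
  excluded tissue contributes to neither TIL nor stromal area.
* An empty effective stroma (no stroma, or fully excluded) is an error, not
  a zero.
* A case requires 5 fields by default (`min_fields` overrides explicitly);
  the case value is the arithmetic mean of the 5 field percentages. Field
  percentages, not raw areas, are averaged: each field is treated as one
  equally weighted observation of the stromal composition regardless of how
  much stroma it happens to contain.
* Masks are dimensionless; magnification calibration cancels in the ratio.

The cohort dichotomy is the sample median, with values equal to the cutoff
labelled **low**. The tie rule matters: it is what yields an exactly equal
29/29 split in a 58-case cohort when the median is attained, and it makes
"low" the closed interval (≤ median). Percentages are carried at full
floating precision; rounding (2 decimals for summaries, 3 for p-values)
happens only in the presentation layer.

## Scoring

The modified BG score sums three binary indicators, each scored 1 when
adverse: WPOI-5 present, PNI present, TILs **low**. Treating a weak
lymphocytic response as adverse follows the original BG model's reading of
the lymphocytic host response and is consistent with high-score tumors
faring worse; since the coding direction is the one genuinely convention-like
choice in the score, `til_low_is_adverse` is an explicit parameter and the
reports document which direction was used. Scores 0–1 are low risk, 2–3
high risk.

## Association statistics

* **Pearson chi-square**: Σ(O−E)²/E with E = row·col/N, no continuity
  correction anywhere — the uncorrected statistic is what reproduces the
  published 2×2 p-values (e.g. gender × risk, p = 0.092). Levels with a zero
  marginal are dropped (df adjusted) with a warning. Expected counts < 5
  trigger a warning only; no exact test is substituted, matching the source
  analysis.
* **Linear-by-linear trend**: with ordinal scores u, v on the axes (integer
  ranks by default), r is the Pearson correlation over the N expanded
  observations and M² = (N−1)r² is referred to χ²(1). The statistic is
  invariant to affine rescaling of either score set. Both tests are computed
  and reported for every ordered×ordered pair: the published single p column
  demonstrably mixes the two (grading × score matches Pearson; pN × score,
  cN × risk and clinical-staging × risk match only the trend statistic), so
  the reports label the method per row instead of reproducing an ambiguous
  column.
* **One-way ANOVA** from raw data (scipy, with degenerate-input guards:
  SSB = 0 → F = 0, p = 1; SSW = 0 with SSB > 0 → p = 0 with a warning) and
  from printed (n, mean, SD) cells via SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)sᵢ².
  Printed SDs are treated as sample (n−1) SDs; this is validated by the
  pooled reconstruction of the printed cohort total (22.71 ± 12.75) being
  exact to the printed precision. Groups with n = 1 contribute nothing to
  SSW. Missing outcome values (depth of invasion is unavailable for 3 of the
  58 study cases) are dropped pairwise, reproducing the published n = 55
  blocks.
* **ROC AUC** by the rank (Mann–Whitney) method with mid-ranked ties,
  oriented to ≥ 0.5 with an explicit orientation flag, Hanley–McNeil
  standard error, and a normal-approximation test against AUC = 0.5.

## Survival

Kaplan–Meier product-limit estimation, restricted mean survival and
(pairwise) log-rank tests are computed through lifelines behind the module
surface. "Mean survival" is implemented as the KM restricted mean with the
group's largest observed time as the default horizon — the convention behind
the group means printed by standard statistical packages; a horizon beyond
the largest observed time is rejected rather than extrapolated. Censored
subjects tied with events at t remain at risk at t. Pairwise log-rank
p-values are reported unadjusted.

## Synthetic cohorts

The generator emulates the structure of the 58-patient study cohort so that
every pipeline stage, and the statistical behaviour of the tests, can be
exercised without deposited data. Defaults:

| parameter | default | rationale |
|---|---|---|
| n_patients | 58 | study cohort size |
| p_wpoi5, p_pni | 22/58, 15/58 | published marginal frequencies |
| til_mean, til_sd | 22.8, 12.7 (%) | published mean ± SD |
| baseline_hazard | 1/37 per month | score-0 printed mean survival of 37 months |
| hazard_ratio_per_point | (37/17)^(1/3) ≈ 1.30 | spans the printed 37→17-month gradient over 3 points |
| censor_rate | 36/58 | published censored fraction |
| doi_mean, doi_sd, missing | 1.13, 0.67 cm, 3/58 | published DOI summary and missingness |
| covariate_marginals | published level counts | gender, site, stage, nodal, grade, age brackets |

Model choices, each made once:

* **%stromal TILs** is log-normal, moment-matched to the target mean/SD and
  clipped to [0, 100]. The published mean (22.8) exceeding the median (18)
  implies right skew; the family itself is unstated, and the moment-matched
  log-normal has median ≈ 19.9 rather than 18 — the generator matches the
  moments, not the median.
* **Survival** is exponential with hazard λ₀·HRˢ, s the modified BG score —
  the simplest model with a multiplicative per-point effect, sufficient for
  power and recovery checks.
* **Censoring** is administrative: C ~ Uniform(0, W) for every subject, with
  W solved numerically so the expected censored fraction equals
  `censor_rate` under the implied score mixture (W ≈ 28 months at the
  defaults). These constraints cannot all hold at once: with ~62% censoring
  under a uniform window, the window is necessarily shorter than the
  published 37-month score-0 mean, so group restricted means sit below the
  published ones while their ordering and the censored fraction are
  preserved. The generator favours the censored fraction and the ordering.
* **Covariates** are drawn independently from their marginals. Real
  clinicopathological variables are correlated (stage with nodal status,
  grade with invasion pattern); passing tests on these cohorts therefore
  demonstrates correctness of the computations, not realism of joint
  clinical structure. A single association knob (`score_node_association`)
  tilts pathological nodal status with the score, exp(a·s·rank) odds
  weighting, for trend-test power checks.
* Age is drawn as a bracket from the published age-group counts, then
  uniformly within the bracket (28–76 overall, matching the published
  range).

Determinism: one `numpy.random.Generator` seeded from `seed` drives every
draw; identical parameters give byte-identical cohort exports
(`write_cohort` uses fixed float formatting).

### Mask fields

Synthetic fields are disc composites: stroma as a union of random discs,
TILs as discs confined to the stroma, each topped up or trimmed pixel-wise
to the exact target count, so the true areas are known exactly and the
measured percentage equals the requested fraction to single-pixel
quantisation. They exercise the area arithmetic, not the appearance of H&E
histology — no nuclei, color or texture.

## Test problem sizes

The suite verifies exact identities at desk scale and stochastic properties
at sizes chosen for stable Monte-Carlo behaviour: marginal recovery on a
4000-patient cohort, TIL moments at 20 000, calibration and null-uniformity
checks over 120–1000 replicates with 3-standard-error acceptance bands, and
closed-form survival recovery at 2000–20 000 subjects.

## Known limitations

* The 4-group log-rank test across score groups is anti-conservative at the
  study's cohort size: the expected score-3 group is ~3 subjects (~1 event
  under the default censoring), outside the validity range of the χ²(3)
  reference. The two-group (risk-category) log-rank and the ANOVA calibrate
  at the nominal level under the same conditions, and the score-group test
  calibrates as n grows.
* Summary-based ANOVA inherits the 2-decimal rounding of printed inputs;
  reconstructed p-values are accurate to roughly ±0.005.
* The survival generator's uniform-censoring window cannot reproduce
  published restricted means and the published censored fraction
  simultaneously (see above); comparisons against printed group means are
  ordering-level only.
* No multiple-testing correction is applied anywhere, matching the source
  analysis; the many association p-values per report should be read
  accordingly.
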