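# bgrisk

Modified Brandwein-Gensler (BG) histological risk scoring for oral squamous
cell carcinoma (OSCC), with quantitative tumor-infiltrating-lymphocyte (TIL)
measurement and the full downstream association and survival analysis.

## The problem

The original BG risk model grades three features at the tumor front — worst
pattern of invasion (WPOI), perineural invasion (PNI) and lymphocytic host
response — with sub-grades that are slow to apply and subjective, especially
the qualitative three-tier immune-infiltrate assessment. A simplified,
objective variant replaces the qualitative immune tier with **%stromal
TILs**, the percentage of tumor stroma occupied by mononuclear inflammatory
cells, measured on routine H&E sections:

```
%stromal TILs = 100 x area(TILs ∩ stroma, after exclusions) / area(stroma, after exclusions)
```

averaged over 5 representative microscopic fields per case (granulocyte-rich,
ulcerated, crushed and necrotic areas are excluded from both numerator and
denominator). Cases are dichotomized at the cohort median (ties go to "low"),
and the modified score sums three binary adverse indicators:

```
score = [WPOI-5 present] + [PNI present] + [TILs low]      (0..3)
risk  = low if score <= 1, high if score >= 2
```

The package implements this pipeline end to end for pathologists and
biostatisticians: mask-based TIL quantification, scoring, contingency-table
tests (Pearson chi-square and the linear-by-linear trend statistic
M² = (N−1)r²), one-way ANOVA — both from raw data and reconstructed from
printed per-group (n, mean ± SD) cells — Pearson correlation, rank-based ROC
AUC, and Kaplan-Meier / log-rank survival analysis with restricted means. A
synthetic-cohort generator reproduces the structure of the 58-patient study
cohort this design comes from, so every stage is testable although no
per-patient data were deposited; the study's printed cross-tabulations and
group summaries ship as packaged fixtures.

## Worked example

Recompute the published association statistics from the packaged printed
tables:

```python
from bgrisk import pipeline

cat, cont = pipeline.study_association_report()
print(cat[cat.variable.isin(["grade", "p_n"])]
      [["variable", "against", "method", "statistic", "df", "p_display"]])
```

```
variable  against             method  statistic  df p_display
     p_n bg_score pearson_chi_square  12.581624   9     0.182
     p_n bg_score   linear_by_linear   7.933282   1     0.005
   grade bg_score pearson_chi_square  14.478772   6     0.025
   grade bg_score   linear_by_linear   3.150990   1     0.076
     p_n  bg_risk pearson_chi_square   9.643332   3     0.022
     p_n  bg_risk   linear_by_linear   8.971589   1     0.003
   grade  bg_risk pearson_chi_square   6.393601   2     0.041
   grade  bg_risk   linear_by_linear   1.096215   1     0.295
```

Tumor grading associates with the score by the Pearson test (p = 0.025);
pathological nodal status associates by the ordinal trend test (p = 0.005
against the score, p = 0.022/0.003 against the risk tiers). Both methods are
always reported side by side — a single unlabelled p column would conflate
two different tests. Continuous outcomes are reconstructed from the printed
group cells; e.g. %stromal TILs across age groups:

```
TIL x age ANOVA: F=5.13 on (4,53) df, p=0.001; pooled 22.71+-12.75 (n=58)
```

The pooled total reproduces the printed cohort row (22.71 ± 12.75, n = 58)
exactly, confirming the printed SDs are sample (n−1) SDs.

The same reports run on any cohort CSV (see the column dictionary in
`bgrisk.cohort`), and the whole pipeline is scriptable from the shell:

```sh
bgrisk simulate --seed 7 --out cohort.csv          # synthetic 58-patient cohort
bgrisk score --cohort cohort.csv --out scored.csv  # median split + BG score
bgrisk associate --cohort scored.csv --outdir out/
bgrisk survival  --cohort scored.csv --outdir out/
bgrisk report --from-study-fixtures --outdir out/  # published-table reports
```

Mask-based quantification (`bgrisk quantify-tils --manifest manifest.csv`)
reads single-channel PNG/TIFF masks (nonzero = inside region), five fields
per case.

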