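# pgxresponse

Pharmacogenomic analysis of patient-reported SSRI response by CYP2C19
metaboliser status, built for biostatisticians and pharmacogenomics
researchers who want a tested, reusable version of this study design:
infer CYP2C19 metabolism from the tier-1 star alleles, test for
differences in antidepressant efficacy, tolerability and side effects
between metaboliser groups, and quantify the study's power by
simulation — all exercisable end to end on synthetic cohorts with known
ground truth.

## What it does

**Metaboliser inference.** The tier-1 *CYP2C19* variants rs12248560
(\*17), rs4244285 (\*2) and rs4986893 (\*3) are read from a VCF (GT hard
calls, or imputed DS dosages hardened with a configurable tolerance) and
converted to star-allele diplotypes under the standard no-cis assumption
(each haplotype carries at most one variant-defining allele, so a \*2/\*17
double heterozygote is called trans). Diplotypes translate to the five
CPIC phenotypes:

| diplotype | phenotype |
|---|---|
| \*17/\*17 | ultrarapid |
| \*1/\*17 | rapid |
| \*1/\*1 | normal |
| \*1/\*2, \*1/\*3, \*2/\*17, \*3/\*17 | intermediate |
| \*2/\*2, \*2/\*3, \*3/\*3 | poor |

**Association battery.** For each SSRI (sertraline, citalopram,
escitalopram) and for all drugs pooled, with normal metabolisers as the
reference and adjusting for age and sex:

* 3-level efficacy ("not at all well" / "moderately well" / "very
  well") — proportional-odds (cumulative-logit) regression,
  `logit P(y ≤ k) = θ_k − xβ`;
* discontinuation due to side effects (inverse tolerability) and
  any-side-effect — logistic regression;
* pooled analyses — the same likelihoods with a participant-level
  random intercept (repeated measures across drugs), maximised by
  adaptive Gauss–Hermite quadrature (15 nodes);
* number of side effects (binned 0 / 1–2 / 3+, ordinal) and a scan of
  23 named side effects per drug;
* Bonferroni families: 0.05/4 for efficacy and tolerability (four
  contrasts vs normal), 0.05/300 for the side-effect family
  (25 outcomes × 3 drugs × 4 contrasts).

All fits are Newton-type with step-halving, converge at gradient
∞-norm < 1e-8, and report Wald ORs with 95% CIs
(`exp(β ± 1.96·SE)`) from the observed information. Crude 2×2 odds
ratios with Woolf CIs are provided for table-level checks.

**Power analysis.** A simulation-based power study for the ordinal
efficacy model: per metaboliser group and log-odds effect size
(grid ≈ OR 1.05–1.82), generate responses from the proportional-odds
model at the observed group sizes (199/2460/3869/2555/448), refit, and
count nominal rejections; the 80%-power effect threshold per group is
located by linear interpolation.

**Synthetic cohorts.** `pgxresponse.cohort` generates realistic
depression-cohort data:
Hardy–Weinberg genotype draws at haplotype frequencies (\*17 21.4%,
\*2 14%, \*3 0.02%), age ~ N(42.8, 15.1²) truncated to [18, 90], 76%
female, overlapping drug exposure (~69/25/6% on one/two/three drugs),
outcome baselines matched to the published normal-metaboliser
marginals, configurable status log-odds effects, and a shared
participant-level random intercept — so every downstream stage is
testable against known truth.

## Worked example

```bash
pgxresponse simulate --n 2000 --seed 7 --out-dir demo/
pgxresponse call-metabolizer --vcf demo/genotypes.vcf --out demo/status.tsv
pgxresponse associate --phenotypes demo/phenotypes.tsv \
    --statuses demo/status.tsv --no-scan --out demo/results.tsv
pgxresponse report --results demo/results.tsv
```

`call-metabolizer` prints the attrition accounting:

```
called	2000
excluded	0
```

and the report renders the forest-table, e.g. (seed 7, null cohort —
all generating status effects are zero, so ORs hover around 1 and no
contrast is flagged):

```
## Efficacy (3-level, cumulative logit)

| scope | contrast | OR [95% CI] | p | sig |
|---|---|---|---|---|
| sertraline | poor vs normal | 0.83 [0.39-1.78] | 0.629 |  |
| sertraline | intermediate vs normal | 1.10 [0.84-1.44] | 0.485 |  |
...
| pooled | poor vs normal | 1.01 [0.56-1.83] | 0.976 |  |
```

Each row is one metaboliser-group contrast against normal: an OR above
1 for efficacy means that group reports better response; for
discontinuation it means higher odds of stopping (lower tolerability).
`*` marks p < 0.05, `**` significance after the family's Bonferroni
correction. The same run as a single command:

```bash
pgxresponse run-all --seed 7 --out-dir demo/   # + power stage & manifest
```

Equivalent library calls: `generate_cohort`, `call_cohort`,
`run_primary_analysis`, `estimate_power`.

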