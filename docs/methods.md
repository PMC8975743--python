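# Methods

## CYP2C19 metaboliser inference

Genotypes at the three tier-1 *CYP2C19* variants — rs12248560 (defines
\*17, increased function), rs4244285 (\*2, loss of function), rs4986893
(\*3, loss of function) — are converted to star-allele diplotypes under
the standard no-cis assumption: a haplotype carries at most one
variant-defining allele, so the \*1 reference haplotype absorbs whatever
the variant alleles do not. A pattern whose total variant-allele count
exceeds two (e.g. homozygous \*2 plus a \*17 allele) admits no such
haplotype pair and is returned as *indeterminate*; exhaustive
enumeration over all 27 genotype patterns shows every pattern maps to
exactly one of the 10 diplotypes or to indeterminate. Imputed dosages
(VCF `DS`) are hardened to the nearest integer when within a tolerance
(default 0.1, a common hard-call convention); ambiguous dosages and
missing genotypes exclude the participant, with counts reported, never
silently dropped. Diplotype → phenotype follows the CPIC lookup
(\*17/\*17 ultrarapid; \*1/\*17 rapid; \*1/\*1 normal; one loss-of-function
allele — including \*2/\*17 and \*3/\*17, CPIC's "likely intermediate" —
intermediate; two loss-of-function alleles poor). Variant matching is
by rsID in the VCF ID column with an optional chrom:pos fallback so no
genome build is hard-coded.

Under random mating at haplotype frequencies (p1, p2, p3, p17) the
phenotype prevalences have closed forms — p17² ultrarapid, 2·p1·p17
rapid, p1² normal, 2(p1+p17)(p2+p3) intermediate, (p2+p3)² poor — used
as the independent oracle for the genotype simulator. At the default
frequencies (21.4% \*17, 14% \*2, 0.02% \*3) these give 4.58% ultrarapid
and 1.97% poor.

## Synthetic cohort generator

The generator emulates the structure of a large retrospective
patient-reported antidepressant-response cohort:

* **Genotypes** — two independent haplotype draws per participant at
  the frequencies above (Hardy–Weinberg; no linkage disequilibrium or
  imputation uncertainty is modelled).
* **Demographics** — age from a normal distribution with SD 15.1 y
  truncated to [18, 90] (adult cohort); because asymmetric truncation
  would shift the realized mean ~1.6 y upward, the location is
  re-solved numerically so the truncated mean equals the configured
  42.8 y. Sex is Bernoulli with P(female) = 0.76.
* **Drug exposure** — the number of SSRIs (sertraline, citalopram,
  escitalopram) is drawn with probabilities 0.69/0.25/0.06 for 1/2/3,
  then that many distinct drugs are chosen with probability
  proportional to the observed per-drug exposure shares
  (Plackett–Luce successive sampling, implemented as Gumbel-top-k).
  Independent per-drug Bernoullis at the observed marginals cannot
  reproduce the observed 25%/6% overlap, so the count-then-choose
  construction is used and calibrating the overlap takes priority over
  matching the marginals exactly.
* **Outcomes** — each participant receives a random intercept
  u ~ N(0, σ²) (default σ = 1, configurable; σ = 0 is the
  mixed-vs-fixed equivalence point) shared across all records and
  outcomes. Efficacy follows the proportional-odds model
  P(y ≤ k) = logit⁻¹(θ_k[drug] − lp) with
  lp = β_status + β_age·age + β_sex·sex + u; binary outcomes follow
  logit⁻¹(intercept[drug] + β_status + covariates + u). Per-drug
  thresholds and intercepts default to the published
  normal-metaboliser marginals (e.g. sertraline efficacy 37/36/28%,
  discontinuation 46%, any side effect 70%). All status effects and
  covariate effects default to zero (the study adjusts for age and sex
  but reports no estimates), so the default generator is an exact null
  for the analysis models. The 23 named side effects are exchangeable
  Bernoullis (default rate 0.15 each) sharing u; only three names
  (weight loss, fatigue, drowsiness) are taken from the reported
  associations, the rest are plausible SSRI side-effect labels.

What the generator does **not** emulate: dose titration and regime
changes, concomitant (phenoconverting) medication, recall bias,
correlations among specific side effects beyond the shared random
intercept, and any genotype–demographic dependence. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimation machinery under the stated generative model, not robustness
to these real-data complications.

## Association models

All models use normal metabolisers as the reference, with indicator
contrasts for poor/intermediate/rapid/ultrarapid, adjusting for age
(years, uncentred — affects intercepts only) and sex (female = 1);
pooled models add drug indicators (first drug present as reference)
and a participant-level random intercept for repeated measures.

* **Cumulative-logit (proportional-odds)**: logit P(y ≤ k) = θ_k − xβ,
  θ₁ < θ₂, so positive β means better reported response and exp(β) is
  the cumulative OR. Fitted by Newton's method with analytic gradient
  and Hessian (verified against finite differences), step-halving line
  search, ridge fallback for non-PD Hessians, convergence at gradient
  ∞-norm < 1e-8, max 100 iterations.
* **Logistic**: same machinery on the Bernoulli likelihood.
* **Random-intercept (mixed) fits**: the marginal likelihood
  integrates u_i ~ N(0, σ²) per participant by adaptive Gauss–Hermite
  quadrature — per-cluster mode and curvature found by an inner Newton
  iteration, 15 nodes by default (fixed effects move < 1e-4 when
  doubled to 31 on fixtures; the quadrature matches brute-force
  trapezoid integration to ~1e-10 on small fixtures). The outer
  optimization is L-BFGS over (fixed effects, log σ), started at the
  fixed-model estimates; standard errors come from a central
  finite-difference Hessian of the marginal negative log-likelihood.
  Data in which every participant has a single record degenerate to
  the fixed model with σ = 0.
* **Inference** is Wald throughout: OR = exp(β̂), 95% CI
  exp(β̂ ± 1.96·SE), two-sided p from β̂/SE — chosen because the
  emulated study reports OR [95% CI] + p without naming a test;
  profile-likelihood CIs are out of scope. Wald inference degrades
  under (quasi-)separation (Hauck–Donner effect); separated or
  non-convergent fits are flagged (`converged=False`), never raised,
  and simulation loops count them conservatively as non-rejections.
* **Crude 2×2 ORs** use (a·d)/(b·c) with the Woolf log-scale CI and
  a flagged Haldane–Anscombe 0.5 correction for zero cells.
* **Multiplicity**: efficacy and tolerability each form a 4-test
  family (one per contrast; threshold 0.05/4 = 0.0125). The
  side-effect family comprises any-side-effect, the binned
  number-of-side-effects and the 23 specific side effects × 3 drugs ×
  4 contrasts = 300 tests (threshold 0.05/300 ≈ 1.67e-4). The number
  of side effects is analysed as a cumulative-logit on counts binned
  0 / 1–2 / 3+ (configurable), keeping the ordinal machinery rather
  than introducing a count model.

## Power analysis

The power study follows the simulate-and-refit design: for a target
metaboliser group and log-odds effect δ, build the two cumulative
log-odds linear predictors η_k = θ_k − (δ·1[status = target] +
β_age·age + β_sex·sex) for every observation (one observation per
participant at the observed group sizes 199/2460/3869/2555/448),
invert to category probabilities, draw a 3-level response, refit the
plain (non-mixed) cumulative-logit model with status + age + sex, and
record whether the target contrast's Wald p < 0.05. Power is the
rejection fraction over replicates (default 1000; the tests and the
acceptance script use 300, which bounds the Monte-Carlo SE at ~2.9 pp);
the 80%-power effect per group is located by linear interpolation
along the effect grid (log-odds 0.05–0.6, ORs ≈ 1.05–1.82). The
default thresholds place the baseline at the pooled normal-metaboliser
efficacy split (34.9/37.1/27.9%). Effects are applied one status at a
time; covariate effects default to zero but remain in the refit
design. Each (status, effect) cell runs on an independent child RNG
stream of the root seed, so grids are reproducible and individual
cells re-runnable.

## Pipeline

`run_all` chains simulate → call-metabolizer → associate → power. A
single top-level seed expands into per-stage sub-seeds via
`numpy.random.default_rng([seed, stage_index])` (simulate = 0,
call = 1, associate = 2, power = 3), so stages can be re-run
independently. Each run writes a JSON manifest with the SHA-256 of the
canonical config, the seeds, every output path, and exclusion
accounting (missing genotypes, indeterminate diplotypes, participants
lost joining phenotypes to called statuses); identical config + seed
gives byte-identical outputs (timestamps live only in the manifest).
Logging is structured key=value. The forest plot is rendered as a
markdown table (per-drug and pooled rows with `*`/`**` significance
flags); no graphical output is produced.

## Numerical and design notes

* Thresholds are kept ordered during Newton updates by rejecting (and
  halving) steps that violate θ₁ < θ₂; starting values are empirical
  cumulative logits with β = 0.
* The category probability P(Y = y) is floored at 1e-150 before
  taking logs/ratios to avoid underflow at extreme linear predictors.
* Mixed-model σ is optimized as log σ with bounds [1e-4, 50]; a
  boundary estimate at the lower bound reports σ ≈ 0.
* Participants missing an outcome for a given drug still contribute
  to other drugs' models; each model uses the records with that
  outcome observed.
* Test problem sizes (cohorts of 600–2000 for analysis round-trips,
  9531 for prevalence checks, 300–800 power replicates, 100
  recovery replicates at n = 2000) were chosen so Monte-Carlo error
  stays well inside the asserted tolerances.

## Known limitations

Only the three tier-1 alleles are modelled (no \*4–\*35, no activity
scores); genotype QC (missingness, HWE, MAF filters) and imputation are
out of scope. Wald p-values are anti-conservative/degenerate under
separation, and very large simulated effects (log-OR ≳ 3 in small
groups) can separate. The mixed-model SEs rely on a finite-difference
observed information; with very weak random-effect identification
(σ → 0) the σ standard error is unreliable, though fixed effects are
unaffected. Published adjusted pooled ORs from the emulated study are
not reproducible without its individual-level data; they are used here
only as generator settings for recovery tests.
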