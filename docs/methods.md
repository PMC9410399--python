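# Methods

`edcassoc` implements the complete statistical pipeline of a case–control
candidate-gene study of childhood atopic eczema and its progression to
eczema-associated asthma: two SNPs in epidermal differentiation complex
(EDC) genes — HRNR rs877776 (risk allele C) and FLG2 rs12568784 (risk
allele T) — analysed jointly with the combined FLG loss-of-function
genotype (carrier of ≥ 1 of R501X, 2282del4, R2447X, S3247X). This note
records the models, the numerical choices, and what the synthetic data do
and do not establish.

## Study design assumptions baked into the data model

The cohort model enforces the study's recruitment structure as invariants:
every asthma case is also an eczema case (so "asthma" always denotes the
composite asthma-plus-eczema phenotype), SCORAD severity (mild < 25,
moderate 25–50, severe > 50) exists only for eczema cases, polysensitized
implies sensitized, and controls (no eczema, no asthma) have a negative
family history of atopy because that was a control inclusion criterion.
The last invariant matters statistically: family history quasi-separates
case status, so adjusted logistic models that include it routinely need
penalized estimation (below).

Missing genotype calls never code as "unexposed": a subject with a missing
call is retained in the cohort but excluded complete-case from any
statistic that needs that site, with exclusions counted per analysis. This
mirrors the varying denominators across the source study's tables.

## Crude association statistics

All crude measures come from 2×2 integer counts.

* **Odds ratio**: OR = ad/bc with the Woolf (log-OR Wald) interval
  exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d)). Woolf was chosen because it
  reproduces the study's printed crude CIs (e.g. 2.91, CI 1.19–7.13 for the
  within-eczema asthma association of HRNR carriers). With exactly one zero
  cell, the Haldane–Anscombe 0.5 is added to all cells (estimate and CI,
  flagged); two zero cells on a diagonal leave the OR undefined.
* **Genetic models**: dominant (carrier vs wild-type homozygote),
  recessive, genotype3 (0/1/2 risk-allele count), and the allele
  (multiplicative) model in which each subject contributes two allele-level
  observations to an allele × outcome table.
* **χ² test**: Pearson, no Yates correction (a corrected variant is behind
  a flag), generalizing to 2×k. **Fisher exact**: two-sided by summing
  hypergeometric probabilities ≤ the observed table's, margins fixed
  (delegated to scipy; verified in the test suite against an independent
  exact-rational enumeration over *all* tables with total ≤ 60). The
  "as appropriate" rule picks Fisher when any expected cell is < 5.
* p-values are two-sided; no multiple-testing adjustment is applied by
  default, matching the source analysis.

## Hardy–Weinberg testing

χ² goodness of fit on the three genotype classes with the allele frequency
estimated from the sample: expected counts n·((1−q)², 2q(1−q), q²), 1 df
(one estimated parameter), no continuity correction by default. Computed on
controls by default. Notably, the published control genotype counts for
both SNPs deviate from HWE at α = 0.05 (χ² ≈ 5.13 and ≈ 21.5); the pipeline
reports this and draws no conclusion.

## Logistic regression and separation

Adjusted odds ratios come from an in-package maximum-likelihood logistic
regression: Newton iterations with step-halving, convergence at a 10⁻⁸
change in log-likelihood, 100-iteration cap, Wald standard errors. Constant
and exactly collinear columns are dropped with a warning. Separation is
flagged when any fitted probability sits within 10⁻⁶ of 0/1 together with a
diverging coefficient (|β| > 10 or non-convergence); under the default
`method="auto"` the model is then refit with Firth's penalized likelihood
(score adjusted by the hat-diagonal term, objective = log-likelihood +
½·log det I(β)). The fit was cross-checked against statsmodels' Logit to
10⁻⁶ in the test suite. Printed *adjusted* ORs from the source study are
treated as non-reproducible (the exact covariate handling is unstated);
only crude statistics are pinned.

Covariates for adjusted models: age (continuous, months), sex (male = 1),
family history of atopy (binary; the usual separation trigger).

## Gene–gene interaction

Subjects are cross-classified by two binary factors into four strata. The
"RR" of a stratum is the ratio of within-stratum case proportions
cases/(cases + controls) against the double-unexposed stratum. **In a
case–control sample this is a design artifact, not a population risk
ratio** — the case fraction is fixed by the sampling ratio — but it is
exactly the quantity the source tables print, and every printed RR is
reproduced by this definition. Interaction contrasts, always computed from
unrounded RRs:

* RERI = RR₁₁ − RR₁₀ − RR₀₁ + 1 (superadditive if > 0)
* AP = RERI / RR₁₁
* S = (RR₁₁ − 1) / ((RR₁₀ − 1) + (RR₀₁ − 1)), undefined at denominator 0
* ratio of RRs = RR₁₁ / (RR₁₀ · RR₀₁) (positive multiplicative
  interaction if > 1)

Zero-control strata get an uncorrected point RR (= 1/p₀ exactly, as
printed) and a Haldane-corrected, flagged Katz CI. The multiplicative-scale
product-term test is a Wald test of A×B in the logistic fit; zero-cell
strata commonly trigger separation there, which is flagged and Firth-refit.

The source analysis reports no CIs for RERI/AP/S; the package provides them
anyway, via the Hosmer–Lemeshow delta method on the log-RR covariance
(var lₙᵢ = (1−pᵢ)/(nᵢpᵢ) + (1−p₀)/(n₀p₀), shared-reference covariance
(1−p₀)/(n₀p₀); S on the log scale) with an automatic fallback to a
stratified case/control multinomial bootstrap (percentile intervals,
seeded) when any stratum has a zero cell.

## Predictive-biomarker metrics

The default evaluation population is outcome-positives = eczema-associated
asthma cases and outcome-negatives = healthy controls, with
eczema-without-asthma children excluded — the only reading that makes all
four published HRNR/FLG2 metrics mutually consistent with the
joint-genotype counts; a within-eczema variant is available through the
population filters. Sensitivity and specificity carry Clopper–Pearson exact
binomial CIs (these reproduce the published intervals); PPV/NPV intervals
are configurable (Clopper–Pearson default, logit-Wald variant) because the
source's PPV/NPV interval method is unstated and matches no standard
construction. Zero-denominator metrics are reported as undefined, never
silently 0. Conjunction predictors (e.g. SNP carrier AND FLG null) are
first-class.

## Synthetic cohorts

The generator states the study's world and is not tuned to any test:

* genotypes per site are Binomial(2, q) draws — Hardy–Weinberg by
  construction — at the control-estimated risk-allele frequencies
  (q = 0.135 for rs877776[C], 0.106 for rs12568784[T]);
* FLG-null carrier probability 0.03 (between the observed 2.4% in controls
  and 13.6% in cases, as a population value must be);
* eczema from a logistic model (default: dominant log-odds ln 2.2 per SNP,
  ln 6 for FLG null, intercept −1.8 giving a realistic ~15–20% childhood
  prevalence); asthma only among eczema cases (default baseline 18%,
  dominant effects ln 2.9 / ln 5.0); sensitization for everyone with eczema
  as a term;
* case–control accrual by rejection sampling (cap 10⁷ draws) until the
  quotas are met, controls required to be eczema-free, asthma-free and
  family-history negative — reproducing the recruitment design and its
  quasi-separation;
* covariates: truncated-normal ages on 0–24 months (13.6 ± 6.7 cases,
  15.9 ± 5.6 controls, the study-group table's values; the running text
  prints 13.2/15.3 and the package does not arbitrate), sex ratio 107/188
  male, family history 57/103 among cases; severity mild/moderate at the
  observed 79:24; total IgE log-normal with control geometric mean
  17.7 IU/mL and case geometric mean 38.5 IU/mL — the published case value
  (24.6) lies outside its own printed CI (27.8–53.4), so the geometric mean
  of the CI bounds is used instead;
* matching is marginal (same age/sex distributions), not pairwise: the
  source does not state how pairs were matched, and no conditional analysis
  is performed.

A second, risk-table mode draws a plain cohort with explicit per-stratum
outcome risks; it exists because a logistic model cannot hit arbitrary
additive-scale (RERI) targets exactly, and it is what the RERI-coverage
simulations use.

What a green simulation test establishes: calibration of the estimators
(unbiased log-ORs, ~95% Woolf and delta-method coverage, nominal type-I
error of the product-term Wald test, HWE rejection at α) under the stated
generative model. What it does not: linkage disequilibrium between the EDC
loci (the sites are simulated independently; the real loci are ~100 kb
apart on 1q21), haplotype effects, genotyping error, environmental
covariates, or pairwise matching.

## Numerical and policy choices

* Display percentages round half-up to 1 decimal; ORs/RRs render at 2
  decimals and p-values at 3 in "paper" table style, full precision in
  "plain" style and JSON. Internal arithmetic is never rounded.
* The source tables contain internal inconsistencies (a carrier count that
  is 17 in one table and 16 in the joint-genotype table; a synergy index
  printed as 0.02 where its own RRs give ≈ 0.98; one interaction block
  whose printed RRs are not reproducible from its printed counts; an
  estimate printed equal to its CI bound). The package computes everything
  from counts and reports both sides of such conflicts; none of those
  values is asserted in the tests.
* Monte-Carlo suite scaling: the 500-replicate calibration runs (parameter
  recovery at OR 2.5; product-term type-I error) live in the acceptance
  tests; the same checks at OR 1.5/5.0 and the power check run at 60–150
  replicates with correspondingly widened binomial bands, purely for
  runtime.
* Determinism: every stochastic step (simulation, bootstrap) takes an
  explicit seed; pipeline bundles contain no timestamps and re-running the
  same config + seed is byte-identical.

## Known limitations

* No exact (Wigginton-style) HWE test; the χ² approximation is what the
  source used, and small hom-rare counts make it anticonservative there —
  reported, not corrected.
* No conditional logistic regression, no haplotype analysis, no
  gene–environment terms, no prevalence-adjusted PPV/NPV projection, no
  multi-allelic sites.
* The delta-method S interval requires RR₁₀ + RR₀₁ > 2 and RR₁₁ > 1;
  otherwise only bootstrap intervals are offered.
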