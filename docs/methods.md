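# Methods

## Scoring model

The score is strictly additive: for sample *i*,
`PRS_i = Σ_j w_j · d_ij` over the weight-table variants *j* matched in the
genotype data, with `d_ij` the count (0–2) of the effect allele in the
sample's diploid, unphased call. No dominance terms, no interaction terms,
no imputation dosages — dosages are integer allele counts. A per-sample
`n_variants_found` accompanies every score so the effective denominator is
always auditable.

### Effect-allele matching

A weight row names an effect allele and (usually) an other allele. At a
genotyped site with alleles `REF, ALT₁, …, ALTₖ` the effect allele is
located by string equality: `REF_EFFECT` (allele index 0), `ALT_EFFECT(k)`
(allele index k), or `UNMATCHED`. If the row's other allele matches
neither REF nor any ALT the pair is inconsistent with the site and the row
degrades to `UNMATCHED`; unmatched rows are skipped and tallied, never an
error, because published weight files routinely contain them. There is no
strand flipping and no special handling of palindromic (A/T, C/G) SNPs:
a flipped-strand weight row will simply fail to match, or — for
palindromic sites — silently match the wrong orientation. This is a known
limitation; callers who need strand reconciliation must pre-harmonize
their weight files.

Multi-allelic sites are kept as single records with ordered ALTs and the
scorer matches one specific allele index. Splitting multi-allelics would
require re-normalisation conventions the matching rule does not need.

### Missing-call policies

Storage and interpretation are deliberately decoupled. In the sparse
store, a position covered by neither a variant entry nor a reference block
is *absent*; absence is preserved through serialization and round-trips.
What absence means is decided at scoring time:

* `EXCLUDE` (dense-path default): the variant does not contribute for that
  sample and is not counted in its `n_variants_found`. Consequently the
  found count may differ across samples.
* `HOM_REF` (sparse-path default): the call is treated as (0,0) — dosage 2
  if the effect allele is REF, 0 if it is ALT. The found count is constant
  across samples.

The defaults reproduce the two behaviours whose agreement the comparison
battery is designed to measure; either policy can be forced on either
path. The per-sample difference `sparse(HOM_REF) − dense(EXCLUDE)` equals,
in exact arithmetic, the sum of hom-ref-dosage × weight over that sample's
missing weight-variants. The test suite asserts this identity at 1e-9
absolute rather than bitwise, because the two sides accumulate
floating-point terms in different orders.

### Allele orientation on the sparse path

Reference blocks carry no allele strings, so at a locus where *no* sample
has a stored entry the store alone cannot say which allele is genomic REF.
The scorer resolves orientation in priority order: (1) any stored entry's
variant key, (2) the annotation table's (ref, alt) at that locus, (3) the
weight row itself, assuming the effect allele is ALT. Fallback (3) can
misorient a REF-effect weight at an all-hom-ref locus, which is why
scoring the sparse path together with its annotation table is the
recommended (and default CLI) usage. Reference blocks also carry a
`min_quality` field, preserved through serialization but never consulted
by scoring.

## Weight-file dialect

Tab-separated with `#`-prefixed `key=value` metadata, then a header row.
`effect_allele` and `effect_weight` are required; coordinates come from
`hm_chr`/`hm_pos` when present (harmonized coordinates are the
build-correct ones), else `chr_name`/`chr_position`. Rows with
unparseable position or weight are dropped and counted; duplicate
(chrom, pos, effect, other) rows keep the first occurrence with a warning.
The accounting identity `raw rows = kept + dropped + duplicates` always
holds, and both raw and kept counts are reported because published
"score size" figures may refer to either. A declared genome build that
contradicts the caller's expectation warns rather than errors.
Chromosome names are normalised to the `chr`-prefixed GRCh38 convention.

## Statistics

* **Lin's CCC** `= 2ρσₓσᵧ/(σₓ²+σᵧ²+(μₓ−μᵧ)²)` with all moments computed
  with denominator *n* (Lin's original convention; the n−1 variant differs
  negligibly at cohort sizes but the choice is fixed and tested). Pearson
  ρ comes from `scipy.stats.pearsonr`. Degenerate case: exactly one
  constant vector gives CCC = 0 with ρ = NaN; two constant vectors raise.
* **AUC** is computed from midranks (`scipy.stats.rankdata`):
  `AUC = (R₁ − n₁(n₁+1)/2)/(n₁n₀)`, the Mann–Whitney probability that a
  case outscores a control with ties counted half. Tests cross-check it
  against all-pairs enumeration and against scikit-learn's
  `roc_auc_score`, which is never used in the implementation.
* **Logistic association** fits intercept + slope by maximum likelihood
  (`statsmodels.Logit`). The PRS is z-scored first by default (population
  SD, ddof = 0), so `exp(slope)` is the OR per SD — the conventional scale
  for polygenic effects and the one on which simulation-recovery targets
  are well defined; a flag disables standardization. CIs are Wald
  `exp(slope ± 1.96·SE)`; profile-likelihood intervals were not needed for
  the package's purposes. Perfect separation and non-convergence raise an
  explicit error; statsmodels' warnings are converted, never swallowed
  into garbage coefficients. No covariates and no multiple-testing
  correction are offered: the comparison battery evaluates one predictor
  at a time.
* **ECDF distance** is the supremum of |F̂ₓ − F̂ᵧ| over the pooled sample —
  the two-sample Kolmogorov–Smirnov statistic, cross-checked against
  `scipy.stats.ks_2samp` in tests. It is reported as a distributional
  summary, not as a hypothesis test.

## Synthetic cohorts

The generator draws unlinked biallelic SNPs in Hardy–Weinberg
equilibrium across two chromosomes, with inter-variant gaps of 1–300 bp so
hom-ref runs exercise reference-block merging. Parameters (defaults in
parentheses, chosen once as a realistic single-score setting):

| parameter | default | meaning |
| --- | --- | --- |
| `n_samples` | 1,000 | cohort size |
| `n_variants` | 2,000 | weight-table size (typical genome-wide-significant score) |
| `maf_low, maf_high` | 0.01, 0.5 | allele frequency ~ Uniform range |
| `weight_sd` | 0.1 | per-allele weight ~ N(0, sd²), score units |
| `baseline_prevalence` | 0.1 | P(case) at mean PRS |
| `per_sd_log_or` | log 1.8 | slope of the logistic disease model |
| `qc_fail_rate` | 0.05 | fraction of sites flagged failed in the annotation |
| `missing_rate` | 0.0 | per-call missingness |
| `effect_orientation` | `"alt"` | `"random"` flips effect to REF for ~half the weights |

Disease status is `Bernoulli(expit(α + β·z))` with `z` the z-scored true
PRS and `α = logit(baseline_prevalence)`, i.e. the stated prevalence holds
at z = 0 (marginal prevalence is slightly higher because expit is convex
below ½). The phenotype is generated from the *complete* genotypes;
missingness is injected afterwards, so policy effects can be judged
against uncorrupted truth. One root seed spawns named substreams (sites,
frequencies, genotypes, weights, phenotype, QC, missingness); output is
bit-identical for identical configs.

What the generator does **not** emulate: linkage disequilibrium,
population structure, relatedness, realistic site-frequency spectra, and
genotyping error correlated with allele frequency. Passing tests therefore
demonstrate the correctness of scoring arithmetic, storage semantics and
the estimators — not robustness to the confounding structure of real
cohorts.

## Problem sizes and numerical choices

The verification suite runs path equivalence on a 500 × 2,000 cohort,
effect-size recovery on 50 replicates of 20,000 × 50 (small variant count
because association recovery depends on the score distribution, not on
how many variants compose it), and brute-force oracles at n = 200; these
sizes give stable statistics while keeping the whole suite fast on a
single CPU. Path equivalence without missing data is asserted bitwise
(identical accumulation order makes this achievable); cross-path
identities that reorder floating-point sums use 1e-9 absolute tolerance;
closed-form statistic checks use 1e-12. CI-coverage assertions use
binomial tolerance bands (e.g. ≥ 43/50 at nominal 95%) rather than exact
counts.

## Known limitations

* No strand flipping, liftover, or allele-frequency-based resolution of
  ambiguous palindromic SNPs.
* Diploid, unphased genotypes only; half-missing calls collapse to
  missing; no genotype likelihoods or imputation dosages.
* The sparse store's orientation fallback (effect-as-ALT) is a heuristic
  when neither entries nor annotation cover a locus.
* Wald CIs can be anti-conservative in small samples or at extreme
  prevalence; the fit refuses (rather than repairs) separated data.
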