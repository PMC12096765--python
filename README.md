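# prskit

A dual-path polygenic risk score (PRS) engine for biobank-scale genotype
data, with the evaluation statistics needed to show that the two paths
agree.

## The problem

A PRS is the per-individual weighted sum of effect-allele counts,

```
PRS_i = Σ_j  w_j · d_ij ,      d_ij ∈ {0, 1, 2}
```

where `w_j` is a published per-allele weight (e.g. from a PGS Catalog
scoring file) and `d_ij` is individual *i*'s diploid dosage of the effect
allele at variant *j*. Computing this is trivial on a **dense** genotype
matrix, where every sample–variant cell carries an explicit call. But
storing whole-genome cohorts densely is expensive; large programs
increasingly distribute a **sparse** representation instead, in which only
non-reference calls are stored and homozygous-reference stretches are
encoded as per-sample *reference blocks*. Scoring against the sparse form
requires interval queries at the weight-table loci, a QC filter driven by a
variant annotation table, and a policy decision: a locus covered by neither
a call nor a block is *assumed homozygous reference*. That assumption makes
sparse scoring cheap, and introduces small discrepancies relative to the
dense path whenever calls are missing.

`prskit` implements both paths over the same scoring kernel, makes the
missing-call policy explicit (`EXCLUDE` vs `HOM_REF`, both available on
both paths), and quantifies path agreement the way method-comparison
studies do:

* **Lin's concordance correlation coefficient**
  `CCC = 2ρσₓσᵧ / (σₓ² + σᵧ² + (μₓ − μᵧ)²)` — penalises location/scale
  shifts that Pearson's ρ ignores;
* **rank-based ROC AUC** (Mann–Whitney probability, midranks for ties);
* **logistic association** — OR per SD of PRS with Wald 95% CI;
* **ECDF comparison**, including the two-sample Kolmogorov–Smirnov
  supremum distance.

A seeded synthetic-cohort generator (Hardy–Weinberg genotypes, additive
weights, logistic disease model with a configurable per-SD odds ratio)
makes the whole pipeline testable without access to controlled genotype
data.

## Worked example

```python
from prskit import (CohortSimConfig, simulate_cohort, sparsify,
                    score_dense, score_sparse, compare_score_sets)

cfg = CohortSimConfig(n_samples=2000, n_variants=1000, missing_rate=0.02,
                      effect_orientation="random", seed=42)
cohort = simulate_cohort(cfg)

dense_run  = score_dense(cohort.dense, cohort.weights)
sparse_run = score_sparse(sparsify(cohort.dense), cohort.weights,
                          ann=cohort.annotation)
report = compare_score_sets(dense_run, sparse_run, cohort.phenotype)
print(report.summary())
```

prints

```
Paired samples: 2000
Lin's CCC: 0.909263  Pearson r: 0.925436
means: 1.03696 vs 1.37423  variances: 3.57443 vs 3.25336
ECDF max distance: 0.084500
path A: OR per SD: 1.6362 [95% CI 1.4039, 1.9070]  AUC: 0.6327  (cases 200, controls 1800)
path B: OR per SD: 1.6293 [95% CI 1.3977, 1.8993]  AUC: 0.6289  (cases 200, controls 1800)
```

Reading: with 2% of calls missing and a QC filter applied only on the
sparse path, the two score vectors remain strongly concordant
(CCC ≈ 0.91) — the mean shift comes from the hom-ref fill counting two
reference alleles at missing REF-effect sites — while predictive
performance is essentially identical (AUC 0.633 vs 0.629, overlapping OR
confidence intervals). The simulation truth was an OR of 1.8 per SD of the
*true* score; the attenuation to ≈1.63 reflects the Bernoulli noise of a
2,000-sample cohort and scoring on observed rather than true genotypes.

The same workflow is available from the shell:

```sh
prskit simulate --out-dir cohort --seed 42 --n-samples 2000 \
    --n-variants 1000 --missing-rate 0.02 --effect-orientation random
prskit score-dense  --vcf cohort/cohort.vcf --weights cohort/weights.pgs.tsv --out dense.tsv
prskit score-sparse --sparse cohort/cohort.sparse.tsv --weights cohort/weights.pgs.tsv \
    --annotation cohort/annotation.tsv --out sparse.tsv
prskit compare --a dense.tsv --b sparse.tsv --phenotype cohort/phenotype.tsv \
    --out comparison --plot
```

## Layout

| module | contents |
| --- | --- |
| `prskit.weights` | PGS-Catalog-dialect scoring-file reader/writer, annotation table, QC filter |
| `prskit.genotypes` | dense matrix, VCF ingestion (cyvcf2), chromosome normalisation |
| `prskit.sparse` | reference-block store, sparsify/densify, text serialization |
| `prskit.scoring` | effect-allele matching, dosage rules, both scoring paths, TSV export |
| `prskit.stats` | Lin's CCC, rank AUC, logistic OR, ECDF utilities, comparison report |
| `prskit.simulate` | synthetic cohort generator and file writer |
| `prskit.cli` | `prskit` command: `simulate`, `score-dense`, `score-sparse`, `compare` |

Design notes, modelling assumptions and known limitations are in
[docs/methods.md](docs/methods.md).
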