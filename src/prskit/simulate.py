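"""Synthetic biobank-style cohorts for exercising the scoring engine.

The generator draws unlinked biallelic SNPs in Hardy–Weinberg equilibrium:
per-variant allele frequency p ~ Uniform(maf_low, maf_high), genotype
dosage ~ Binomial(2, p) per sample, additive per-allele weights
~ Normal(0, weight_sd^2).  The true PRS is the weighted dosage sum,
z-scored across the cohort; disease status follows a logistic model

    P(case | z) = expit(alpha + beta * z),

with beta the per-SD log odds ratio and alpha = logit(baseline_prevalence)
so that prevalence at z = 0 equals the requested baseline.  A configurable
fraction of variants is flagged as QC-failed in the annotation table, and
calls can be masked missing at a configurable rate.

Linkage disequilibrium, population structure and relatedness are
deliberately absent: they do not bear on the correctness of scoring
arithmetic or of the evaluation statistics, which is what these cohorts
exist to test.

One root seed feeds named independent substreams (positions/alleles,
frequencies, genotypes, weights, phenotype, QC flags, missingness) so each
component is reproducible on its own.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .errors import PrsKitError
from .genotypes import MISSING, DenseGenotypeMatrix, VariantKey, write_vcf
from .sparse import sparsify, write_sparse
from .stats import PhenotypeTable
from .weights import AnnotationTable, ScoreVariant, WeightTable, write_pgs_scoring_file

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_SUBSTREAMS = ("sites", "freqs", "genotypes", "weights", "phenotype", "qc", "missing")


@dataclass
class CohortSimConfig:
    """Cohort-generator parameters.

    Defaults emulate a modest single-score cohort: 1,000 samples scored on
    a ~2,000-variant weight table (the size class of a typical genome-wide
    significant-SNP score), common variants (MAF 0.01–0.5), weight SD 0.1
    score units per allele, 10% baseline disease prevalence and a per-SD
    odds ratio of 1.8 — a strong but realistic polygenic effect; 5% of
    sites carry a failed-QC flag; no missing calls unless requested.
    """

    n_samples: int = 1000
    n_variants: int = 2000
    maf_low: float = 0.01
    maf_high: float = 0.5
    missing_rate: float = 0.0
    weight_sd: float = 0.1
    baseline_prevalence: float = 0.1
    per_sd_log_or: float = math.log(1.8)
    qc_fail_rate: float = 0.05
    seed: int = 0
    score_id: str = "SIM000001"
    #: "alt" assigns every weight's effect allele to ALT; "random" flips a
    #: fair coin per variant so REF-effect matching is exercised too.
    effect_orientation: str = "alt"

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_variants < 1:
            raise PrsKitError("n_samples and n_variants must be positive")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise PrsKitError("need 0 < maf_low <= maf_high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise PrsKitError("missing_rate must be in [0, 1)")
        if not self.weight_sd > 0:
            raise PrsKitError("weight_sd must be > 0")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise PrsKitError("baseline_prevalence must be in (0, 1)")
        if not 0.0 <= self.qc_fail_rate < 1.0:
            raise PrsKitError("qc_fail_rate must be in [0, 1)")
        if self.effect_orientation not in ("alt", "random"):
            raise PrsKitError("effect_orientation must be 'alt' or 'random'")


@dataclass
class SimulatedCohort:
    """Everything one simulated study produces, plus the generating truth."""

    dense: DenseGenotypeMatrix
    weights: WeightTable
    annotation: AnnotationTable
    phenotype: PhenotypeTable
    config: CohortSimConfig
    allele_freqs: np.ndarray = field(repr=False)
    true_prs: np.ndarray = field(repr=False)
    true_prs_z: np.ndarray = field(repr=False)
    qc_failed: np.ndarray = field(repr=False)  # bool per variant


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {
        name: np.random.default_rng(child)
        for name, child in zip(_SUBSTREAMS, children)
    }


def simulate_cohort(cfg: CohortSimConfig) -> SimulatedCohort:
    """Draw one cohort: genotypes, weight table, annotation, phenotype.

    Bit-identical output for identical configs.  The phenotype is generated
    from the *complete* genotypes; missingness (if any) is injected into
    the returned matrix afterwards, so a scorer's missing-data policy can
    be judged against the uncorrupted truth.
    """
    cfg.validate()
    rng = _substreams(cfg.seed)
    m, n = cfg.n_variants, cfg.n_samples

    # sites: two chromosomes, positions strictly increasing with gaps in
    # 1..300 so some hom-ref runs are adjacent and reference blocks merge
    site_rng = rng["sites"]
    half = (m + 1) // 2
    keys: list[VariantKey] = []
    for chrom, count in (("chr1", half), ("chr2", m - half)):
        if count == 0:
            continue
        gaps = site_rng.integers(1, 301, size=count)
        positions = 10_000 + np.cumsum(gaps)
        refs = site_rng.choice(4, size=count)
        alt_off = site_rng.integers(1, 4, size=count)
        for pos, r, off in zip(positions, refs, alt_off):
            ref = _BASES[r]
            alt = _BASES[(r + off) % 4]
            keys.append(VariantKey(chrom, int(pos), str(ref), (str(alt),)))

    freqs = rng["freqs"].uniform(cfg.maf_low, cfg.maf_high, size=m)
    dosages = rng["genotypes"].binomial(2, freqs[:, None], size=(m, n)).astype(np.int16)
    # dosage -> unphased diploid call: 0->(0,0), 1->(0,1), 2->(1,1)
    alleles = np.zeros((m, n, 2), dtype=np.int16)
    alleles[:, :, 0] = (dosages == 2).astype(np.int16)
    alleles[:, :, 1] = (dosages >= 1).astype(np.int16)

    raw_weights = rng["weights"].normal(0.0, cfg.weight_sd, size=m)
    if cfg.effect_orientation == "random":
        ref_effect = rng["weights"].random(m) < 0.5
    else:
        ref_effect = np.zeros(m, dtype=bool)

    sample_ids = [f"S{i:06d}" for i in range(n)]
    dense = DenseGenotypeMatrix(sample_ids, keys, alleles)
    # DenseGenotypeMatrix sorts variants; recover the permutation so the
    # per-variant truth arrays stay aligned with the weight table
    order = sorted(range(m), key=lambda i: keys[i].sort_key())
    keys = [keys[i] for i in order]
    freqs = freqs[order]
    dosages = dosages[order]
    raw_weights = raw_weights[order]
    ref_effect = ref_effect[order]

    variants = []
    for i, key in enumerate(keys):
        alt = key.alts[0]
        effect, other = (key.ref, alt) if ref_effect[i] else (alt, key.ref)
        variants.append(
            ScoreVariant(
                score_id=cfg.score_id,
                chrom=key.chrom,
                pos=key.pos,
                effect_allele=effect,
                other_allele=other,
                weight=float(raw_weights[i]),
            )
        )
    weights = WeightTable(
        score_id=cfg.score_id,
        genome_build="GRCh38",
        variants=variants,
        n_raw_rows=m,
    )

    effect_dosage = np.where(ref_effect[:, None], 2 - dosages, dosages)
    true_prs = (raw_weights[:, None] * effect_dosage).sum(axis=0)
    sd = true_prs.std()
    z = (true_prs - true_prs.mean()) / sd if sd > 0 else np.zeros(n)
    alpha = math.log(cfg.baseline_prevalence / (1.0 - cfg.baseline_prevalence))
    p_case = expit(alpha + cfg.per_sd_log_or * z)
    outcome = rng["phenotype"].random(n) < p_case
    phenotype = PhenotypeTable(
        {sid: int(y) for sid, y in zip(sample_ids, outcome)}
    )

    qc_failed = rng["qc"].random(m) < cfg.qc_fail_rate
    annotation = AnnotationTable(
        {
            (key.chrom, key.pos, key.ref, key.alts[0]): {
                "passed_qc": not bool(qc_failed[i]),
                "allele_freq": float(freqs[i]),
            }
            for i, key in enumerate(keys)
        }
    )

    if cfg.missing_rate > 0:
        dense = inject_missingness(
            dense, cfg.missing_rate, rng=rng["missing"]
        )

    n_cases = int(outcome.sum())
    logger.info(
        "simulated cohort: %d samples x %d variants, %d cases (%.1f%%), "
        "%d QC-failed variants, missing rate %.3f",
        n, m, n_cases, 100.0 * n_cases / n, int(qc_failed.sum()), cfg.missing_rate,
    )
    return SimulatedCohort(
        dense=dense,
        weights=weights,
        annotation=annotation,
        phenotype=phenotype,
        config=cfg,
        allele_freqs=freqs,
        true_prs=true_prs,
        true_prs_z=z,
        qc_failed=qc_failed,
    )


def inject_missingness(
    dense: DenseGenotypeMatrix,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DenseGenotypeMatrix:
    """Return a copy with each call independently masked missing at ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise PrsKitError("rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    alleles = dense.alleles.copy()
    if rate > 0 and alleles.size:
        mask = rng.random(alleles.shape[:2]) < rate
        alleles[mask] = MISSING
        logger.info(
            "injected missingness: %d of %d calls masked (rate %.3f)",
            int(mask.sum()), mask.size, rate,
        )
    return DenseGenotypeMatrix(
        list(dense.sample_ids), list(dense.variants), alleles
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str) -> dict[str, str]:
    """Write a simulated cohort to the package's on-disk formats.

    Produces cohort.vcf (dense genotypes), cohort.sparse.tsv (sparse
    store), weights.pgs.tsv, annotation.tsv, phenotype.tsv in ``out_dir``;
    returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(out / "cohort.vcf"),
        "sparse": str(out / "cohort.sparse.tsv"),
        "weights": str(out / "weights.pgs.tsv"),
        "annotation": str(out / "annotation.tsv"),
        "phenotype": str(out / "phenotype.tsv"),
    }
    write_vcf(cohort.dense, paths["vcf"])
    write_sparse(sparsify(cohort.dense), paths["sparse"])
    write_pgs_scoring_file(cohort.weights, paths["weights"])
    cohort.annotation.to_tsv(paths["annotation"])
    cohort.phenotype.to_tsv(paths["phenotype"])
    return paths
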