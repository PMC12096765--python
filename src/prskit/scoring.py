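"""Per-sample PRS computation over dense or sparse genotypes.

The score for a sample is the weighted sum, over the weight-table variants,
of the sample's *effect-allele dosage* (0, 1 or 2 copies of the effect
allele).  The two paths differ only in where the calls come from and in the
default treatment of missing calls:

* dense path — explicit matrix; missing calls are excluded from the sum by
  default (the variant simply does not contribute for that sample);
* sparse path — calls are materialised at the weight loci from entries and
  reference blocks; positions covered by neither are *assumed homozygous
  reference* by default, the compromise that makes sparse stores cheap.

Both defaults are overridable so the discrepancy between the policies can
be measured directly.  No strand flipping or palindromic-SNP handling is
done: a weight row whose effect allele matches neither REF nor any ALT at
its locus is counted as unmatched and skipped.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractViolation, EmptyTableError, FormatError
from .genotypes import DenseGenotypeMatrix, GenotypeCall, VariantKey
from .sparse import SparseVariantDataset, densify_at
from .weights import AnnotationTable, WeightTable, filter_weights_by_annotation

logger = logging.getLogger(__name__)


class MissingPolicy(enum.Enum):
    """What a missing call means at scoring time."""

    EXCLUDE = "exclude"  # variant skipped for that sample
    HOM_REF = "hom-ref"  # treated as (0, 0)


class RoleKind(enum.Enum):
    REF_EFFECT = "ref"
    ALT_EFFECT = "alt"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class AlleleRole:
    """Which allele index at a site carries the weight (0 = REF, k = k-th ALT)."""

    kind: RoleKind
    allele_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind is RoleKind.ALT_EFFECT and not (self.allele_index or 0) >= 1:
            raise ContractViolation("ALT_EFFECT requires a valid alt index >= 1")
        if self.kind is RoleKind.REF_EFFECT and self.allele_index != 0:
            object.__setattr__(self, "allele_index", 0)


UNMATCHED = AlleleRole(RoleKind.UNMATCHED)


def match_effect_allele(
    key: VariantKey, effect_allele: str, other_allele: str | None = None
) -> AlleleRole:
    """Locate the effect allele among a site's REF/ALT alleles.

    Returns REF_EFFECT when the effect allele is the site's reference
    allele, ALT_EFFECT(k) when it is the k-th alternate (allele index k,
    1-based over the allele list), UNMATCHED otherwise.  When the weight
    row names an other_allele that matches neither REF nor any ALT, the
    pair is inconsistent with the site and the role degrades to UNMATCHED.
    """
    if other_allele is not None:
        if other_allele != key.ref and other_allele not in key.alts:
            return UNMATCHED
    if effect_allele == key.ref:
        return AlleleRole(RoleKind.REF_EFFECT, 0)
    for k, alt in enumerate(key.alts, start=1):
        if effect_allele == alt:
            return AlleleRole(RoleKind.ALT_EFFECT, k)
    return UNMATCHED


#: Sentinel returned by effect_dosage for a skipped (missing under EXCLUDE) call.
SKIP = None


def effect_dosage(
    call: GenotypeCall, role: AlleleRole, policy: MissingPolicy = MissingPolicy.EXCLUDE
):
    """Effect-allele count for one call: 0, 1, 2, or :data:`SKIP`.

    A missing call yields SKIP under EXCLUDE; under HOM_REF it is treated
    as (0, 0) — dosage 2 when the reference allele is the effect allele,
    0 when an alternate is.
    """
    if role.kind is RoleKind.UNMATCHED:
        raise ContractViolation("effect_dosage called with UNMATCHED role")
    if call.is_missing:
        if policy is MissingPolicy.EXCLUDE:
            return SKIP
        return 2 if role.allele_index == 0 else 0
    return call.dosage_of(role.allele_index)


@dataclass
class ScoreResult:
    """One sample's PRS and accounting.

    ``contributions`` (present when requested) lists, per scored variant,
    (VariantKey, dosage, weight, dosage*weight); the products sum to
    ``prs_sum``.
    """

    sample_id: str
    prs_sum: float
    n_variants_found: int
    n_variants_in_score: int
    contributions: list[tuple[VariantKey, int, float, float]] | None = None


class ScoreRun(Sequence):
    """Scoring output: a sequence of :class:`ScoreResult` plus run-level
    tallies (how many weight variants were found, absent from the data, or
    unmatched on alleles)."""

    def __init__(
        self,
        results: list[ScoreResult],
        n_variants_in_score: int,
        n_matched: int,
        n_absent: int,
        n_unmatched: int,
        n_removed_by_qc: int = 0,
    ):
        self.results = results
        self.n_variants_in_score = n_variants_in_score
        self.n_matched = n_matched
        self.n_absent = n_absent
        self.n_unmatched = n_unmatched
        self.n_removed_by_qc = n_removed_by_qc

    def __len__(self):
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]

    @property
    def prs(self) -> np.ndarray:
        return np.array([r.prs_sum for r in self.results], dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.results]


def _score_calls(
    sample_ids: list[str],
    call_arrays,  # iterable of (weight_variant, role, (n_samples, 2) int array) triples
    n_in_score: int,
    policy: MissingPolicy,
    collect_contributions: bool,
    n_matched: int,
    n_absent: int,
    n_unmatched: int,
    n_removed_by_qc: int = 0,
) -> ScoreRun:
    """Shared vectorised accumulation kernel for both paths."""
    n = len(sample_ids)
    prs = np.zeros(n, dtype=float)
    found = np.zeros(n, dtype=np.int64)
    contribs: list[list] | None = [[] for _ in range(n)] if collect_contributions else None
    for sv, role, calls in call_arrays:
        a = calls[:, 0].astype(np.int64)
        b = calls[:, 1].astype(np.int64)
        miss = a < 0
        k = role.allele_index
        dos = (a == k).astype(np.int64) + (b == k).astype(np.int64)
        if policy is MissingPolicy.EXCLUDE:
            dos[miss] = 0
            found += ~miss
            used = ~miss
        else:
            dos[miss] = 2 if k == 0 else 0
            found += 1
            used = np.ones(n, dtype=bool)
        prs += sv.weight * dos
        if contribs is not None:
            key = sv.site_key
            for si in np.nonzero(used)[0]:
                contribs[si].append(
                    (key, int(dos[si]), sv.weight, float(dos[si] * sv.weight))
                )
    results = [
        ScoreResult(
            sample_id=sid,
            prs_sum=float(prs[si]),
            n_variants_found=int(found[si]),
            n_variants_in_score=n_in_score,
            contributions=contribs[si] if contribs is not None else None,
        )
        for si, sid in enumerate(sample_ids)
    ]
    return ScoreRun(results, n_in_score, n_matched, n_absent, n_unmatched, n_removed_by_qc)


def score_dense(
    dense: DenseGenotypeMatrix,
    wt: WeightTable,
    policy: MissingPolicy = MissingPolicy.EXCLUDE,
    collect_contributions: bool = False,
) -> ScoreRun:
    """Score a dense matrix against a weight table.

    Weight variants absent from the matrix, and ones whose effect allele
    matches neither REF nor ALT at their locus, contribute nothing and are
    tallied on the returned :class:`ScoreRun`.
    """
    if len(wt) == 0:
        raise EmptyTableError("cannot score with an empty weight table")
    triples = []
    n_absent = n_unmatched = 0
    for sv in wt.variants:
        vi = dense.locus_index.get((sv.chrom, sv.pos))
        if vi is None:
            n_absent += 1
            continue
        key = dense.variants[vi]
        role = match_effect_allele(key, sv.effect_allele, sv.other_allele)
        if role.kind is RoleKind.UNMATCHED:
            n_unmatched += 1
            continue
        sv = _WithKey(sv, key)
        triples.append((sv, role, dense.alleles[vi]))
    run = _score_calls(
        dense.sample_ids,
        triples,
        len(wt),
        policy,
        collect_contributions,
        n_matched=len(triples),
        n_absent=n_absent,
        n_unmatched=n_unmatched,
    )
    logger.info(
        "dense scoring: %d in score, %d matched, %d absent, %d unmatched (%s)",
        len(wt), run.n_matched, n_absent, n_unmatched, policy.value,
    )
    return run


class _WithKey:
    """ScoreVariant proxy carrying the genotype-side site key for contributions."""

    __slots__ = ("_sv", "site_key")

    def __init__(self, sv, site_key: VariantKey):
        self._sv = sv
        self.site_key = site_key

    def __getattr__(self, name):
        return getattr(self._sv, name)


def score_sparse(
    vds: SparseVariantDataset,
    wt: WeightTable,
    ann: AnnotationTable | None = None,
    policy: MissingPolicy = MissingPolicy.HOM_REF,
    collect_contributions: bool = False,
) -> ScoreRun:
    """Score a sparse variant dataset against a weight table.

    When an annotation table is given, the weight table is first restricted
    to QC-passed variants.  Calls are then materialised at the weight loci
    (interval queries against each sample's reference blocks) and scored
    exactly as on the dense path; the default HOM_REF policy treats
    uncovered loci as homozygous reference.

    The allele role at a locus is taken from the stored variant key when
    any sample has an entry there; failing that from the annotation
    table's REF/ALT orientation; failing both, the weight row's effect
    allele is assumed to be the ALT allele.  The last fallback can
    misorient a reference-effect weight at a locus where every sample is
    hom-ref or missing, which is why scoring the sparse path with its
    annotation table is recommended.
    """
    if len(wt) == 0:
        raise EmptyTableError("cannot score with an empty weight table")
    n_removed_by_qc = 0
    if ann is not None:
        before = len(wt)
        wt = filter_weights_by_annotation(wt, ann)
        n_removed_by_qc = before - len(wt)
        if len(wt) == 0:
            raise EmptyTableError("annotation filter removed every weight variant")
    loci = wt.loci
    calls = densify_at(vds, loci)
    keys = vds.locus_keys(loci)
    triples = []
    n_unmatched = 0
    for i, sv in enumerate(wt.variants):
        key = keys[i]
        if key is None and ann is not None:
            # no stored entry anywhere: the annotation table knows the
            # site's REF/ALT orientation
            ref_alt = ann.ref_alt_at(sv.chrom, sv.pos)
            if ref_alt is not None:
                key = VariantKey(sv.chrom, sv.pos, ref_alt[0], (ref_alt[1],))
        if key is None:
            # last resort: orient from the weight row, effect allele as ALT
            ref = sv.other_allele if sv.other_allele is not None else "N"
            key = VariantKey(sv.chrom, sv.pos, ref, (sv.effect_allele,))
        role = match_effect_allele(key, sv.effect_allele, sv.other_allele)
        if role.kind is RoleKind.UNMATCHED:
            n_unmatched += 1
            continue
        triples.append((_WithKey(sv, key), role, calls[i]))
    run = _score_calls(
        vds.sample_ids,
        triples,
        len(wt),
        policy,
        collect_contributions,
        n_matched=len(triples),
        n_absent=0,
        n_unmatched=n_unmatched,
        n_removed_by_qc=n_removed_by_qc,
    )
    logger.info(
        "sparse scoring: %d in score (%d removed by QC), %d matched, "
        "%d unmatched (%s)",
        len(wt), n_removed_by_qc, run.n_matched, n_unmatched, policy.value,
    )
    return run


def export_results(
    results: Sequence[ScoreResult], path: str, include_contributions: bool = False
) -> None:
    """Write scoring results as TSV: sample_id, prs_sum, n_variants_found,
    n_variants_in_score.

    ``prs_sum`` is printed with shortest round-trip precision so reading
    the file back reproduces the floats bit-for-bit.  With
    ``include_contributions``, a sibling file ``<path>.contributions.tsv``
    lists one row per (sample, scored variant) with dosage, weight (fixed
    6 decimals) and product; per-sample products sum to prs_sum.
    """
    with open(str(path), "wt") as fh:
        fh.write("sample_id\tprs_sum\tn_variants_found\tn_variants_in_score\n")
        for r in results:
            fh.write(
                f"{r.sample_id}\t{r.prs_sum!r}\t{r.n_variants_found}\t"
                f"{r.n_variants_in_score}\n"
            )
    if include_contributions:
        cpath = str(path) + ".contributions.tsv"
        with open(cpath, "wt") as fh:
            fh.write(
                "sample_id\tchrom\tpos\tref\talts\tdosage\tweight\tproduct\n"
            )
            for r in results:
                for key, dosage, weight, product in r.contributions or []:
                    fh.write(
                        f"{r.sample_id}\t{key.chrom}\t{key.pos}\t{key.ref}\t"
                        f"{','.join(key.alts)}\t{dosage}\t{weight:.6f}\t{product!r}\n"
                    )


def read_results(path: str) -> list[ScoreResult]:
    """Read an export_results TSV back into ScoreResult objects."""
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip"
    )
    required = {"sample_id", "prs_sum", "n_variants_found", "n_variants_in_score"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: not a prskit results file (columns {list(df.columns)})"
        )
    return [
        ScoreResult(
            sample_id=row.sample_id,
            prs_sum=float(row.prs_sum),
            n_variants_found=int(row.n_variants_found),
            n_variants_in_score=int(row.n_variants_in_score),
        )
        for row in df.itertuples(index=False)
    ]
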