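"""Dense genotype representation and VCF ingestion.

The dense store mirrors a samples x variants genotype matrix in which every
cell holds an explicit diploid, unphased call.  Calls are kept in a single
``(n_variants, n_samples, 2)`` int16 array of allele indices (0 = REF,
k = k-th ALT, -1 = missing) so that scoring can run vectorised per variant.

Coordinates are 1-based (VCF convention) throughout; genomic intervals used
elsewhere in the package are half-open ``[start, end)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import FormatError, InvariantError

#: Sentinel allele index for a missing call.
MISSING = -1

_CHR_NUM = re.compile(r"^(?:chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name to the "chr"-prefixed GRCh38 style."""
    chrom = str(chrom).strip()
    if not chrom:
        raise FormatError("empty chromosome name")
    if chrom.lower().startswith("chr"):
        return "chr" + chrom[3:]
    return "chr" + chrom


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key placing chr1..chr22 numerically before chrX/chrY/chrM."""
    m = _CHR_NUM.match(chrom)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return (int(tok), "")
        return ({"X": 23, "Y": 24, "M": 25, "MT": 25}[tok], "")
    return (99, chrom)


class GenotypeCall(NamedTuple):
    """One diploid, unphased genotype: two allele indices (0 = REF,
    k = k-th ALT) or both :data:`MISSING`."""

    allele_a: int
    allele_b: int

    @property
    def is_missing(self) -> bool:
        return self.allele_a < 0 or self.allele_b < 0

    @property
    def is_hom_ref(self) -> bool:
        return self.allele_a == 0 and self.allele_b == 0

    def dosage_of(self, allele_index: int) -> int:
        """Count of alleles in this call equal to ``allele_index``."""
        return int(self.allele_a == allele_index) + int(self.allele_b == allele_index)


MISSING_CALL = GenotypeCall(MISSING, MISSING)
HOM_REF_CALL = GenotypeCall(0, 0)


@dataclass(frozen=True)
class VariantKey:
    """Identity of one variant record: chromosome, 1-based position,
    reference allele, and the ordered ALT alleles.

    Multi-allelic sites stay single records; scoring matches a specific
    allele index against this key, so no splitting/renormalisation is done.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvariantError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise InvariantError("ref allele must be non-empty")
        for alt in self.alts:
            if not alt:
                raise InvariantError("alt allele must be non-empty")
            if alt == self.ref:
                raise InvariantError(
                    f"alt allele equals ref at {self.chrom}:{self.pos}"
                )

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def sort_key(self):
        return (*chrom_sort_key(self.chrom), self.pos)


@dataclass
class DenseGenotypeMatrix:
    """Samples x variants matrix of explicit diploid calls.

    ``alleles`` has shape ``(n_variants, n_samples, 2)`` with dtype int16;
    missing calls are ``(-1, -1)``.  Variants are kept sorted by
    (chromosome, position); construction sorts if needed.
    """

    sample_ids: list[str]
    variants: list[VariantKey]
    alleles: np.ndarray
    _locus_index: dict[tuple[str, int], int] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int16)
        if self.alleles.shape != (len(self.variants), len(self.sample_ids), 2):
            raise InvariantError(
                "alleles array shape "
                f"{self.alleles.shape} does not match "
                f"({len(self.variants)} variants, {len(self.sample_ids)} samples, 2)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvariantError("duplicate sample IDs")
        order = sorted(range(len(self.variants)), key=lambda i: self.variants[i].sort_key())
        if order != list(range(len(self.variants))):
            self.variants = [self.variants[i] for i in order]
            self.alleles = self.alleles[order]
        # exactly-one-allele-missing is not a representable diploid state here
        half = (self.alleles < 0).sum(axis=2) == 1
        if half.any():
            raise InvariantError("call with exactly one missing allele")
        self._locus_index = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def locus_index(self) -> dict[tuple[str, int], int]:
        """(chrom, pos) -> first variant index at that locus."""
        if self._locus_index is None:
            idx: dict[tuple[str, int], int] = {}
            for i, key in enumerate(self.variants):
                idx.setdefault(key.locus, i)
            self._locus_index = idx
        return self._locus_index

    def call(self, variant_index: int, sample_index: int) -> GenotypeCall:
        a, b = self.alleles[variant_index, sample_index]
        return GenotypeCall(int(a), int(b))

    def n_missing_calls(self) -> int:
        return int(((self.alleles[:, :, 0] < 0)).sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, DenseGenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and np.array_equal(self.alleles, other.alleles)
        )


def matrix_from_calls(
    sample_ids: Sequence[str],
    records: Iterable[tuple[VariantKey, Sequence[GenotypeCall]]],
) -> DenseGenotypeMatrix:
    """Build a dense matrix from per-variant call sequences (test/helper API)."""
    sample_ids = list(sample_ids)
    variants: list[VariantKey] = []
    rows: list[list[tuple[int, int]]] = []
    for key, calls in records:
        calls = list(calls)
        if len(calls) != len(sample_ids):
            raise InvariantError(
                f"variant {key.chrom}:{key.pos} has {len(calls)} calls "
                f"for {len(sample_ids)} samples"
            )
        variants.append(key)
        rows.append([(c.allele_a, c.allele_b) for c in calls])
    alleles = (
        np.array(rows, dtype=np.int16)
        if rows
        else np.empty((0, len(sample_ids), 2), dtype=np.int16)
    )
    return DenseGenotypeMatrix(sample_ids, variants, alleles)


def read_vcf(path: str) -> DenseGenotypeMatrix:
    """Read a VCF 4.x file (plain or gzipped) into a dense matrix.

    Only the GT field is consumed.  ``./.`` and ``.`` become missing calls;
    the phase separator is ignored.  A GT allele index exceeding the number
    of ALT alleles on its record is a parse error naming the offending line.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    variants: list[VariantKey] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        alts = tuple(a for a in (rec.ALT or []) if a != "<NON_REF>")
        key = VariantKey(normalize_chrom(rec.CHROM), rec.POS, rec.REF, alts)
        gts = np.array(
            [(g[0], g[1]) for g in rec.genotypes], dtype=np.int16
        ) if sample_ids else np.empty((0, 2), dtype=np.int16)
        if gts.size:
            if int(gts.max(initial=0)) > len(alts):
                raise FormatError(
                    f"GT allele index out of range at {rec.CHROM}:{rec.POS} "
                    f"(site has {len(alts)} ALT allele(s))"
                )
            # half-missing diploid calls (e.g. "./0") collapse to missing
            any_missing = (gts < 0).any(axis=1)
            gts[any_missing] = MISSING
        variants.append(key)
        rows.append(gts)
    alleles = (
        np.stack(rows)
        if rows
        else np.empty((0, len(sample_ids), 2), dtype=np.int16)
    )
    return DenseGenotypeMatrix(sample_ids, variants, alleles)


def write_vcf(dense: DenseGenotypeMatrix, path: str) -> None:
    """Write the matrix as a minimal VCF 4.2 file with GT-only FORMAT."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    chroms: list[str] = []
    for key in dense.variants:
        if key.chrom not in chroms:
            chroms.append(key.chrom)
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=prskit\n")
        for c in sorted(chroms, key=chrom_sort_key):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dense.sample_ids)
            + "\n"
        )
        for vi, key in enumerate(dense.variants):
            alt = ",".join(key.alts) if key.alts else "."
            gt_tokens = []
            for a, b in dense.alleles[vi]:
                gt_tokens.append("./." if a < 0 else f"{a}/{b}")
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_tokens)
                + "\n"
            )
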