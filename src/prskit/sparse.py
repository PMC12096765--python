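"""Sparse reference-block genotype store.

Instead of one explicit call per sample-variant cell, each sample carries
(a) variant entries — the non-reference calls only — and (b) reference
blocks, half-open intervals ``[start, end)`` asserting homozygous-reference
state across their span.  A position covered by neither an entry nor a
block is *absent*: missing in storage terms.  Whether absent means
"missing" or "hom-ref" is a scoring-time policy, not a storage property,
so sparsifying a matrix loses nothing.

Serialization is a line-delimited, tab-separated text format (gz-transparent):

    ##prskit-sparse	v1
    S	<sample_id>                                     (one per sample, in order)
    E	<sample_id>	<chrom>	<pos>	<ref>	<alt1,alt2,...>	<a>/<b>
    B	<sample_id>	<chrom>	<start>	<end>	<min_quality>

Entry lines store non-hom-ref calls; block lines store reference blocks.
Order of E/B lines is free; reading re-sorts and re-validates invariants.
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InvariantError
from .genotypes import (
    MISSING,
    DenseGenotypeMatrix,
    GenotypeCall,
    VariantKey,
    chrom_sort_key,
)

#: GQ carried on reference blocks produced by sparsify(); carried through
#: serialization but never consulted by scoring.
DEFAULT_BLOCK_QUALITY = 30


@dataclass(frozen=True)
class ReferenceBlock:
    """Half-open hom-ref interval [start, end) on one chromosome."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # exclusive
    min_quality: int = DEFAULT_BLOCK_QUALITY

    def __post_init__(self) -> None:
        if self.start < 1:
            raise InvariantError(f"block start must be >= 1, got {self.start}")
        if not self.start < self.end:
            raise InvariantError(
                f"block [{self.start}, {self.end}) on {self.chrom} is empty/inverted"
            )

    def covers(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class SampleRecord:
    """One sample's sparse state: non-ref entries + hom-ref blocks."""

    entries: dict[VariantKey, GenotypeCall] = field(default_factory=dict)
    blocks: dict[str, list[ReferenceBlock]] = field(default_factory=dict)
    # caches rebuilt on validate()
    _pos_index: dict[tuple[str, int], tuple[VariantKey, GenotypeCall]] = field(
        default=None, repr=False, compare=False
    )
    _block_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )

    def validate(self) -> None:
        pos_index: dict[tuple[str, int], tuple[VariantKey, GenotypeCall]] = {}
        for key, call in self.entries.items():
            if call.is_hom_ref:
                raise InvariantError(
                    f"hom-ref call stored as entry at {key.chrom}:{key.pos}"
                )
            if call.is_missing:
                raise InvariantError(
                    f"missing call stored as entry at {key.chrom}:{key.pos}"
                )
            for allele in (call.allele_a, call.allele_b):
                if not 0 <= allele <= len(key.alts):
                    raise InvariantError(
                        f"allele index {allele} out of range at {key.chrom}:{key.pos}"
                    )
            pos_index[key.locus] = (key, call)
        block_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, blocks in self.blocks.items():
            blocks.sort(key=lambda b: b.start)
            prev_end = 0
            for b in blocks:
                if b.chrom != chrom:
                    raise InvariantError(
                        f"block chrom {b.chrom} filed under {chrom}"
                    )
                if b.start < prev_end:
                    raise InvariantError(
                        f"overlapping reference blocks on {chrom} at {b.start}"
                    )
                prev_end = b.end
            starts = np.array([b.start for b in blocks], dtype=np.int64)
            ends = np.array([b.end for b in blocks], dtype=np.int64)
            block_arrays[chrom] = (starts, ends)
        for (chrom, pos) in pos_index:
            if chrom in block_arrays:
                starts, ends = block_arrays[chrom]
                j = int(np.searchsorted(starts, pos, side="right")) - 1
                if j >= 0 and pos < ends[j]:
                    raise InvariantError(
                        f"reference block overlaps variant entry at {chrom}:{pos}"
                    )
        self._pos_index = pos_index
        self._block_arrays = block_arrays

    def call_at(self, chrom: str, pos: int) -> GenotypeCall:
        """Stored entry, else hom-ref if block-covered, else missing."""
        hit = self._pos_index.get((chrom, pos))
        if hit is not None:
            return hit[1]
        arrays = self._block_arrays.get(chrom)
        if arrays is not None:
            starts, ends = arrays
            j = bisect_right(starts, pos) - 1
            if j >= 0 and pos < ends[j]:
                return GenotypeCall(0, 0)
        return GenotypeCall(MISSING, MISSING)


@dataclass
class SparseVariantDataset:
    """Per-sample non-reference calls plus reference blocks."""

    sample_ids: list[str]
    records: list[SampleRecord]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.records):
            raise InvariantError("sample_ids and records length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvariantError("duplicate sample IDs")
        self.validate()

    def validate(self) -> None:
        for rec in self.records:
            rec.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def n_entries(self) -> int:
        return sum(len(r.entries) for r in self.records)

    def locus_keys(self, loci: list[tuple[str, int]]) -> list[VariantKey | None]:
        """For each locus, the stored VariantKey (consistent across samples),
        or None when no sample has an entry there."""
        keys: list[VariantKey | None] = [None] * len(loci)
        for rec in self.records:
            for i, locus in enumerate(loci):
                hit = rec._pos_index.get(locus)
                if hit is None:
                    continue
                if keys[i] is None:
                    keys[i] = hit[0]
                elif keys[i] != hit[0]:
                    raise InvariantError(
                        f"conflicting variant keys stored at {locus[0]}:{locus[1]}"
                    )
        return keys


def sparsify(dense: DenseGenotypeMatrix) -> SparseVariantDataset:
    """Convert a dense matrix to the sparse representation.

    Per sample: hom-ref calls become maximal merged reference blocks over
    exactly the hom-ref positions (contiguous positions merge); any other
    non-missing call becomes a variant entry; missing calls leave no trace.
    """
    records: list[SampleRecord] = []
    alleles = dense.alleles
    for si in range(dense.n_samples):
        entries: dict[VariantKey, GenotypeCall] = {}
        homref_pos: dict[str, list[int]] = {}
        col = alleles[:, si, :]
        for vi, key in enumerate(dense.variants):
            a, b = int(col[vi, 0]), int(col[vi, 1])
            if a < 0:
                continue
            if a == 0 and b == 0:
                homref_pos.setdefault(key.chrom, []).append(key.pos)
            else:
                entries[key] = GenotypeCall(a, b)
        blocks: dict[str, list[ReferenceBlock]] = {}
        for chrom, positions in homref_pos.items():
            positions = sorted(set(positions))
            merged: list[ReferenceBlock] = []
            start = prev = positions[0]
            for pos in positions[1:]:
                if pos == prev + 1:
                    prev = pos
                    continue
                merged.append(ReferenceBlock(chrom, start, prev + 1))
                start = prev = pos
            merged.append(ReferenceBlock(chrom, start, prev + 1))
            blocks[chrom] = merged
        records.append(SampleRecord(entries=entries, blocks=blocks))
    return SparseVariantDataset(list(dense.sample_ids), records)


def densify_at(
    vds: SparseVariantDataset, loci: list[tuple[str, int]]
) -> np.ndarray:
    """Materialise calls at the given (chrom, pos) loci for every sample.

    Returns an ``(n_loci, n_samples, 2)`` int16 array: the stored entry call
    where present, hom-ref ``(0, 0)`` where a reference block covers the
    position (half-open interval lookup, ``[pos, pos+1)``), else missing
    ``(-1, -1)``.  Batch lookup is exactly equivalent to per-locus lookup.
    """
    loci = [(chrom, int(pos)) for chrom, pos in loci]
    n_loci = len(loci)
    out = np.full((n_loci, vds.n_samples, 2), MISSING, dtype=np.int16)
    by_chrom: dict[str, tuple[list[int], np.ndarray]] = {}
    for i, (chrom, pos) in enumerate(loci):
        by_chrom.setdefault(chrom, ([], None))[0].append(i)
    for chrom, (idx, _) in by_chrom.items():
        positions = np.array([loci[i][1] for i in idx], dtype=np.int64)
        by_chrom[chrom] = (idx, positions)
    for si, rec in enumerate(vds.records):
        for chrom, (idx, positions) in by_chrom.items():
            arrays = rec._block_arrays.get(chrom)
            if arrays is not None and arrays[0].size:
                starts, ends = arrays
                j = np.searchsorted(starts, positions, side="right") - 1
                covered = (j >= 0) & (positions < ends[np.clip(j, 0, None)])
                for k in np.nonzero(covered)[0]:
                    out[idx[k], si] = 0
        for i, locus in enumerate(loci):
            hit = rec._pos_index.get(locus)
            if hit is not None:
                out[i, si, 0] = hit[1].allele_a
                out[i, si, 1] = hit[1].allele_b
    return out


def _opener(path: str):
    return gzip.open if str(path).endswith(".gz") else open


_MAGIC = "##prskit-sparse"
_VERSION = "v1"


def write_sparse(vds: SparseVariantDataset, path: str) -> None:
    """Serialize to the line-delimited sparse text format (gz by suffix)."""
    with _opener(path)(str(path), "wt") as fh:
        fh.write(f"{_MAGIC}\t{_VERSION}\n")
        for sid in vds.sample_ids:
            fh.write(f"S\t{sid}\n")
        for sid, rec in zip(vds.sample_ids, vds.records):
            for key in sorted(rec.entries, key=VariantKey.sort_key):
                call = rec.entries[key]
                alts = ",".join(key.alts)
                fh.write(
                    f"E\t{sid}\t{key.chrom}\t{key.pos}\t{key.ref}\t{alts}\t"
                    f"{call.allele_a}/{call.allele_b}\n"
                )
            for chrom in sorted(rec.blocks, key=chrom_sort_key):
                for b in rec.blocks[chrom]:
                    fh.write(
                        f"B\t{sid}\t{b.chrom}\t{b.start}\t{b.end}\t{b.min_quality}\n"
                    )


def read_sparse(path: str) -> SparseVariantDataset:
    """Read the sparse text format; read(write(x)) == x field-for-field."""
    sample_ids: list[str] = []
    by_sample: dict[str, SampleRecord] = {}
    with _opener(path)(str(path), "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != _MAGIC:
            raise FormatError(f"{path}: not a prskit sparse file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag = fields[0]
            try:
                if tag == "S":
                    (sid,) = fields[1:]
                    if sid in by_sample:
                        raise FormatError(f"duplicate sample {sid!r}")
                    sample_ids.append(sid)
                    by_sample[sid] = SampleRecord()
                elif tag == "E":
                    sid, chrom, pos, ref, alts, gt = fields[1:]
                    a_str, b_str = gt.split("/")
                    key = VariantKey(chrom, int(pos), ref, tuple(alts.split(",")))
                    by_sample[sid].entries[key] = GenotypeCall(int(a_str), int(b_str))
                elif tag == "B":
                    sid, chrom, start, end, minq = fields[1:]
                    by_sample[sid].blocks.setdefault(chrom, []).append(
                        ReferenceBlock(chrom, int(start), int(end), int(minq))
                    )
                else:
                    raise FormatError(f"unknown record tag {tag!r}")
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed record: {exc}") from exc
    # constructor validates sorting/overlap/hom-ref invariants
    return SparseVariantDataset(sample_ids, [by_sample[s] for s in sample_ids])
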