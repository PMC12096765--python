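"""PRS weight tables in the PGS Catalog scoring-file dialect.

A scoring file is tab-separated: ``#``-prefixed ``key=value`` metadata
lines, then a header row, then one data row per score variant.  Harmonized
coordinate columns (``hm_chr``/``hm_pos``) are preferred over the
author-submitted ones (``chr_name``/``chr_position``) when both are
present, since the harmonized ones are the build-correct coordinates.

The annotation table maps a variant key (chrom, pos, ref, alt) to a QC-pass
flag and an allele frequency — a minimal stand-in for a full variant
annotation resource — and is used to restrict scoring to QC-passed
variants on the sparse path.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import EmptyTableError, FormatError, InvariantError
from .genotypes import normalize_chrom

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


def _is_allele(tok: str) -> bool:
    return bool(tok) and set(tok) <= _VALID_BASES


@dataclass(frozen=True)
class ScoreVariant:
    """One weight-table row: where the variant is, which allele the weight
    applies to (the *effect allele*), and the per-allele weight."""

    score_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str | None
    weight: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvariantError(f"position must be >= 1, got {self.pos}")
        if not _is_allele(self.effect_allele):
            raise InvariantError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele is not None:
            if not _is_allele(self.other_allele):
                raise InvariantError(f"invalid other allele {self.other_allele!r}")
            if self.other_allele == self.effect_allele:
                raise InvariantError(
                    f"effect and other allele identical at {self.chrom}:{self.pos}"
                )
        if not (self.weight == self.weight and abs(self.weight) != float("inf")):
            raise InvariantError(f"non-finite weight at {self.chrom}:{self.pos}")

    @property
    def dedup_key(self):
        return (self.chrom, self.pos, self.effect_allele, self.other_allele)


@dataclass
class WeightTable:
    """One PRS model: ordered score variants sharing a score accession.

    ``n_raw_rows``/``n_dropped``/``n_duplicates`` carry parse accounting so
    ``n_raw_rows == len(variants) + n_dropped + n_duplicates`` always holds
    for tables produced by :func:`read_pgs_scoring_file`.
    """

    score_id: str
    genome_build: str
    variants: list[ScoreVariant] = field(default_factory=list)
    n_raw_rows: int = 0
    n_dropped: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for v in self.variants:
            if v.score_id != self.score_id:
                raise InvariantError(
                    f"variant score_id {v.score_id!r} != table {self.score_id!r}"
                )
            if v.dedup_key in seen:
                raise InvariantError(f"duplicate score variant {v.dedup_key}")
            seen.add(v.dedup_key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def loci(self) -> list[tuple[str, int]]:
        return [(v.chrom, v.pos) for v in self.variants]


@dataclass
class AnnotationTable:
    """Variant key -> {passed_qc, allele_freq} lookup.

    Serves two purposes on the sparse scoring path: restricting weights to
    QC-passed variants, and orienting alleles (its keys carry which allele
    is the genomic REF) at loci where the sparse store has no entry.
    """

    entries: dict[tuple[str, int, str, str], dict]

    def __post_init__(self) -> None:
        for key, rec in self.entries.items():
            af = rec["allele_freq"]
            if not 0.0 <= af <= 1.0:
                raise InvariantError(f"allele_freq {af} outside [0, 1] for {key}")
        self._locus_index: dict[tuple[str, int], tuple[str, str]] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def ref_alt_at(self, chrom: str, pos: int) -> tuple[str, str] | None:
        """(ref, alt) annotated at a locus, or None if unannotated.

        With several annotated alt alleles at one locus the first entry in
        table order is returned; all share the same REF.
        """
        if self._locus_index is None:
            idx: dict[tuple[str, int], tuple[str, str]] = {}
            for (c, p, ref, alt) in self.entries:
                idx.setdefault((c, p), (ref, alt))
            self._locus_index = idx
        return self._locus_index.get((chrom, pos))

    def passes_qc(
        self, chrom: str, pos: int, effect_allele: str, other_allele: str | None
    ) -> bool:
        """True if a QC-passed annotation key matches the variant.

        The annotation key orientation (which allele is REF) is not knowable
        from the weight table alone, so both orientations are tried:
        (other as REF, effect as ALT) and the swap.  With no other_allele,
        any passed key at the locus mentioning the effect allele counts.
        """
        if other_allele is not None:
            for ref, alt in ((other_allele, effect_allele), (effect_allele, other_allele)):
                rec = self.entries.get((chrom, pos, ref, alt))
                if rec is not None and rec["passed_qc"]:
                    return True
            return False
        for (c, p, ref, alt), rec in self.entries.items():
            if (
                c == chrom
                and p == pos
                and effect_allele in (ref, alt)
                and rec["passed_qc"]
            ):
                return True
        return False

    @classmethod
    def from_tsv(cls, path: str) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"chrom", "pos", "ref", "alt", "passed_qc", "allele_freq"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"annotation table missing columns: {sorted(missing)}")
        entries = {}
        for row in df.itertuples(index=False):
            key = (normalize_chrom(row.chrom), int(row.pos), row.ref, row.alt)
            entries[key] = {
                "passed_qc": str(row.passed_qc).lower() in ("1", "true", "t", "yes"),
                "allele_freq": float(row.allele_freq),
            }
        return cls(entries)

    def to_tsv(self, path: str) -> None:
        rows = [
            {
                "chrom": c,
                "pos": p,
                "ref": r,
                "alt": a,
                "passed_qc": int(rec["passed_qc"]),
                "allele_freq": f"{rec['allele_freq']:.6g}",
            }
            for (c, p, r, a), rec in self.entries.items()
        ]
        pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "passed_qc", "allele_freq"]
        ).to_csv(path, sep="\t", index=False)


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(str(path), "rb"), encoding="utf-8")
    return open(str(path), "rt", encoding="utf-8")


def read_pgs_scoring_file(path: str, expected_build: str | None = None) -> WeightTable:
    """Parse a PGS Catalog scoring file into a :class:`WeightTable`.

    Parameters
    ----------
    path
        Tab-separated scoring file, plain or gzipped.
    expected_build
        Genome build the caller intends to score against (e.g. "GRCh38").
        A metadata build that disagrees triggers a warning, not an error —
        coordinates may still be usable via the harmonized columns.

    Rows with an unparseable weight or position are dropped and counted in
    ``n_dropped``; duplicate (chrom, pos, effect, other) rows keep the first
    occurrence and count in ``n_duplicates``.
    """
    metadata: dict[str, str] = {}
    header_and_data: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not header_and_data and line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    metadata[k.strip()] = v.strip()
                continue
            if line:
                header_and_data.append(line)
    if not header_and_data:
        raise FormatError(f"{path}: no header row found")
    df = pd.read_csv(
        io.StringIO("\n".join(header_and_data)), sep="\t", dtype=str, keep_default_na=False
    )
    cols = set(df.columns)
    if "effect_allele" not in cols or "effect_weight" not in cols:
        raise FormatError(
            f"{path}: required columns missing "
            f"(need effect_allele and effect_weight; found {sorted(cols)})"
        )
    if {"hm_chr", "hm_pos"} <= cols:
        chr_col, pos_col = "hm_chr", "hm_pos"
    elif {"chr_name", "chr_position"} <= cols:
        chr_col, pos_col = "chr_name", "chr_position"
    else:
        raise FormatError(
            f"{path}: no coordinate columns (need hm_chr/hm_pos or "
            "chr_name/chr_position)"
        )
    other_col = next(
        (c for c in ("other_allele", "hm_inferOtherAllele", "reference_allele") if c in cols),
        None,
    )
    score_id = metadata.get("pgs_id", metadata.get("pgs_name", "UNKNOWN"))
    build = metadata.get(
        "HmPOS_build", metadata.get("genome_build", metadata.get("Hm_genome_build", ""))
    )
    if expected_build and build and build != expected_build:
        warnings.warn(
            f"{path}: genome build {build!r} differs from expected "
            f"{expected_build!r}",
            stacklevel=2,
        )

    variants: list[ScoreVariant] = []
    seen: set[tuple] = set()
    n_dropped = 0
    n_duplicates = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        try:
            pos = int(float(row[pos_col]))
            weight = float(row["effect_weight"])
            other = row.get(other_col) if other_col else None
            if other is not None and not _is_allele(str(other)):
                other = None
            sv = ScoreVariant(
                score_id=score_id,
                chrom=normalize_chrom(row[chr_col]),
                pos=pos,
                effect_allele=str(row["effect_allele"]).strip(),
                other_allele=other,
                weight=weight,
            )
        except (ValueError, KeyError, InvariantError, FormatError):
            n_dropped += 1
            continue
        if sv.dedup_key in seen:
            n_duplicates += 1
            continue
        seen.add(sv.dedup_key)
        variants.append(sv)
    if n_duplicates:
        warnings.warn(
            f"{path}: {n_duplicates} duplicate weight row(s); kept first occurrence",
            stacklevel=2,
        )
    if not variants:
        raise EmptyTableError(f"{path}: zero usable weight rows (of {len(df)})")
    wt = WeightTable(
        score_id=score_id,
        genome_build=build,
        variants=variants,
        n_raw_rows=len(df),
        n_dropped=n_dropped,
        n_duplicates=n_duplicates,
    )
    logger.info(
        "parsed %s: %d raw rows -> %d variants (%d dropped, %d duplicates)",
        path, wt.n_raw_rows, len(wt), n_dropped, n_duplicates,
    )
    return wt


def write_pgs_scoring_file(wt: WeightTable, path: str) -> None:
    """Serialize a WeightTable back to the scoring-file dialect.

    Uses harmonized coordinate columns; read(write(wt)) reproduces the
    table field-for-field (weights at full precision via repr round-trip).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("### PGS scoring file (prskit dialect)\n")
        fh.write(f"#pgs_id={wt.score_id}\n")
        fh.write(f"#HmPOS_build={wt.genome_build}\n")
        fh.write("hm_chr\thm_pos\teffect_allele\tother_allele\teffect_weight\n")
        for v in wt.variants:
            other = v.other_allele if v.other_allele is not None else ""
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.effect_allele}\t{other}\t{v.weight!r}\n"
            )


def filter_weights_by_annotation(
    wt: WeightTable, ann: AnnotationTable
) -> WeightTable:
    """Restrict a weight table to variants whose key passes QC annotation.

    Retains exactly the score variants with a QC-passed annotation entry in
    either allele orientation; the output is always a subset of the input
    and the operation is idempotent.  An empty result is returned (with a
    warning), never raised.
    """
    kept = [
        v
        for v in wt.variants
        if ann.passes_qc(v.chrom, v.pos, v.effect_allele, v.other_allele)
    ]
    n_removed = len(wt.variants) - len(kept)
    logger.info(
        "annotation filter: %d of %d variants retained (%d removed)",
        len(kept), len(wt.variants), n_removed,
    )
    if not kept:
        warnings.warn(
            f"annotation filter removed all {len(wt.variants)} variants",
            stacklevel=2,
        )
    return WeightTable(
        score_id=wt.score_id,
        genome_build=wt.genome_build,
        variants=kept,
        n_raw_rows=wt.n_raw_rows,
        n_dropped=wt.n_dropped,
        n_duplicates=wt.n_duplicates,
    )
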