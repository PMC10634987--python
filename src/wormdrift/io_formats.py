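"""Readers, writers, and interval algebra for the comparison pipeline.

Standard formats handled here: FASTA (Bio.SeqIO), VCF 4.x (pysam), GFF3
(gffutils), BED6, SyRI-style structural-variant TSVs, and the gap-free
alignment-block TSV that underlies coordinate liftover.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open.  Conversion to and from
1-based systems happens only at the VCF/GFF3/SV-table boundaries:

* VCF / GFF3 are 1-based inclusive, as their specifications require.
* SV tables are read in the 1-based inclusive dialect of SyRI-like callers
  and converted on load.
* BED and the alignment-block TSV are already 0-based half-open.

The indel-interval convention is the reference span of the REF allele:
a deletion ``POS=100 REF=ATTT ALT=A`` covers ``[99, 103)``; an insertion
contributes only its 1-bp anchor base.  This is a documented choice; the
base-accurate alternative conventions differ only by the anchor base.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

logger = logging.getLogger(__name__)

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
UNKNOWN = "unknown"

#: Closed vocabulary of structural-variant type codes (SyRI-style), plus the
#: highly-divergent-region and syntenic categories that travel in the same
#: tables.
SV_TYPES = frozenset(
    {"NOTAL", "DEL", "INS", "CPG", "CPL", "TDM", "INV", "DUP", "TRANS", "INVTR", "HDR", "SYN"}
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Core interval type and algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named chromosome.

    Zero-length intervals (``start == end``) are permitted so that boundary
    cases such as an empty chromosome center can be represented.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:[{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, non-overlapping list (touching spans merge)."""
    ivs = sorted(iv for iv in intervals if len(iv) > 0)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def complement_intervals(
    intervals: Iterable[GenomicInterval], chrom: str, length: int
) -> list[GenomicInterval]:
    """Complement of the union of ``intervals`` within ``[0, length)`` on ``chrom``."""
    merged = [iv for iv in merge_intervals(intervals) if iv.chrom == chrom]
    out: list[GenomicInterval] = []
    cursor = 0
    for iv in merged:
        if iv.end > length or iv.start < 0:
            raise ValueError(f"interval {iv} extends beyond {chrom} length {length}")
        if iv.start > cursor:
            out.append(GenomicInterval(chrom, cursor, iv.start))
        cursor = max(cursor, iv.end)
    if cursor < length:
        out.append(GenomicInterval(chrom, cursor, length))
    return out


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One VCF row: a SNP or indel call of the query genome against the reference.

    ``pos`` is 1-based as in VCF.  Depth fields may be ``None`` when the VCF
    lacked them; such records fail the default quality filter (fail closed).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float | None = None
    alt_depth: int | None = None
    total_depth: int | None = None
    genotype_class: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if (
            self.alt_depth is not None
            and self.total_depth is not None
            and self.alt_depth > self.total_depth
        ):
            raise ValueError("alt_depth cannot exceed total_depth")

    @property
    def var_class(self) -> str:
        """``snp`` iff both alleles are single bases, else ``indel``."""
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "snp"
        return "indel"

    @property
    def pos0(self) -> int:
        """0-based position of the first REF base."""
        return self.pos - 1


@dataclass(frozen=True)
class VariantFilter:
    """Quality filter for short-read variant calls.

    Defaults retain calls with QUAL >= 30, at least 10 reads supporting the
    alternate allele, and at least 30 total high-quality reads; by default
    only homozygous calls are kept, mirroring comparisons restricted to
    sites where the query strain is homozygous.
    """

    min_qual: float = 30.0
    min_alt_reads: int = 10
    min_total_reads: int = 30
    homozygous_only: bool = True

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_alt_reads < 0 or self.min_total_reads < 0:
            raise ValueError("filter thresholds must be >= 0")

    def passes(self, rec: VariantRecord) -> bool:
        if rec.qual is None or rec.qual < self.min_qual:
            return False
        if rec.alt_depth is None or rec.alt_depth < self.min_alt_reads:
            return False
        if rec.total_depth is None or rec.total_depth < self.min_total_reads:
            return False
        if self.homozygous_only and rec.genotype_class != HOMOZYGOUS:
            return False
        return True


def filter_variants(
    records: Iterable[VariantRecord], flt: VariantFilter | None = None
) -> list[VariantRecord]:
    """Retain records passing the quality filter; order preserved, idempotent."""
    flt = flt or VariantFilter()
    return [r for r in records if flt.passes(r)]


def split_variants(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition records into (snps, indels), each order-preserving."""
    snps, indels = [], []
    for r in records:
        (snps if r.var_class == "snp" else indels).append(r)
    return snps, indels


def indel_intervals(records: Iterable[VariantRecord]) -> dict[str, list[GenomicInterval]]:
    """Reference spans of indel REF alleles, per chromosome, sorted.

    An indel at POS covers ``[POS-1, POS-1+len(REF))``; insertions therefore
    contribute only their 1-bp anchor.  SNP records are rejected: callers
    must pre-split with :func:`split_variants`.
    """
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for r in records:
        if r.var_class != "indel":
            raise ValueError(
                f"snp record at {r.chrom}:{r.pos} passed to indel_intervals; pre-split variants"
            )
        per_chrom.setdefault(r.chrom, []).append(
            GenomicInterval(r.chrom, r.pos0, r.pos0 + len(r.ref_allele))
        )
    return {c: sorted(per_chrom[c]) for c in sorted(per_chrom)}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: uppercase sequence}`` map."""
    genome: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if rec.id in genome:
            raise FormatError(f"duplicate FASTA record '{rec.id}' in {path}")
        genome[rec.id] = str(rec.seq).upper()
    if n == 0:
        raise FormatError(f"empty FASTA file: {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    del width  # Bio.SeqIO wraps at its own default width


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# VCF (via pysam)
# ---------------------------------------------------------------------------


def _genotype_class(gt: tuple | None) -> str:
    if gt is None or any(a is None for a in gt):
        return UNKNOWN
    alleles = set(gt)
    if alleles == {1} or (len(alleles) == 1 and alleles != {0}):
        return HOMOZYGOUS
    if len(alleles) > 1:
        return HETEROZYGOUS
    return UNKNOWN


def read_vcf(path: str | os.PathLike) -> list[VariantRecord]:
    """Parse a VCF 4.x file into :class:`VariantRecord` objects.

    QUAL, the sample AD/DP fields, and the genotype are carried through;
    missing depth annotations are parsed as ``None`` and fail the default
    filter.  Multi-allelic rows are rejected (the pipeline's callers emit
    biallelic rows only).
    """
    import pysam

    records: list[VariantRecord] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for i, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
            try:
                if rec.alts is None or len(rec.alts) != 1:
                    raise ValueError("expected exactly one ALT allele")
                alt_depth = total_depth = None
                gclass = UNKNOWN
                if len(rec.samples) >= 1:
                    sample = rec.samples[0]
                    ad = sample.get("AD")
                    if ad is not None and len(ad) >= 2 and ad[1] is not None:
                        alt_depth = int(ad[1])
                    dp = sample.get("DP")
                    if dp is not None:
                        total_depth = int(dp)
                    gclass = _genotype_class(sample.get("GT"))
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=rec.alts[0],
                        qual=rec.qual,
                        alt_depth=alt_depth,
                        total_depth=total_depth,
                        genotype_class=gclass,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"malformed VCF record #{i} in {path}: {exc}") from exc
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | os.PathLike,
    contigs: dict[str, int],
    sample: str = "QUERY",
) -> None:
    """Write biallelic records as VCF 4.2 with GT/AD/DP sample fields."""
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total high-quality read depth")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (list(contigs).index(r.chrom), r.pos)):
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos0,
                alleles=(r.ref_allele, r.alt_allele),
                qual=r.qual,
            )
            gt = (1, 1) if r.genotype_class == HOMOZYGOUS else (0, 1)
            rec.samples[sample]["GT"] = gt
            if r.alt_depth is not None and r.total_depth is not None:
                rec.samples[sample]["AD"] = (r.total_depth - r.alt_depth, r.alt_depth)
            if r.total_depth is not None:
                rec.samples[sample]["DP"] = r.total_depth
            out.write(rec)


# ---------------------------------------------------------------------------
# Genes / GFF3 and annotation interval algebra
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    """A gene span with its exon and UTR substructure (all 0-based half-open)."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utrs: list[GenomicInterval] = field(default_factory=list)
    strand: str = "+"


def write_gff3(genes: Sequence[Gene], path: str | os.PathLike, source: str = "wormdrift") -> None:
    """Write genes with exon/UTR children as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for kind, ivs in (("exon", g.exons), ("UTR", g.utrs)):
                for j, sub in enumerate(ivs):
                    fh.write(
                        f"{sub.chrom}\t{source}\t{kind}\t{sub.start + 1}\t{sub.end}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.{kind.lower()}{j};Parent={g.gene_id}\n"
                    )


def read_gff3(path: str | os.PathLike) -> list[Gene]:
    """Read genes with exon/UTR children from GFF3 via gffutils."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
    genes: list[Gene] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene = Gene(
            gene_id=feat.id,
            interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end),
            strand=feat.strand if feat.strand in "+-" else "+",
        )
        for child in db.children(feat, order_by="start"):
            sub = GenomicInterval(child.seqid, child.start - 1, child.end)
            ftype = child.featuretype.lower()
            if ftype == "exon":
                gene.exons.append(sub)
            elif "utr" in ftype:
                gene.utrs.append(sub)
        genes.append(gene)
    return genes


def derive_introns(
    genes: Sequence[GenomicInterval],
    exons: Sequence[GenomicInterval],
    utrs: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Intronic intervals: per gene, the gene span minus its exon and UTR union.

    Exons and UTRs are associated with genes by containment (gene spans are
    assumed non-overlapping).  A feature that overlaps a gene but extends
    beyond it raises an error naming the gene.  A gene with no exon or UTR
    features is emitted whole as a single intron, with a warning.
    """
    features = list(exons) + list(utrs)
    introns: list[GenomicInterval] = []
    for gene in genes:
        mine = []
        for f in features:
            if f.overlaps(gene):
                if not gene.contains(f):
                    raise ValueError(
                        f"feature {f.chrom}:[{f.start},{f.end}) extends beyond gene "
                        f"{gene.chrom}:[{gene.start},{gene.end})"
                    )
                mine.append(f)
        if not mine:
            logger.warning(
                "gene %s:[%d,%d) has no exon/UTR features; emitting whole span as intron",
                gene.chrom,
                gene.start,
                gene.end,
            )
            introns.append(gene)
            continue
        covered = merge_intervals(mine)
        cursor = gene.start
        for iv in covered:
            if iv.start > cursor:
                introns.append(GenomicInterval(gene.chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < gene.end:
            introns.append(GenomicInterval(gene.chrom, cursor, gene.end))
    return sorted(introns)


def derive_intergenic(
    genes: Sequence[GenomicInterval], chrom_lengths: dict[str, int]
) -> list[GenomicInterval]:
    """Per chromosome, the complement of the union of gene intervals."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_lengths}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene chromosome {g.chrom} missing from chromosome lengths")
        if g.end > chrom_lengths[g.chrom]:
            raise ValueError(
                f"gene {g.chrom}:[{g.start},{g.end}) beyond chromosome end "
                f"{chrom_lengths[g.chrom]}"
            )
        by_chrom[g.chrom].append(g)
    for chrom, length in chrom_lengths.items():
        out.extend(complement_intervals(by_chrom[chrom], chrom, length))
    return out


# ---------------------------------------------------------------------------
# Structural variants and alignment blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SVRecord:
    """A structural variant / HDR row, internally 0-based half-open.

    ``qry_interval`` is absent for one-sided NOTAL records; the query-side
    complement is obtained from the reciprocal table produced with reference
    and query swapped.
    """

    sv_type: str
    ref_interval: GenomicInterval
    qry_interval: GenomicInterval | None
    size: int

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type code '{self.sv_type}'")
        if self.sv_type != "SYN" and self.size < 50:
            raise ValueError(
                f"{self.sv_type} at {self.ref_interval.chrom}:{self.ref_interval.start} "
                f"has size {self.size} < 50"
            )


_SV_COLUMNS = [
    "type",
    "ref_chrom",
    "ref_start1",
    "ref_end1",
    "qry_chrom",
    "qry_start1",
    "qry_end1",
]


def read_sv_table(path: str | os.PathLike) -> list[SVRecord]:
    """Read a SyRI-style SV/HDR TSV (1-based inclusive) into internal records.

    ``size`` is the larger of the reference and query spans in the 1-based
    inclusive dialect (``end - start + 1``), which makes deletions
    reference-sized and insertions query-sized.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SV table {path} missing columns: {missing}")
    out: list[SVRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        code = str(row.type)
        if code not in SV_TYPES:
            raise FormatError(f"unknown SV type code '{code}' at line {i} of {path}")
        ref = GenomicInterval(str(row.ref_chrom), int(row.ref_start1) - 1, int(row.ref_end1))
        qry = None
        if str(row.qry_chrom) not in (".", "-", "nan"):
            qry = GenomicInterval(str(row.qry_chrom), int(row.qry_start1) - 1, int(row.qry_end1))
        size = max(len(ref), len(qry) if qry else 0)
        try:
            out.append(SVRecord(code, ref, qry, size))
        except ValueError as exc:
            raise FormatError(f"invalid SV record at line {i} of {path}: {exc}") from exc
    return out


def write_sv_table(records: Sequence[SVRecord], path: str | os.PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "type": r.sv_type,
                "ref_chrom": r.ref_interval.chrom,
                "ref_start1": r.ref_interval.start + 1,
                "ref_end1": r.ref_interval.end,
                "qry_chrom": r.qry_interval.chrom if r.qry_interval else ".",
                "qry_start1": r.qry_interval.start + 1 if r.qry_interval else ".",
                "qry_end1": r.qry_interval.end if r.qry_interval else ".",
            }
        )
    pd.DataFrame(rows, columns=_SV_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AlignmentBlock:
    """A gap-free syntenic mapping between reference and query coordinates.

    Under the gap-free model the two sides have equal length; a ``-`` strand
    block maps reference base ``ref.start + i`` to query base
    ``qry.end - 1 - i``.
    """

    ref: GenomicInterval
    qry: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.ref) != len(self.qry):
            raise ValueError(
                f"alignment block sides differ in length: {self.ref} vs {self.qry}"
            )


_BLOCK_COLUMNS = [
    "ref_chrom",
    "ref_start0",
    "ref_end0",
    "qry_chrom",
    "qry_start0",
    "qry_end0",
    "strand",
]


def read_alignment_blocks(path: str | os.PathLike) -> list[AlignmentBlock]:
    """Read the PAF-like block TSV; blocks are validated non-overlapping on the
    reference and returned sorted by reference coordinate."""
    df = pd.read_csv(path, sep="\t", dtype={"strand": str})
    missing = [c for c in _BLOCK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"alignment-block table {path} missing columns: {missing}")
    blocks = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            blocks.append(
                AlignmentBlock(
                    GenomicInterval(str(row.ref_chrom), int(row.ref_start0), int(row.ref_end0)),
                    GenomicInterval(str(row.qry_chrom), int(row.qry_start0), int(row.qry_end0)),
                    str(row.strand),
                )
            )
        except ValueError as exc:
            raise FormatError(f"invalid alignment block at line {i} of {path}: {exc}") from exc
    blocks.sort(key=lambda b: (b.ref.chrom, b.ref.start))
    for a, b in zip(blocks, blocks[1:]):
        if a.ref.chrom == b.ref.chrom and b.ref.start < a.ref.end:
            raise FormatError(
                f"alignment blocks overlap on reference: {a.ref} and {b.ref} in {path}"
            )
    return blocks


def write_alignment_blocks(blocks: Sequence[AlignmentBlock], path: str | os.PathLike) -> None:
    rows = [
        {
            "ref_chrom": b.ref.chrom,
            "ref_start0": b.ref.start,
            "ref_end0": b.ref.end,
            "qry_chrom": b.qry.chrom,
            "qry_start0": b.qry.start,
            "qry_end0": b.qry.end,
            "strand": b.strand,
        }
        for b in sorted(blocks, key=lambda b: (b.ref.chrom, b.ref.start))
    ]
    pd.DataFrame(rows, columns=_BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
    strands: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED6 (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"feature{i}"
            strand = strands[i] if strands else "+"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def read_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, str, str]]:
    """Read BED (3-6 columns) as ``(interval, name, strand)`` tuples."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {i} of {path} has fewer than 3 columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise FormatError(f"invalid BED line {i} of {path}: {exc}") from exc
            name = parts[3] if len(parts) > 3 else f"feature{i}"
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((iv, name, strand))
    return out
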