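"""Fingerprinting and tracking of transposable elements between two assemblies.

The core idea: a TE family has many near-identical copies, so the copy
itself cannot be tracked by sequence alone.  But SNPs called between the
two genomes that fall *inside* a reference TE copy, once substituted into
that copy's sequence, yield a "fingerprint" that is usually unique to the
copy.  Searching the query genome's TE annotations for that exact
fingerprint locates the same element in the other assembly.  Comparing the
located query position with the position *expected* from the whole-genome
alignment (liftover through syntenic blocks) then classifies each element
as unmoved, moved within its chromosome, moved between chromosomes, or
duplicated in the query genome.

Movement classification
-----------------------
* ``duplicated_in_query`` - the fingerprint matched more than one query TE.
* ``unresolvable``        - no defensible expected position exists (the
  reference start falls in a divergent alignment gap).
* ``interchromosomal``    - the matched query TE sits on a different
  chromosome than the liftover target.
* ``intrachromosomal``    - same chromosome but displaced by more than
  ``tolerance_bp`` from the expected position.
* ``unmoved``             - within tolerance of the expected position.

A TE that was excised from its locus in the query genome leaves a clean
deletion gap in the gap-free block model: the flanking blocks are on the
same query chromosome, on the forward strand, and query-adjacent.  For
such gaps the expected position is the junction point between the flanks.
Gaps whose flanks are *not* collinear (non-alignable regions, strand
switches, translocation breakpoints) give no defensible expectation and
yield ``unresolvable``.
"""

from __future__ import annotations

import bisect
import os
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import CoordinateMismatchError
from .io_formats import (
    AlignmentBlock,
    GenomicInterval,
    VariantRecord,
    read_bed,
    reverse_complement,
    write_bed,
)

TE_FAMILIES = frozenset(
    {"Tc1/mariner", "Zator", "Sola", "hAT", "CMC", "MITE", "Novosib", "Helitron", "other"}
)

CALL_UNMOVED = "unmoved"
CALL_INTRA = "intrachromosomal"
CALL_INTER = "interchromosomal"
CALL_DUP = "duplicated_in_query"
CALL_UNRESOLVABLE = "unresolvable"


@dataclass(frozen=True)
class TEAnnotation:
    """One TE copy: location, family, and reference-strand sequence."""

    te_id: str
    chrom: str
    interval: GenomicInterval
    strand: str
    family: str
    te_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.family not in TE_FAMILIES:
            raise ValueError(f"unknown TE family {self.family!r}")
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"TE {self.te_id}: sequence length {len(self.sequence)} != span "
                f"length {len(self.interval)}"
            )

    @property
    def start(self) -> int:
        return self.interval.start


@dataclass(frozen=True)
class FingerprintedTE:
    """A reference TE with overlapping SNP alleles substituted into its sequence."""

    te: TEAnnotation
    applied_snps: tuple[tuple[int, str, str], ...]  # (offset, ref_base, alt_base)
    fingerprint: str
    is_unique: bool


@dataclass(frozen=True)
class TEMatch:
    """A fingerprint located in the query TE set (possibly at several copies)."""

    ref_te_id: str
    query_te_ids: tuple[str, ...]
    identity: float

    def __post_init__(self) -> None:
        if not self.query_te_ids:
            raise ValueError("a TEMatch must name at least one query TE")
        if not 0 <= self.identity <= 1:
            raise ValueError(f"identity must be in [0,1], got {self.identity}")


@dataclass(frozen=True)
class MovementCall:
    ref_te_id: str
    call: str
    observed_qry_chrom: str
    observed_qry_pos: int
    expected_qry_chrom: str | None = None
    expected_qry_pos: int | None = None
    displacement: int | None = None
    family: str = "other"
    n_query_copies: int = 1


@dataclass(frozen=True)
class TrackingConfig:
    """Tunable parameters of the tracking procedure.

    ``tolerance_bp`` is the displacement below which a same-chromosome TE is
    considered unmoved (alignment jitter, not transposition).
    ``min_identity = 1.0`` demands exact fingerprint matches.
    """

    tolerance_bp: int = 1_000
    min_identity: float = 1.0
    same_family_only: bool = True
    try_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if self.tolerance_bp < 0:
            raise ValueError("tolerance_bp must be >= 0")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


# ---------------------------------------------------------------------------
# Fingerprinting
# ---------------------------------------------------------------------------


def fingerprint_tes(
    tes: Sequence[TEAnnotation],
    snps: Iterable[VariantRecord],
    same_family_only: bool = True,
) -> list[FingerprintedTE]:
    """Substitute overlapping SNP alt alleles into reference TE sequences.

    Only TEs overlapping at least one SNP are emitted.  ``is_unique`` marks
    fingerprints whose string occurs exactly once in the emitted multiset
    (evaluated within each family when ``same_family_only``).  A SNP whose
    REF base disagrees with the TE sequence at that offset signals that the
    annotations and genome are out of register and raises
    :class:`CoordinateMismatchError`.
    """
    by_chrom: dict[str, list[VariantRecord]] = defaultdict(list)
    for s in snps:
        if s.var_class == "snp":
            by_chrom[s.chrom].append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.pos0)

    out: list[FingerprintedTE] = []
    for te in tes:
        chrom_snps = by_chrom.get(te.chrom, [])
        positions = [s.pos0 for s in chrom_snps]
        lo = bisect.bisect_left(positions, te.interval.start)
        hi = bisect.bisect_left(positions, te.interval.end)
        hits = chrom_snps[lo:hi]
        if not hits:
            continue
        seq = list(te.sequence)
        applied = []
        for s in hits:
            offset = s.pos0 - te.interval.start
            if seq[offset] != s.ref_allele:
                raise CoordinateMismatchError(
                    f"SNP at {s.chrom}:{s.pos} REF={s.ref_allele} disagrees with TE "
                    f"{te.te_id} base {seq[offset]!r} at offset {offset}"
                )
            seq[offset] = s.alt_allele
            applied.append((offset, s.ref_allele, s.alt_allele))
        out.append(
            FingerprintedTE(
                te=te,
                applied_snps=tuple(applied),
                fingerprint="".join(seq),
                is_unique=False,  # filled below
            )
        )

    counts: Counter = Counter()
    for fp in out:
        key = (fp.te.family, fp.fingerprint) if same_family_only else fp.fingerprint
        counts[key] += 1
    return [
        FingerprintedTE(
            te=fp.te,
            applied_snps=fp.applied_snps,
            fingerprint=fp.fingerprint,
            is_unique=counts[
                (fp.te.family, fp.fingerprint) if same_family_only else fp.fingerprint
            ]
            == 1,
        )
        for fp in out
    ]


def sequence_identity(a: str, b: str) -> float:
    """Matching positions over the shorter length, divided by the longer length.

    Equal-length strings reduce to 1 - Hamming/len; unequal lengths are
    penalized by the length difference.
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    matches = sum(1 for x, y in zip(short, long_) if x == y)
    return matches / len(long_)


def match_fingerprints(
    fps: Sequence[FingerprintedTE],
    query_tes: Sequence[TEAnnotation],
    config: TrackingConfig | None = None,
) -> list[TEMatch]:
    """Locate each unique fingerprint among the query genome's TE sequences.

    All query TEs reaching ``min_identity`` are listed (multiplicity feeds
    duplication calls).  With ``try_reverse_complement`` the reverse
    complement of each query sequence is also tried and the better
    orientation kept.  Fingerprints without any qualifying query TE are
    absent from the output.
    """
    config = config or TrackingConfig()
    fps = [fp for fp in fps if fp.is_unique]

    def candidates(fp: FingerprintedTE) -> Iterable[TEAnnotation]:
        if config.same_family_only:
            return by_family.get(fp.te.family, ())
        return query_tes

    by_family: dict[str, list[TEAnnotation]] = defaultdict(list)
    for q in query_tes:
        by_family[q.family].append(q)

    # Exact matching uses a hash lookup; sub-identity matching scans.
    exact = config.min_identity == 1.0
    if exact:
        index: dict[tuple, list[TEAnnotation]] = defaultdict(list)
        for q in query_tes:
            fam = q.family if config.same_family_only else None
            index[(fam, q.sequence)].append(q)
            if config.try_reverse_complement:
                rc = reverse_complement(q.sequence)
                if rc != q.sequence:
                    index[(fam, rc)].append(q)

    matches: list[TEMatch] = []
    for fp in fps:
        fam = fp.te.family if config.same_family_only else None
        if exact:
            hits = index.get((fam, fp.fingerprint), [])
            seen: dict[str, TEAnnotation] = {q.te_id: q for q in hits}
            if seen:
                matches.append(TEMatch(fp.te.te_id, tuple(sorted(seen)), 1.0))
            continue
        best: dict[str, float] = {}
        for q in candidates(fp):
            ident = sequence_identity(fp.fingerprint, q.sequence)
            if config.try_reverse_complement:
                ident = max(ident, sequence_identity(fp.fingerprint, reverse_complement(q.sequence)))
            if ident >= config.min_identity:
                best[q.te_id] = ident
        if best:
            matches.append(TEMatch(fp.te.te_id, tuple(sorted(best)), max(best.values())))
    return matches


# ---------------------------------------------------------------------------
# Liftover
# ---------------------------------------------------------------------------


class _BlockIndex:
    def __init__(self, blocks: Sequence[AlignmentBlock]):
        self.by_chrom: dict[str, list[AlignmentBlock]] = defaultdict(list)
        for b in blocks:
            self.by_chrom[b.ref.chrom].append(b)
        self.starts: dict[str, list[int]] = {}
        for chrom, lst in self.by_chrom.items():
            lst.sort(key=lambda b: b.ref.start)
            for a, b in zip(lst, lst[1:]):
                if b.ref.start < a.ref.end:
                    raise ValueError(f"alignment blocks overlap on reference {chrom}")
            self.starts[chrom] = [b.ref.start for b in lst]

    def locate(self, chrom: str, pos: int) -> tuple[AlignmentBlock | None, int]:
        """Return (containing block or None, index of first block starting after pos)."""
        lst = self.by_chrom.get(chrom, [])
        if not lst:
            return None, 0
        i = bisect.bisect_right(self.starts[chrom], pos) - 1
        if i >= 0 and lst[i].ref.start <= pos < lst[i].ref.end:
            return lst[i], i + 1
        return None, i + 1


def liftover(
    chrom: str, pos: int, blocks: Sequence[AlignmentBlock] | _BlockIndex
) -> tuple[str, int] | None:
    """Map a reference position to query coordinates through syntenic blocks.

    Strand ``+``: ``qry_start + (pos - ref_start)``;
    strand ``-``: ``qry_start + (ref_end - 1 - pos)``.
    Positions in alignment gaps return ``None``.
    """
    index = blocks if isinstance(blocks, _BlockIndex) else _BlockIndex(blocks)
    block, _ = index.locate(chrom, pos)
    if block is None:
        return None
    if block.strand == "+":
        qpos = block.qry.start + (pos - block.ref.start)
    else:
        qpos = block.qry.start + (block.ref.end - 1 - pos)
    return block.qry.chrom, qpos


def invert_blocks(blocks: Sequence[AlignmentBlock]) -> list[AlignmentBlock]:
    """The reciprocal block map (query becomes reference); strand preserved."""
    return sorted(
        (AlignmentBlock(ref=b.qry, qry=b.ref, strand=b.strand) for b in blocks),
        key=lambda b: (b.ref.chrom, b.ref.start),
    )


def expected_query_position(
    chrom: str, pos: int, blocks: Sequence[AlignmentBlock] | _BlockIndex
) -> tuple[str, int] | None:
    """Expected query position of a reference coordinate, gap-aware.

    Inside a block this is plain :func:`liftover`.  In an alignment gap the
    expectation is defensible only when the gap is a clean deletion in the
    query: both flanking blocks exist, map to the same query chromosome on
    the forward strand, and are query-adjacent.  The expected position is
    then the junction point.  Any other gap returns ``None``.
    """
    index = blocks if isinstance(blocks, _BlockIndex) else _BlockIndex(blocks)
    block, nxt = index.locate(chrom, pos)
    if block is not None:
        if block.strand == "+":
            return block.qry.chrom, block.qry.start + (pos - block.ref.start)
        return block.qry.chrom, block.qry.start + (block.ref.end - 1 - pos)
    lst = index.by_chrom.get(chrom, [])
    left = lst[nxt - 1] if nxt - 1 >= 0 else None
    right = lst[nxt] if nxt < len(lst) else None
    if (
        left is not None
        and right is not None
        and left.strand == "+"
        and right.strand == "+"
        and left.qry.chrom == right.qry.chrom
        and left.qry.end == right.qry.start
    ):
        return left.qry.chrom, left.qry.end
    return None


# ---------------------------------------------------------------------------
# Movement calls
# ---------------------------------------------------------------------------


def call_movement(
    matches: Sequence[TEMatch],
    ref_tes: Sequence[TEAnnotation],
    query_tes: Sequence[TEAnnotation],
    blocks: Sequence[AlignmentBlock],
    config: TrackingConfig | None = None,
) -> list[MovementCall]:
    """Classify each matched TE as unmoved/intra/inter/duplicated/unresolvable."""
    config = config or TrackingConfig()
    ref_by_id = {t.te_id: t for t in ref_tes}
    qry_by_id = {t.te_id: t for t in query_tes}
    index = _BlockIndex(blocks)
    calls: list[MovementCall] = []
    for m in matches:
        if m.ref_te_id not in ref_by_id:
            raise KeyError(f"match references unknown reference TE {m.ref_te_id!r}")
        for qid in m.query_te_ids:
            if qid not in qry_by_id:
                raise KeyError(f"match references unknown query TE {qid!r}")
        ref_te = ref_by_id[m.ref_te_id]
        qtes = [qry_by_id[q] for q in m.query_te_ids]
        observed = min(qtes, key=lambda t: (t.chrom, t.start))
        expected = expected_query_position(ref_te.chrom, ref_te.start, index)

        if len(qtes) > 1:
            call, displacement = CALL_DUP, None
            exp_chrom, exp_pos = expected if expected else (None, None)
        elif expected is None:
            call, displacement = CALL_UNRESOLVABLE, None
            exp_chrom, exp_pos = None, None
        else:
            exp_chrom, exp_pos = expected
            if observed.chrom != exp_chrom:
                call, displacement = CALL_INTER, None
            else:
                displacement = abs(observed.start - exp_pos)
                call = CALL_INTRA if displacement > config.tolerance_bp else CALL_UNMOVED
        calls.append(
            MovementCall(
                ref_te_id=m.ref_te_id,
                call=call,
                observed_qry_chrom=observed.chrom,
                observed_qry_pos=observed.start,
                expected_qry_chrom=exp_chrom,
                expected_qry_pos=exp_pos,
                displacement=displacement,
                family=ref_te.family,
                n_query_copies=len(qtes),
            )
        )
    return calls


def track(
    te_annotations_A: Sequence[TEAnnotation],
    te_annotations_B: Sequence[TEAnnotation],
    snps: Sequence[VariantRecord],
    blocks: Sequence[AlignmentBlock],
    config: TrackingConfig | None = None,
) -> tuple[list[MovementCall], dict]:
    """Full pipeline: fingerprint -> match -> movement calls + summary counts.

    The summary reports totals per call class and per TE family, plus the
    fingerprinting funnel (total reference TEs, fingerprinted, unique,
    matched in the query genome).
    """
    config = config or TrackingConfig()
    fps = fingerprint_tes(te_annotations_A, snps, same_family_only=config.same_family_only)
    unique = [fp for fp in fps if fp.is_unique]
    matches = match_fingerprints(unique, te_annotations_B, config)
    calls = call_movement(matches, te_annotations_A, te_annotations_B, blocks, config)
    assert len(calls) == len(matches)

    per_call = Counter(c.call for c in calls)
    per_family: dict[str, Counter] = defaultdict(Counter)
    for c in calls:
        per_family[c.family][c.call] += 1
    summary = {
        "n_ref_tes": len(te_annotations_A),
        "n_fingerprinted": len(fps),
        "n_unique": len(unique),
        "n_matched": len(matches),
        "calls": dict(per_call),
        "calls_by_family": {f: dict(c) for f, c in per_family.items()},
    }
    return calls, summary


# ---------------------------------------------------------------------------
# TE annotation I/O (BED6 + genome sequence extraction)
# ---------------------------------------------------------------------------


def write_te_bed(tes: Sequence[TEAnnotation], path: str | os.PathLike) -> None:
    """Write TE annotations as BED6; name encodes ``te_id|family|class``."""
    write_bed(
        [t.interval for t in tes],
        path,
        names=[f"{t.te_id}|{t.family}|{t.te_class}" for t in tes],
        strands=[t.strand for t in tes],
    )


def read_te_annotations(
    bed_path: str | os.PathLike, genome: dict[str, str]
) -> list[TEAnnotation]:
    """Load TE annotations from BED6 and extract their sequences from a genome."""
    out = []
    for iv, name, strand in read_bed(bed_path):
        parts = name.split("|")
        te_id = parts[0]
        family = parts[1] if len(parts) > 1 else "other"
        te_class = parts[2] if len(parts) > 2 else "II"
        seq = genome[iv.chrom][iv.start : iv.end]
        out.append(TEAnnotation(te_id, iv.chrom, iv, strand, family, te_class, seq))
    return out
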