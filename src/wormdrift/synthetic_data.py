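"""Synthetic genome-pair generator with planted variants and truth sets.

The generator emulates the comparison of two wild-type laboratory lineages
derived from a common ancestor: an ancestral genome is built with genes and
transposable-element copies, and two lineages A and B are derived such that
B differs from A by a planted truth set of SNPs, short indels, structural
variants (>= 50 bp: DEL/INS/INV/DUP/TRANS/NOTAL), and TE movements or
duplications.  SNP density is arm-biased, mirroring the elevated sequence
divergence of *C. elegans* chromosome arms.  Alongside the sequences the
generator emits a gap-free alignment-block map between A and B that is
consistent with every planted event, so liftover-based analyses can be
exercised without running a whole-genome aligner.

Consistency guarantees (tested):

* Any A position not covered by a planted event lifts through the block map
  to a B position carrying the identical base.
* Re-applying the truth set to genome A with the naive editor
  :func:`apply_truth` reconstructs genome B exactly.
* Identical configuration (including seed) produces byte-identical output.

Event semantics: all structural payloads are taken from the *SNP-substituted*
A sequence, i.e. conceptually SNPs happen first, then structural events.
A TE move therefore transports the element's fingerprint (its internal
B-lineage substitutions) to the destination, exactly as short-read SNP
calls against the A assembly would report them at the A locus.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple

import numpy as np
from intervaltree import IntervalTree

from .errors import SizingError
from .io_formats import (
    HOMOZYGOUS,
    AlignmentBlock,
    Gene,
    GenomicInterval,
    SVRecord,
    VariantRecord,
    read_alignment_blocks,
    read_fasta,
    read_gff3,
    reverse_complement,
    write_alignment_blocks,
    write_chrom_sizes,
    write_fasta,
    write_gff3,
    write_sv_table,
    write_vcf,
)
from .te_tracking import TEAnnotation, read_te_annotations, write_te_bed

_CELEGANS_NAMES = ["I", "II", "III", "IV", "V", "X"]
_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES = "ACGT"


def chromosome_names(n: int) -> list[str]:
    """Chromosome names: the six nematode names, then chr7, chr8, ..."""
    if n <= len(_CELEGANS_NAMES):
        return _CELEGANS_NAMES[:n]
    return _CELEGANS_NAMES + [f"chr{i + 1}" for i in range(len(_CELEGANS_NAMES), n)]


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return _DNA[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, base: str) -> str:
    alternatives = _BASES.replace(base, "")
    return alternatives[int(rng.integers(0, 3))]


def default_te_library(seed: int = 7_919) -> list[tuple[str, str]]:
    """A deterministic consensus library covering the DNA-transposon families.

    Consensus lengths are loosely realistic (hundreds of bases to ~1.6 kb for
    Tc1/mariner-sized elements); sequences are arbitrary but fixed.
    """
    rng = np.random.default_rng(seed)
    lengths = {
        "Tc1/mariner": 1_610,
        "Zator": 900,
        "Sola": 1_200,
        "hAT": 1_000,
        "CMC": 1_100,
        "MITE": 800,
        "Novosib": 950,
        "Helitron": 1_400,
    }
    return [(fam, _rand_dna(rng, n)) for fam, n in lengths.items()]


@dataclass(frozen=True)
class SVTypeSpec:
    """Per-type structural-variant plan: how many events, within a size range."""

    count: int
    min_size: int
    max_size: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("SV count must be >= 0")
        if self.min_size < 50:
            raise ValueError("SVs are >= 50 bp by definition; min_size too small")
        if self.max_size < self.min_size:
            raise ValueError("max_size < min_size")


def default_sv_spec() -> dict[str, SVTypeSpec]:
    return {
        "DEL": SVTypeSpec(2, 50, 500),
        "INS": SVTypeSpec(2, 50, 500),
        "INV": SVTypeSpec(1, 100, 1_000),
        "DUP": SVTypeSpec(1, 100, 500),
        "TRANS": SVTypeSpec(1, 100, 500),
        "NOTAL": SVTypeSpec(1, 200, 1_000),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic genome pair.

    Defaults describe five 1-Mb chromosomes carrying 200 TE copies, with
    five intrachromosomal moves, two interchromosomal moves, and three
    duplications planted between the lineages, SNPs three-fold denser on
    the terminal-third arms than the center, and a small spectrum of
    >= 50-bp structural variants.
    """

    n_chromosomes: int = 5
    chrom_length: int = 1_000_000
    arm_fraction: float = 1 / 3
    snp_rate: float = 1e-3
    arm_bias: float = 3.0
    indel_rate: float = 1e-4
    indel_size_max: int = 10
    te_library: tuple[tuple[str, str], ...] = tuple(default_te_library())
    n_te_copies: int = 200
    te_private_snp_rate: float = 0.02
    n_te_moves_intra: int = 5
    n_te_moves_inter: int = 2
    n_te_dups: int = 3
    sv_spec: dict[str, SVTypeSpec] = field(default_factory=default_sv_spec)
    n_genes: int = 100
    min_move_displacement: int = 20_000
    placement_margin: int = 300
    max_retries: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1_000:
            raise ValueError("need >= 1 chromosome of >= 1 kb")
        if not 0 < self.arm_fraction <= 0.5:
            raise ValueError("arm_fraction must be in (0, 0.5]")
        for name, rate in (
            ("snp_rate", self.snp_rate),
            ("indel_rate", self.indel_rate),
            ("te_private_snp_rate", self.te_private_snp_rate),
            ("arm_bias", self.arm_bias),
        ):
            if rate < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.te_library:
            raise ValueError("te_library must be non-empty")
        for fam, cons in self.te_library:
            if not cons or set(cons) - set("ACGT"):
                raise ValueError(f"TE consensus for {fam} must be non-empty ACGT")
        for code, spec in self.sv_spec.items():
            if code not in {"DEL", "INS", "INV", "DUP", "TRANS", "NOTAL"}:
                raise ValueError(f"unsupported SV type in sv_spec: {code}")
        needs_second_chrom = self.n_te_moves_inter > 0 or (
            "TRANS" in self.sv_spec and self.sv_spec["TRANS"].count > 0
        )
        if needs_second_chrom and self.n_chromosomes < 2:
            raise ValueError("interchromosomal events require >= 2 chromosomes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed % 2**31])


class SNP(NamedTuple):
    chrom: str
    pos0: int
    ref_allele: str
    alt_allele: str


class Indel(NamedTuple):
    chrom: str
    pos0: int
    ref_seq: str
    alt_seq: str


class TEMove(NamedTuple):
    te_id: str
    src_chrom: str
    src_start0: int
    dst_chrom: str
    dst_start0: int  # realized position in genome B
    dst_anchor0: int  # planned insertion anchor in genome A coordinates
    kind: str  # intra | inter | duplication


@dataclass(frozen=True)
class PlantedSV:
    """One planted structural variant, with both A-side and B-side coordinates.

    ``start``/``end`` are genome-A coordinates of the affected reference
    span (``start == end`` for pure insertions).  ``dst_anchor`` is the
    genome-A coordinate before which inserted material lands (DUP/TRANS).
    ``qry_*`` give the realized genome-B span of the replacement/insertion.
    ``seq`` carries the payload for events whose content is not derivable
    from genome A (INS, NOTAL).
    """

    sv_type: str
    chrom: str
    start: int
    end: int
    dst_chrom: str | None = None
    dst_anchor: int | None = None
    qry_chrom: str | None = None
    qry_start: int | None = None
    qry_end: int | None = None
    seq: str | None = None

    @property
    def size(self) -> int:
        return max(self.end - self.start, len(self.seq) if self.seq else 0)


@dataclass
class TruthSet:
    """Everything planted between the lineages, plus the consistent block map."""

    snps: list[SNP] = field(default_factory=list)
    indels: list[Indel] = field(default_factory=list)
    svs: list[PlantedSV] = field(default_factory=list)
    te_moves: list[TEMove] = field(default_factory=list)
    alignment_blocks: list[AlignmentBlock] = field(default_factory=list)
    te_annotations_A: list[TEAnnotation] = field(default_factory=list)
    te_annotations_B: list[TEAnnotation] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)
    chrom_lengths_A: dict[str, int] = field(default_factory=dict)
    chrom_lengths_B: dict[str, int] = field(default_factory=dict)

    def to_variant_records(
        self, qual: float = 60.0, alt_depth: int = 45, total_depth: int = 50
    ) -> list[VariantRecord]:
        """Truth SNPs and indels as idealized homozygous VCF-style calls."""
        records = [
            VariantRecord(
                s.chrom, s.pos0 + 1, s.ref_allele, s.alt_allele, qual, alt_depth,
                total_depth, HOMOZYGOUS,
            )
            for s in self.snps
        ]
        records.extend(
            VariantRecord(
                i.chrom, i.pos0 + 1, i.ref_seq, i.alt_seq, qual, alt_depth,
                total_depth, HOMOZYGOUS,
            )
            for i in self.indels
        )
        return records


@dataclass
class Ancestor:
    genome: dict[str, str]
    genes: list[Gene]
    te_copies: list[TEAnnotation]


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------


def _sample_start(
    rng: np.random.Generator,
    tree: IntervalTree,
    lo: int,
    hi: int,
    span: int,
    max_retries: int,
    what: str,
    constraint: Callable[[int], bool] | None = None,
) -> int:
    """Uniformly sample a start in [lo, hi - span] avoiding reserved spans."""
    if hi - span < lo:
        raise SizingError(f"no room to place {what}: span {span} in [{lo},{hi})")
    for _ in range(max_retries):
        s = int(rng.integers(lo, hi - span + 1))
        if tree.overlaps(s - 1, s + span + 1):
            continue
        if constraint is not None and not constraint(s):
            continue
        return s
    raise SizingError(
        f"could not place {what} after {max_retries} retries; "
        f"reduce feature counts or enlarge chromosomes"
    )


def _reserve(tree: IntervalTree, start: int, end: int) -> None:
    tree.addi(start - 1, max(end, start + 1) + 1)


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------


def build_ancestor(config: SimConfig) -> Ancestor:
    """Build the ancestral genome with genes and fingerprintable TE copies.

    Each TE copy is its family consensus with private substitutions drawn
    per base at ``te_private_snp_rate``, which makes copies of the same
    family distinguishable.  TE placements avoid exons and UTRs (introns
    and intergenic space are fair game); genes do not overlap each other.
    """
    rng = config.rng(0)
    names = chromosome_names(config.n_chromosomes)
    L = config.chrom_length
    margin = config.placement_margin
    genome = {c: bytearray(_rand_dna(rng, L).encode("ascii")) for c in names}
    gene_tree = {c: IntervalTree() for c in names}
    coding_tree = {c: IntervalTree() for c in names}  # exon + UTR spans
    te_tree = {c: IntervalTree() for c in names}

    genes: list[Gene] = []
    for i in range(config.n_genes):
        chrom = names[i % len(names)]
        glen = int(rng.integers(1_500, 4_001))
        start = _sample_start(
            rng, gene_tree[chrom], margin, L - margin, glen, config.max_retries,
            f"gene {i}",
        )
        _reserve(gene_tree[chrom], start, start + glen)
        gene = _gene_structure(rng, f"gene{i:04d}", chrom, start, glen)
        for sub in gene.exons + gene.utrs:
            coding_tree[chrom].addi(sub.start, sub.end)
        genes.append(gene)

    te_copies: list[TEAnnotation] = []
    lib = list(config.te_library)
    for j in range(config.n_te_copies):
        family, consensus = lib[int(rng.integers(len(lib)))]
        seq = _diverge_from_consensus(rng, consensus, config.te_private_snp_rate)
        chrom = names[int(rng.integers(len(names)))]
        start = _sample_start(
            rng,
            te_tree[chrom],
            margin,
            L - margin,
            len(seq),
            config.max_retries,
            f"TE copy {j}",
            constraint=lambda s, c=chrom, n=len(seq): not coding_tree[c].overlaps(s, s + n),
        )
        _reserve(te_tree[chrom], start, start + len(seq))
        genome[chrom][start : start + len(seq)] = seq.encode("ascii")
        te_copies.append(
            TEAnnotation(
                te_id=f"te{j:04d}",
                chrom=chrom,
                interval=GenomicInterval(chrom, start, start + len(seq)),
                strand="+",
                family=family,
                te_class="II",
                sequence=seq,
            )
        )

    return Ancestor(
        genome={c: bytes(genome[c]).decode("ascii") for c in names},
        genes=genes,
        te_copies=te_copies,
    )


def _gene_structure(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int, glen: int
) -> Gene:
    """UTR-exon-intron-...-exon-UTR layout with >= 50 bp pieces."""
    utr = 150
    interior_len = glen - 2 * utr
    n_exons = int(rng.integers(2, 5))
    while 2 * n_exons - 1 > interior_len // 50 and n_exons > 1:
        n_exons -= 1
    k = 2 * n_exons - 1
    slack = interior_len - 50 * k
    cuts = np.sort(rng.integers(0, slack + 1, size=k - 1)) if k > 1 else np.array([], int)
    widths = np.diff(np.concatenate([[0], cuts, [slack]])) + 50
    pieces = []
    cursor = start + utr
    for w in widths:
        pieces.append(GenomicInterval(chrom, cursor, cursor + int(w)))
        cursor += int(w)
    return Gene(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, start + glen),
        exons=pieces[0::2],
        utrs=[
            GenomicInterval(chrom, start, start + utr),
            GenomicInterval(chrom, start + glen - utr, start + glen),
        ],
    )


def _diverge_from_consensus(
    rng: np.random.Generator, consensus: str, rate: float
) -> str:
    if rate <= 0:
        return consensus
    seq = list(consensus)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        seq[i] = _mutate(rng, seq[i])
    return "".join(seq)


# ---------------------------------------------------------------------------
# Lineage derivation
# ---------------------------------------------------------------------------


@dataclass
class _Edit:
    """One structural edit on genome A: replace [start, end) by ``replacement``.

    ``start == end`` encodes an insertion before A position ``start``.
    ``kind`` tags the planting event for bookkeeping; ``inv`` edits emit a
    minus-strand alignment block instead of breaking synteny.
    """

    chrom: str
    start: int
    end: int
    replacement: str
    kind: str
    tag: str
    b_start: int | None = None  # realized genome-B coordinate of the replacement


def derive_lineages(
    ancestor: Ancestor, config: SimConfig
) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Derive lineages A (identical to the ancestor) and B (edited) plus truth.

    Event spans are kept mutually disjoint by rejection-resampling with a
    bounded retry count, so the alignment map is well defined.  SNPs may
    fall inside TE spans (that is what makes elements fingerprintable) but
    never inside another event's footprint.
    """
    rng = config.rng(1)
    names = list(ancestor.genome)
    L = {c: len(s) for c, s in ancestor.genome.items()}
    margin = config.placement_margin
    retries = config.max_retries

    # Reservation tree guards structural placements: chromosome margins and
    # all TE spans (a TE may only be altered by its own move or internal SNPs).
    res = {c: IntervalTree() for c in names}
    snp_blocked = {c: IntervalTree() for c in names}
    for c in names:
        res[c].addi(0, margin)
        res[c].addi(L[c] - margin, L[c])
    for te in ancestor.te_copies:
        _reserve(res[te.chrom], te.interval.start, te.interval.end)

    # ---- TE movement / duplication plan --------------------------------
    n_events = config.n_te_moves_intra + config.n_te_moves_inter + config.n_te_dups
    if n_events > len(ancestor.te_copies):
        raise SizingError(
            f"{n_events} TE events requested but only {len(ancestor.te_copies)} copies exist"
        )
    order = rng.permutation(len(ancestor.te_copies))
    chosen = [ancestor.te_copies[i] for i in order[:n_events]]
    te_plan: list[tuple[TEAnnotation, str, int, str]] = []  # (te, dst_chrom, anchor, kind)
    cursor = 0
    for kind, count in (
        ("intra", config.n_te_moves_intra),
        ("inter", config.n_te_moves_inter),
        ("duplication", config.n_te_dups),
    ):
        for _ in range(count):
            te = chosen[cursor]
            cursor += 1
            if kind == "intra":
                dst = te.chrom
                constraint = (
                    lambda p, s=te.interval.start: abs(p - s) >= config.min_move_displacement
                )
            elif kind == "inter":
                others = [c for c in names if c != te.chrom]
                dst = others[int(rng.integers(len(others)))]
                constraint = None
            else:
                dst = names[int(rng.integers(len(names)))]
                constraint = None
            anchor = _sample_start(
                rng, res[dst], margin, L[dst] - margin, 0, retries,
                f"TE {kind} destination for {te.te_id}", constraint,
            )
            _reserve(res[dst], anchor, anchor)
            _reserve(snp_blocked[dst], anchor, anchor)
            te_plan.append((te, dst, anchor, kind))
            if kind != "duplication":
                snp_blocked[te.chrom].addi(te.interval.start, te.interval.end)

    # ---- structural variant plan ---------------------------------------
    sv_plan: list[PlantedSV] = []
    random_payload: dict[int, str] = {}
    for code, spec in sorted(config.sv_spec.items()):
        for k in range(spec.count):
            size = int(rng.integers(spec.min_size, spec.max_size + 1))
            chrom = names[int(rng.integers(len(names)))]
            tag = len(sv_plan)
            if code == "INS":
                anchor = _sample_start(rng, res[chrom], margin, L[chrom] - margin, 0,
                                       retries, f"INS {k}")
                _reserve(res[chrom], anchor, anchor)
                _reserve(snp_blocked[chrom], anchor, anchor)
                random_payload[tag] = _rand_dna(rng, size)
                sv_plan.append(PlantedSV("INS", chrom, anchor, anchor, seq=random_payload[tag]))
            elif code == "TRANS":
                start = _sample_start(rng, res[chrom], margin, L[chrom] - margin, size,
                                      retries, f"TRANS {k} source")
                _reserve(res[chrom], start, start + size)
                snp_blocked[chrom].addi(start, start + size)
                others = [c for c in names if c != chrom]
                dst = others[int(rng.integers(len(others)))]
                anchor = _sample_start(rng, res[dst], margin, L[dst] - margin, 0,
                                       retries, f"TRANS {k} destination")
                _reserve(res[dst], anchor, anchor)
                _reserve(snp_blocked[dst], anchor, anchor)
                sv_plan.append(
                    PlantedSV("TRANS", chrom, start, start + size, dst_chrom=dst, dst_anchor=anchor)
                )
            elif code == "DUP":
                start = _sample_start(rng, res[chrom], margin, L[chrom] - margin, size,
                                      retries, f"DUP {k}")
                _reserve(res[chrom], start, start + size)
                _reserve(snp_blocked[chrom], start + size, start + size)
                sv_plan.append(
                    PlantedSV("DUP", chrom, start, start + size,
                              dst_chrom=chrom, dst_anchor=start + size)
                )
            else:  # DEL, INV, NOTAL
                start = _sample_start(rng, res[chrom], margin, L[chrom] - margin, size,
                                      retries, f"{code} {k}")
                _reserve(res[chrom], start, start + size)
                snp_blocked[chrom].addi(start, start + size)
                if code == "NOTAL":
                    random_payload[tag] = _rand_dna(rng, size)
                    sv_plan.append(PlantedSV("NOTAL", chrom, start, start + size,
                                             seq=random_payload[tag]))
                else:
                    sv_plan.append(PlantedSV(code, chrom, start, start + size))

    # ---- indel plan ------------------------------------------------------
    indels: list[Indel] = []
    indel_edits: list[tuple[str, int, int, int, bool]] = []  # chrom, anchor, k, tag, is_del
    for c in names:
        count = int(round(L[c] * config.indel_rate))
        for k_i in range(count):
            k = int(rng.integers(1, config.indel_size_max + 1))
            is_del = bool(rng.integers(0, 2))
            span = k + 1 if is_del else 1
            p = _sample_start(rng, res[c], margin, L[c] - margin, span, retries,
                             f"indel on {c}")
            _reserve(res[c], p, p + span)
            snp_blocked[c].addi(p - 1, p + span + 1)
            indel_edits.append((c, p, k, len(indels), is_del))
            indels.append(Indel(c, p, "", ""))  # alleles filled after SNP substitution

    # ---- SNPs: arm-biased genome-wide + TE-internal fingerprint subs -----
    f = config.arm_fraction
    arm_mass = config.arm_bias * 2 * f
    p_arm = arm_mass / (arm_mass + (1 - 2 * f)) if arm_mass + (1 - 2 * f) > 0 else 0.0
    snps: list[SNP] = []
    taken: set[tuple[str, int]] = set()
    for c in names:
        n_target = int(round(L[c] * config.snp_rate))
        a = int(f * L[c])
        placed = 0
        attempts = 0
        while placed < n_target:
            attempts += 1
            if attempts > max(retries, 50 * n_target):
                raise SizingError(f"could not place {n_target} SNPs on {c}")
            if rng.random() < p_arm:
                if rng.integers(0, 2) == 0:
                    pos = int(rng.integers(0, a))
                else:
                    pos = int(rng.integers(L[c] - a, L[c]))
            else:
                pos = int(rng.integers(a, L[c] - a))
            if (c, pos) in taken or snp_blocked[c].overlaps(pos):
                continue
            ref = ancestor.genome[c][pos]
            snps.append(SNP(c, pos, ref, _mutate(rng, ref)))
            taken.add((c, pos))
            placed += 1

    for te in ancestor.te_copies:
        n_sub = int(rng.binomial(len(te.sequence), config.te_private_snp_rate))
        if n_sub == 0:
            continue
        offsets = rng.choice(len(te.sequence), size=n_sub, replace=False)
        for off in sorted(int(o) for o in offsets):
            pos = te.interval.start + off
            if (te.chrom, pos) in taken:
                continue
            ref = ancestor.genome[te.chrom][pos]
            snps.append(SNP(te.chrom, pos, ref, _mutate(rng, ref)))
            taken.add((te.chrom, pos))
    snps.sort()

    # ---- substitute SNPs into A' ----------------------------------------
    a_prime = {c: bytearray(ancestor.genome[c].encode("ascii")) for c in names}
    for s in snps:
        assert chr(a_prime[s.chrom][s.pos0]) == s.ref_allele
        a_prime[s.chrom][s.pos0] = ord(s.alt_allele)
    a_prime_str = {c: bytes(a_prime[c]).decode("ascii") for c in names}

    # ---- indel alleles (REF from original A; spans are SNP-free) ---------
    for c, p, k, tag, is_del in indel_edits:
        if is_del:
            ref_seq = ancestor.genome[c][p : p + k + 1]
            alt_seq = ref_seq[0]
        else:
            ref_seq = ancestor.genome[c][p]
            alt_seq = ref_seq + _rand_dna(rng, k)
        indels[tag] = Indel(c, p, ref_seq, alt_seq)
    indels.sort()

    # ---- assemble the edit list ------------------------------------------
    edits: dict[str, list[_Edit]] = {c: [] for c in names}
    for i, sv in enumerate(sv_plan):
        c = sv.chrom
        if sv.sv_type == "DEL":
            edits[c].append(_Edit(c, sv.start, sv.end, "", "DEL", f"sv{i}"))
        elif sv.sv_type == "INS":
            edits[c].append(_Edit(c, sv.start, sv.start, sv.seq, "INS", f"sv{i}"))
        elif sv.sv_type == "INV":
            payload = reverse_complement(a_prime_str[c][sv.start : sv.end])
            edits[c].append(_Edit(c, sv.start, sv.end, payload, "INV", f"sv{i}"))
        elif sv.sv_type == "NOTAL":
            edits[c].append(_Edit(c, sv.start, sv.end, sv.seq, "NOTAL", f"sv{i}"))
        elif sv.sv_type == "DUP":
            payload = a_prime_str[c][sv.start : sv.end]
            edits[c].append(_Edit(c, sv.dst_anchor, sv.dst_anchor, payload, "DUP", f"sv{i}"))
        elif sv.sv_type == "TRANS":
            payload = a_prime_str[c][sv.start : sv.end]
            edits[c].append(_Edit(c, sv.start, sv.end, "", "TRANS_out", f"sv{i}"))
            edits[sv.dst_chrom].append(
                _Edit(sv.dst_chrom, sv.dst_anchor, sv.dst_anchor, payload, "TRANS_in", f"sv{i}")
            )
    for te, dst, anchor, kind in te_plan:
        payload = a_prime_str[te.chrom][te.interval.start : te.interval.end]
        if kind != "duplication":
            edits[te.chrom].append(
                _Edit(te.chrom, te.interval.start, te.interval.end, "", "TE_out", te.te_id)
            )
        edits[dst].append(_Edit(dst, anchor, anchor, payload, "TE_in", te.te_id))
    for c, p, k, tag, is_del in indel_edits:
        if is_del:
            edits[c].append(_Edit(c, p + 1, p + k + 1, "", "indel_del", f"indel{tag}"))
        else:
            alt_tail = indels_by_tag(indels, c, p).alt_seq[1:]
            edits[c].append(_Edit(c, p + 1, p + 1, alt_tail, "indel_ins", f"indel{tag}"))

    # ---- walk: build B, the block map, and realized B coordinates --------
    genome_b: dict[str, str] = {}
    blocks: list[AlignmentBlock] = []
    segments: dict[str, list[tuple[int, int, int]]] = {c: [] for c in names}
    for c in names:
        evs = sorted(edits[c], key=lambda e: (e.start, e.end))
        parts: list[str] = []
        ca = cb = 0
        for e in evs:
            if e.start < ca:
                raise AssertionError("overlapping edits; reservation failed")
            if e.start > ca:
                seg = a_prime_str[c][ca : e.start]
                parts.append(seg)
                blocks.append(
                    AlignmentBlock(
                        GenomicInterval(c, ca, e.start),
                        GenomicInterval(c, cb, cb + len(seg)),
                        "+",
                    )
                )
                segments[c].append((ca, e.start, cb))
                cb += len(seg)
            e.b_start = cb
            if e.kind == "INV":
                blocks.append(
                    AlignmentBlock(
                        GenomicInterval(c, e.start, e.end),
                        GenomicInterval(c, cb, cb + len(e.replacement)),
                        "-",
                    )
                )
            parts.append(e.replacement)
            cb += len(e.replacement)
            ca = e.end
        if ca < L[c]:
            seg = a_prime_str[c][ca:]
            parts.append(seg)
            blocks.append(
                AlignmentBlock(
                    GenomicInterval(c, ca, L[c]),
                    GenomicInterval(c, cb, cb + len(seg)),
                    "+",
                )
            )
            segments[c].append((ca, L[c], cb))
        genome_b[c] = "".join(parts)

    def to_b(chrom: str, pos: int) -> int:
        for a0, a1, b0 in segments[chrom]:
            if a0 <= pos < a1:
                return b0 + (pos - a0)
        raise AssertionError(f"position {chrom}:{pos} not in any syntenic segment")

    edit_by_tag = {
        e.tag: e for lst in edits.values() for e in lst if not e.kind.endswith("_out")
    }
    out_by_tag = {e.tag: e for lst in edits.values() for e in lst if e.kind.endswith("_out")}

    # ---- realized B coordinates for the truth records --------------------
    svs: list[PlantedSV] = []
    for i, sv in enumerate(sv_plan):
        tag = f"sv{i}"
        if sv.sv_type == "TRANS":
            e_in = edit_by_tag[tag]
            svs.append(replace(sv, qry_chrom=sv.dst_chrom,
                               qry_start=e_in.b_start, qry_end=e_in.b_start + (sv.end - sv.start)))
        elif sv.sv_type == "DEL":
            e = out_by_tag.get(tag) or edit_by_tag[tag]
            svs.append(replace(sv, qry_chrom=sv.chrom, qry_start=e.b_start, qry_end=e.b_start))
        else:
            e = edit_by_tag[tag]
            svs.append(replace(sv, qry_chrom=e.chrom,
                               qry_start=e.b_start, qry_end=e.b_start + len(e.replacement)))

    te_moves: list[TEMove] = []
    moved_ids = {}
    for te, dst, anchor, kind in te_plan:
        e_in = edit_by_tag[te.te_id]
        te_moves.append(
            TEMove(te.te_id, te.chrom, te.interval.start, dst, e_in.b_start, anchor, kind)
        )
        moved_ids[te.te_id] = (kind, dst, e_in.b_start)

    # ---- TE annotations in B ---------------------------------------------
    te_b: list[TEAnnotation] = []
    for te in ancestor.te_copies:
        n = len(te.sequence)
        if te.te_id in moved_ids and moved_ids[te.te_id][0] != "duplication":
            _, dst, b0 = moved_ids[te.te_id]
            iv = GenomicInterval(dst, b0, b0 + n)
            te_b.append(replace(te, chrom=dst, interval=iv, sequence=genome_b[dst][b0 : b0 + n]))
        else:
            b0 = to_b(te.chrom, te.interval.start)
            iv = GenomicInterval(te.chrom, b0, b0 + n)
            te_b.append(
                replace(te, interval=iv, sequence=genome_b[te.chrom][b0 : b0 + n])
            )
            if te.te_id in moved_ids:  # duplication: add the extra copy
                _, dst, bc = moved_ids[te.te_id]
                ivc = GenomicInterval(dst, bc, bc + n)
                te_b.append(
                    replace(te, te_id=f"{te.te_id}_dup", chrom=dst, interval=ivc,
                            sequence=genome_b[dst][bc : bc + n])
                )
    te_b.sort(key=lambda t: (t.chrom, t.start))

    blocks.sort(key=lambda b: (b.ref.chrom, b.ref.start))
    truth = TruthSet(
        snps=snps,
        indels=indels,
        svs=svs,
        te_moves=te_moves,
        alignment_blocks=blocks,
        te_annotations_A=list(ancestor.te_copies),
        te_annotations_B=te_b,
        genes=list(ancestor.genes),
        chrom_lengths_A={c: L[c] for c in names},
        chrom_lengths_B={c: len(genome_b[c]) for c in names},
    )
    return dict(ancestor.genome), genome_b, truth


def indels_by_tag(indels: list[Indel], chrom: str, pos0: int) -> Indel:
    for i in indels:
        if i.chrom == chrom and i.pos0 == pos0:
            return i
    raise KeyError(f"no indel at {chrom}:{pos0}")


# ---------------------------------------------------------------------------
# Naive truth re-application (independent oracle path)
# ---------------------------------------------------------------------------


def apply_truth(genome_a: dict[str, str], truth: TruthSet) -> dict[str, str]:
    """Reconstruct genome B from genome A and the truth records alone.

    Deliberately naive: substitute SNPs into per-chromosome strings, gather
    every structural edit implied by the truth tables (indels, SVs, TE
    moves), and splice them right-to-left.  Shares no construction code
    with :func:`derive_lineages`; used to verify simulator self-consistency.
    """
    seqs = {c: bytearray(s.encode("ascii")) for c, s in genome_a.items()}
    for s in truth.snps:
        if chr(seqs[s.chrom][s.pos0]) != s.ref_allele:
            raise ValueError(f"truth SNP ref mismatch at {s.chrom}:{s.pos0}")
        seqs[s.chrom][s.pos0] = ord(s.alt_allele)
    subbed = {c: bytes(b).decode("ascii") for c, b in seqs.items()}

    splices: dict[str, list[tuple[int, int, str]]] = {c: [] for c in genome_a}
    for ind in truth.indels:
        splices[ind.chrom].append((ind.pos0, ind.pos0 + len(ind.ref_seq), ind.alt_seq))
    for sv in truth.svs:
        src = subbed[sv.chrom][sv.start : sv.end]
        if sv.sv_type == "DEL":
            splices[sv.chrom].append((sv.start, sv.end, ""))
        elif sv.sv_type == "INS":
            splices[sv.chrom].append((sv.start, sv.start, sv.seq))
        elif sv.sv_type == "INV":
            splices[sv.chrom].append((sv.start, sv.end, reverse_complement(src)))
        elif sv.sv_type == "NOTAL":
            splices[sv.chrom].append((sv.start, sv.end, sv.seq))
        elif sv.sv_type == "DUP":
            splices[sv.dst_chrom].append((sv.dst_anchor, sv.dst_anchor, src))
        elif sv.sv_type == "TRANS":
            splices[sv.chrom].append((sv.start, sv.end, ""))
            splices[sv.dst_chrom].append((sv.dst_anchor, sv.dst_anchor, src))
        else:
            raise ValueError(f"cannot re-apply SV type {sv.sv_type}")
    te_by_id = {t.te_id: t for t in truth.te_annotations_A}
    for mv in truth.te_moves:
        te = te_by_id[mv.te_id]
        payload = subbed[mv.src_chrom][te.interval.start : te.interval.end]
        if mv.kind != "duplication":
            splices[mv.src_chrom].append((te.interval.start, te.interval.end, ""))
        splices[mv.dst_chrom].append((mv.dst_anchor0, mv.dst_anchor0, payload))

    out = {}
    for c, seq in subbed.items():
        for start, end, rep in sorted(splices[c], reverse=True):
            seq = seq[:start] + rep + seq[end:]
        out[c] = seq
    return out


# ---------------------------------------------------------------------------
# Emission / loading
# ---------------------------------------------------------------------------


def emit(
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    truth: TruthSet,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Write the bundle (FASTA x2, VCF, GFF3, BEDs, block TSV, truth TSVs).

    Returns a manifest mapping artifact names to file paths.  Re-reading the
    files through ``io_formats`` reproduces the in-memory objects.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in {
        "genome_A": "genome_A.fasta",
        "genome_B": "genome_B.fasta",
        "chrom_sizes_A": "genome_A.chrom.sizes",
        "vcf": "variants_B_vs_A.vcf",
        "genes": "genes_A.gff3",
        "te_A": "te_A.bed",
        "te_B": "te_B.bed",
        "blocks": "alignment_blocks.tsv",
        "sv_table": "sv_table.tsv",
        "truth_snps": "truth_snps.tsv",
        "truth_indels": "truth_indels.tsv",
        "truth_svs": "truth_svs.tsv",
        "truth_te_moves": "truth_te_moves.tsv",
    }.items()}

    write_fasta(genome_a, paths["genome_A"])
    write_fasta(genome_b, paths["genome_B"])
    write_chrom_sizes({c: len(s) for c, s in genome_a.items()}, paths["chrom_sizes_A"])
    write_vcf(
        truth.to_variant_records(), paths["vcf"],
        contigs={c: len(s) for c, s in genome_a.items()},
    )
    write_gff3(truth.genes, paths["genes"])
    write_te_bed(truth.te_annotations_A, paths["te_A"])
    write_te_bed(truth.te_annotations_B, paths["te_B"])
    write_alignment_blocks(truth.alignment_blocks, paths["blocks"])

    sv_records = []
    for sv in truth.svs:
        ref = (
            GenomicInterval(sv.chrom, sv.start, max(sv.end, sv.start + 1))
        )  # inclusive dialect cannot express zero-length; anchor base for INS
        qry = None
        if sv.qry_chrom is not None and sv.qry_end > sv.qry_start:
            qry = GenomicInterval(sv.qry_chrom, sv.qry_start, sv.qry_end)
        sv_records.append(SVRecord(sv.sv_type, ref, qry, max(sv.size, 50)))
    write_sv_table(sv_records, paths["sv_table"])

    import pandas as pd

    pd.DataFrame(truth.snps).to_csv(paths["truth_snps"], sep="\t", index=False)
    pd.DataFrame(truth.indels).to_csv(paths["truth_indels"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "type": sv.sv_type, "chrom": sv.chrom, "start0": sv.start, "end0": sv.end,
                "dst_chrom": sv.dst_chrom or ".",
                "dst_anchor0": sv.dst_anchor if sv.dst_anchor is not None else ".",
                "qry_chrom": sv.qry_chrom or ".",
                "qry_start0": sv.qry_start if sv.qry_start is not None else ".",
                "qry_end0": sv.qry_end if sv.qry_end is not None else ".",
                "seq": sv.seq or ".",
            }
            for sv in truth.svs
        ],
        columns=["type", "chrom", "start0", "end0", "dst_chrom", "dst_anchor0",
                 "qry_chrom", "qry_start0", "qry_end0", "seq"],
    ).to_csv(paths["truth_svs"], sep="\t", index=False)
    pd.DataFrame(truth.te_moves).to_csv(paths["truth_te_moves"], sep="\t", index=False)

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(
            {"files": {name: os.path.basename(p) for name, p in paths.items()}},
            fh, indent=2, sort_keys=True,
        )
    paths["manifest"] = os.path.join(outdir, "manifest.json")
    return paths


def load_bundle(outdir: str | os.PathLike) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Re-read an emitted bundle into (genome_A, genome_B, truth)."""
    import pandas as pd

    outdir = os.fspath(outdir)
    genome_a = read_fasta(os.path.join(outdir, "genome_A.fasta"))
    genome_b = read_fasta(os.path.join(outdir, "genome_B.fasta"))

    snps_df = pd.read_csv(os.path.join(outdir, "truth_snps.tsv"), sep="\t", dtype=str)
    indels_df = pd.read_csv(os.path.join(outdir, "truth_indels.tsv"), sep="\t", dtype=str)
    svs_df = pd.read_csv(os.path.join(outdir, "truth_svs.tsv"), sep="\t", dtype=str)
    moves_df = pd.read_csv(os.path.join(outdir, "truth_te_moves.tsv"), sep="\t", dtype=str)

    truth = TruthSet(
        snps=[SNP(r.chrom, int(r.pos0), r.ref_allele, r.alt_allele)
              for r in snps_df.itertuples(index=False)],
        indels=[Indel(r.chrom, int(r.pos0), r.ref_seq, r.alt_seq)
                for r in indels_df.itertuples(index=False)],
        svs=[
            PlantedSV(
                sv_type=r.type, chrom=r.chrom, start=int(r.start0), end=int(r.end0),
                dst_chrom=None if r.dst_chrom == "." else r.dst_chrom,
                dst_anchor=None if r.dst_anchor0 == "." else int(r.dst_anchor0),
                qry_chrom=None if r.qry_chrom == "." else r.qry_chrom,
                qry_start=None if r.qry_start0 == "." else int(r.qry_start0),
                qry_end=None if r.qry_end0 == "." else int(r.qry_end0),
                seq=None if r.seq == "." else r.seq,
            )
            for r in svs_df.itertuples(index=False)
        ],
        te_moves=[
            TEMove(r.te_id, r.src_chrom, int(r.src_start0), r.dst_chrom,
                   int(r.dst_start0), int(r.dst_anchor0), r.kind)
            for r in moves_df.itertuples(index=False)
        ],
        alignment_blocks=read_alignment_blocks(os.path.join(outdir, "alignment_blocks.tsv")),
        te_annotations_A=read_te_annotations(os.path.join(outdir, "te_A.bed"), genome_a),
        te_annotations_B=read_te_annotations(os.path.join(outdir, "te_B.bed"), genome_b),
        genes=read_gff3(os.path.join(outdir, "genes_A.gff3")),
        chrom_lengths_A={c: len(s) for c, s in genome_a.items()},
        chrom_lengths_B={c: len(s) for c, s in genome_b.items()},
    )
    return genome_a, genome_b, truth


def simulate(
    config: SimConfig, outdir: str | os.PathLike | None = None
) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Build the ancestor, derive both lineages, and optionally emit the bundle."""
    ancestor = build_ancestor(config)
    genome_a, genome_b, truth = derive_lineages(ancestor, config)
    if outdir is not None:
        emit(genome_a, genome_b, truth, outdir)
    return genome_a, genome_b, truth
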