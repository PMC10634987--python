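"""Per-chromosome comparison summaries and the mutation-accumulation model.

Summaries mirror the standard genome-comparison table: chromosome lengths
of both assemblies, aligned bases and percent syntenic, and counts (and
affected base pairs) of SNPs, indels, SVs, and highly divergent regions.
Totals are recomputed from summed numerators and denominators, never
averaged, and all stored values are exact; rounding is presentation-only.

The mutation-accumulation model estimates how many single-nucleotide
mutations a self-fertilizing laboratory lineage is expected to accrue:
``mu * genome_sites * generations`` with ``generations = years * 365 /
generation_days``.  Defaults use the germline rate of 2.7e-9 mutations per
site per generation, 1e8 sites, and a three-day generation time.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import pandas as pd

from .te_tracking import TEAnnotation

_COUNT_FIELDS = [
    "length_A",
    "length_B",
    "aligned_bases",
    "n_snps",
    "n_indels",
    "indel_bp",
    "n_svs",
    "sv_bp",
    "n_hdrs",
    "hdr_bp",
]


@dataclass(frozen=True)
class ChromosomeSummary:
    """One comparison-table row.  bp fields may be None when not tabulated."""

    chrom: str
    length_A: int = 0
    length_B: int = 0
    aligned_bases: int = 0
    pct_syntenic: float | None = None
    n_snps: int = 0
    n_indels: int = 0
    indel_bp: int | None = None
    n_svs: int = 0
    sv_bp: int | None = None
    n_hdrs: int = 0
    hdr_bp: int | None = None

    def __post_init__(self) -> None:
        if self.aligned_bases > self.length_A:
            raise ValueError(
                f"{self.chrom}: aligned bases {self.aligned_bases} exceed length "
                f"{self.length_A}"
            )
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and f.name != "pct_syntenic" and v < 0:
                raise ValueError(f"{self.chrom}: negative {f.name}")


@dataclass(frozen=True)
class MutationModel:
    """Germline mutation-accumulation parameters (per-generation rate model)."""

    mu: float = 2.7e-9  # mutations per site per generation
    genome_sites: float = 1.0e8
    generation_days: float = 3.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.genome_sites <= 0 or self.generation_days <= 0:
            raise ValueError("all mutation-model parameters must be > 0")


def summarize(rows: Sequence[ChromosomeSummary]) -> tuple[list[ChromosomeSummary], ChromosomeSummary]:
    """Column-sum totals row; pct fields recomputed from summed bases.

    Integer count/bp columns are summed exactly; a bp column that is None in
    any row is None on the totals row.  ``pct_syntenic`` on the totals row
    is the aligned-bases-weighted value only when every row carries one.
    """
    sums: dict[str, int | None] = {}
    for name in _COUNT_FIELDS:
        vals = [getattr(r, name) for r in rows]
        sums[name] = None if any(v is None for v in vals) else int(sum(vals))
    pct = None
    if rows and all(r.pct_syntenic is not None for r in rows) and sums["aligned_bases"]:
        syntenic = sum(r.pct_syntenic / 100 * r.aligned_bases for r in rows)
        pct = 100 * syntenic / sums["aligned_bases"]
    totals = ChromosomeSummary(chrom="Total", pct_syntenic=pct, **{
        k: (v if v is not None else None) for k, v in sums.items()
    })
    return list(rows), totals


def summary_table(rows: Sequence[ChromosomeSummary]) -> pd.DataFrame:
    """Rows plus the totals row as a DataFrame (exact stored values)."""
    rows, totals = summarize(rows)
    return pd.DataFrame([r.__dict__ for r in rows] + [totals.__dict__])


def percent_aligned(
    aligned_per_chrom: Mapping[str, int], lengths: Mapping[str, int], decimals: int = 1
) -> float:
    """100 x (total aligned bases) / (total reference length), rounded for display."""
    if set(aligned_per_chrom) - set(lengths):
        missing = sorted(set(aligned_per_chrom) - set(lengths))
        raise ValueError(f"chromosomes missing from lengths: {missing}")
    for chrom, a in aligned_per_chrom.items():
        if a > lengths[chrom]:
            raise ValueError(f"{chrom}: aligned {a} exceeds length {lengths[chrom]}")
    total_len = sum(lengths[c] for c in aligned_per_chrom)
    if total_len == 0:
        raise ValueError("total chromosome length is zero")
    return round(100 * sum(aligned_per_chrom.values()) / total_len, decimals)


def expected_mutations(model: MutationModel, years: float) -> float:
    """Expected accumulated single-nucleotide mutations over ``years``.

    ``generations = years * 365 / generation_days``; the return value is
    unrounded (callers round for presentation).
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    generations = years * 365.0 / model.generation_days
    return model.mu * model.genome_sites * generations


def te_family_composition(tes: Sequence[TEAnnotation]) -> pd.DataFrame:
    """Per-chromosome and genome-wide family fractions of the class-II TE set.

    Returns a tidy frame with columns (chrom, family, count, fraction);
    ``chrom == "genome"`` rows give genome-wide values.  Fractions are of
    each chromosome's class-II elements and sum to 1 per chromosome.
    """
    import warnings

    if not tes:
        warnings.warn("empty TE annotation set; composition report is empty")
        return pd.DataFrame(columns=["chrom", "family", "count", "fraction"])
    class2 = [t for t in tes if t.te_class == "II"]
    per_chrom: dict[str, Counter] = defaultdict(Counter)
    for t in class2:
        per_chrom[t.chrom][t.family] += 1
        per_chrom["genome"][t.family] += 1
    rows = []
    for chrom in sorted(per_chrom):
        total = sum(per_chrom[chrom].values())
        for family, count in sorted(per_chrom[chrom].items()):
            rows.append(
                {"chrom": chrom, "family": family, "count": count, "fraction": count / total}
            )
    return pd.DataFrame(rows)


def family_count_difference(
    tes_a: Sequence[TEAnnotation], tes_b: Sequence[TEAnnotation]
) -> dict[str, float]:
    """Relative family-count excess of genome A over genome B, in percent.

    ``100 * (nA - nB) / nB`` per family; families absent from B map to
    ``inf`` when present in A.
    """
    ca = Counter(t.family for t in tes_a)
    cb = Counter(t.family for t in tes_b)
    out = {}
    for family in sorted(set(ca) | set(cb)):
        na, nb = ca.get(family, 0), cb.get(family, 0)
        out[family] = float("inf") if nb == 0 else 100.0 * (na - nb) / nb
    return out


def class_fractions(tes: Sequence[TEAnnotation]) -> dict[str, float]:
    """Genome-wide fraction of elements per TE class."""
    counts = Counter(t.te_class for t in tes)
    total = sum(counts.values())
    return {cls: n / total for cls, n in sorted(counts.items())} if total else {}
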