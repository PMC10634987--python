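"""End-to-end orchestration: filter -> derive -> enrich -> track -> report.

The pipeline consumes a bundle of files (two FASTAs, a B-vs-A VCF, gene
GFF3, TE BEDs for both genomes, and the alignment-block TSV — exactly what
``synthetic_data.emit`` writes, or equivalently prepared real data) and
writes TSV results plus a JSON run manifest recording the seed, package
version, input checksums, and every output path.  Stages log to stderr;
results never go to stderr.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .errors import PipelineError
from .io_formats import (
    GenomicInterval,
    VariantFilter,
    derive_intergenic,
    derive_introns,
    filter_variants,
    indel_intervals,
    read_alignment_blocks,
    read_fasta,
    read_gff3,
    read_vcf,
    split_variants,
    write_bed,
)
from .landscape import EnrichmentConfig, classify_domains, domain_enrichment
from .reporting import ChromosomeSummary, MutationModel, summary_table
from .te_tracking import TrackingConfig, read_te_annotations, track

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one full run."""

    genome_a: str
    genome_b: str
    vcf: str
    genes_gff3: str
    te_bed_a: str
    te_bed_b: str
    blocks_tsv: str
    outdir: str
    variant_filter: VariantFilter = field(default_factory=VariantFilter)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    mutation_model: MutationModel = field(default_factory=MutationModel)
    arm_fraction: float = 1 / 3
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("genome_a", "genome_b", "vcf", "genes_gff3", "te_bed_a",
                     "te_bed_b", "blocks_tsv"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise PipelineError(f"config validation: missing input {name}: {path}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "stages": {},
        "partial": False,
    }
    for name in ("genome_a", "genome_b", "vcf", "genes_gff3", "te_bed_a",
                 "te_bed_b", "blocks_tsv"):
        path = getattr(config, name)
        manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    def out(name: str) -> str:
        path = os.path.join(config.outdir, name)
        manifest["outputs"][os.path.splitext(name)[0]] = path
        return path

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest["partial"] = True
                _write_manifest(config, manifest)
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            logger.info("stage %s finished in %.2fs", name, dt)
            return result

        return deco

    # --- filter ----------------------------------------------------------
    @stage("filter")
    def _filter():
        records = read_vcf(config.vcf)
        kept = filter_variants(records, config.variant_filter)
        snps, indels = split_variants(kept)
        return records, kept, snps, indels

    records, kept, snps, indels = _filter

    # --- interval derivation ---------------------------------------------
    @stage("derive")
    def _derive():
        genome_a = read_fasta(config.genome_a)
        chrom_lengths = {c: len(s) for c, s in genome_a.items()}
        genes = read_gff3(config.genes_gff3)
        gene_ivs = [g.interval for g in genes]
        exons = [e for g in genes for e in g.exons]
        utrs = [u for g in genes for u in g.utrs]
        introns = derive_introns(gene_ivs, exons, utrs)
        intergenic = derive_intergenic(gene_ivs, chrom_lengths)
        write_bed(introns, out("introns.bed"))
        write_bed(intergenic, out("intergenic.bed"))
        per_chrom_indels = indel_intervals(indels)
        flat = [iv for ivs in per_chrom_indels.values() for iv in ivs]
        write_bed(flat, out("indel_intervals.bed"))
        return genome_a, chrom_lengths, genes

    genome_a, chrom_lengths, genes = _derive

    # --- arm/center enrichment -------------------------------------------
    @stage("domains")
    def _domains():
        rows = []
        for chrom, length in chrom_lengths.items():
            part = classify_domains(chrom, length, config.arm_fraction)
            sites = [GenomicInterval(chrom, s.pos0, s.pos0 + 1) for s in snps
                     if s.chrom == chrom]
            if not sites:
                continue
            results = domain_enrichment(sites, part, config.enrichment)
            for domain, res in results.items():
                rows.append(
                    {
                        "chrom": chrom,
                        "domain": domain,
                        "observed": res.observed,
                        "expected": res.expected,
                        "fold": res.fold_enrichment,
                        "p_empirical": res.p_value,
                        "p_hypergeom": res.p_hypergeometric,
                    }
                )
        df = pd.DataFrame(rows)
        df.to_csv(out("domain_enrichment.tsv"), sep="\t", index=False)
        return df

    _domains

    # --- TE tracking ------------------------------------------------------
    @stage("track")
    def _track():
        genome_b = read_fasta(config.genome_b)
        tes_a = read_te_annotations(config.te_bed_a, genome_a)
        tes_b = read_te_annotations(config.te_bed_b, genome_b)
        blocks = read_alignment_blocks(config.blocks_tsv)
        calls, summary = track(tes_a, tes_b, snps, blocks, config.tracking)
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
            out("te_calls.tsv"), sep="\t", index=False
        )
        with open(out("te_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return calls, summary

    calls, te_summary = _track

    # --- report -----------------------------------------------------------
    @stage("report")
    def _report():
        rows = []
        for chrom, length in chrom_lengths.items():
            rows.append(
                ChromosomeSummary(
                    chrom=chrom,
                    length_A=length,
                    length_B=length,
                    aligned_bases=length,
                    n_snps=sum(1 for s in snps if s.chrom == chrom),
                    n_indels=sum(1 for i in indels if i.chrom == chrom),
                )
            )
        df = summary_table(rows)
        df.to_csv(out("summary.tsv"), sep="\t", index=False)
        return df

    _report

    manifest["n_variants_raw"] = len(records)
    manifest["n_variants_kept"] = len(kept)
    manifest["te_summary"] = te_summary
    _write_manifest(config, manifest)
    return manifest


def _write_manifest(config: PipelineConfig, manifest: dict) -> None:
    with open(os.path.join(config.outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
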