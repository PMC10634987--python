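"""Simulator invariants: determinism, conservation, consistency, round trips."""

import numpy as np
import pytest

from conftest import small_config
from wormdrift.errors import SizingError
from wormdrift.io_formats import read_vcf
from wormdrift.landscape import classify_domains, domain_fraction
from wormdrift.io_formats import GenomicInterval
from wormdrift.synthetic_data import (
    SimConfig,
    apply_truth,
    build_ancestor,
    load_bundle,
    simulate,
)
from wormdrift.te_tracking import liftover, _BlockIndex


def test_seeded_determinism_in_memory_and_on_disk(tmp_path):
    cfg = small_config(seed=11)
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    ga1, gb1, t1 = simulate(cfg, out_a)
    ga2, gb2, t2 = simulate(cfg, out_b)
    assert ga1 == ga2 and gb1 == gb2
    assert t1.snps == t2.snps and t1.svs == t2.svs and t1.te_moves == t2.te_moves
    for f in sorted(p.name for p in out_a.iterdir()):
        assert (out_a / f).read_bytes() == (out_b / f).read_bytes(), f


def test_all_zero_config_gives_identical_genomes_and_whole_chrom_blocks():
    cfg = small_config(
        snp_rate=0, indel_rate=0, te_private_snp_rate=0,
        n_te_moves_intra=0, n_te_moves_inter=0, n_te_dups=0,
        sv_spec={},
    )
    ga, gb, truth = simulate(cfg)
    assert ga == gb
    assert truth.snps == [] and truth.indels == [] and truth.svs == []
    assert truth.te_moves == []
    assert len(truth.alignment_blocks) == cfg.n_chromosomes
    for b in truth.alignment_blocks:
        assert b.ref == b.qry and b.strand == "+"
        assert len(b.ref) == cfg.chrom_length


def test_event_count_conservation(small_sim):
    cfg, _, _, truth = small_sim
    kinds = [m.kind for m in truth.te_moves]
    assert kinds.count("intra") == cfg.n_te_moves_intra
    assert kinds.count("inter") == cfg.n_te_moves_inter
    assert kinds.count("duplication") == cfg.n_te_dups
    by_type = {}
    for sv in truth.svs:
        by_type[sv.sv_type] = by_type.get(sv.sv_type, 0) + 1
    assert by_type == {t: s.count for t, s in cfg.sv_spec.items() if s.count}
    for mv in truth.te_moves:
        if mv.kind == "inter":
            assert mv.src_chrom != mv.dst_chrom
        elif mv.kind == "intra":
            assert mv.src_chrom == mv.dst_chrom and mv.src_start0 != mv.dst_start0


def test_te_private_substitution_rate_matches_binomial_expectation():
    """Mean Hamming distance of 20 copies from a 1000-bp consensus at rate 0.05."""
    lib = (("Zator", "".join("ACGT"[i % 4] for i in range(1_000))),)
    cfg = SimConfig(
        n_chromosomes=1, chrom_length=200_000, te_library=lib, n_te_copies=20,
        te_private_snp_rate=0.05, n_te_moves_intra=0, n_te_moves_inter=0,
        n_te_dups=0, sv_spec={}, n_genes=4, seed=3,
    )
    anc = build_ancestor(cfg)
    consensus = lib[0][1]
    dists = [
        sum(a != b for a, b in zip(te.sequence, consensus)) for te in anc.te_copies
    ]
    mean = np.mean(dists)
    sigma = np.sqrt(1_000 * 0.05 * 0.95 / 20)
    assert abs(mean - 50) < 3 * sigma


def test_zero_private_rate_gives_identical_copies():
    lib = (("Zator", "ACGT" * 100),)
    cfg = SimConfig(
        n_chromosomes=1, chrom_length=100_000, te_library=lib, n_te_copies=2,
        te_private_snp_rate=0, n_te_moves_intra=0, n_te_moves_inter=0,
        n_te_dups=0, sv_spec={}, n_genes=2, seed=0,
    )
    anc = build_ancestor(cfg)
    assert anc.te_copies[0].sequence == anc.te_copies[1].sequence


def test_arm_biased_snp_fraction_matches_density_mixture():
    """arm_bias=3 over terminal thirds puts ~85.7% of SNPs on the arms."""
    cfg = SimConfig(
        seed=5, n_te_copies=0, n_te_moves_intra=0, n_te_moves_inter=0, n_te_dups=0,
    )
    _, _, truth = simulate(cfg)
    n = len(truth.snps)
    assert n >= 2_000
    expected = (3 * 2 / 3) / (3 * 2 / 3 + 1 / 3)
    a = int(cfg.chrom_length / 3)
    in_arms = sum(
        1 for s in truth.snps if s.pos0 < a or s.pos0 >= cfg.chrom_length - a
    )
    sigma = np.sqrt(expected * (1 - expected) / n)
    assert abs(in_arms / n - expected) < 3 * sigma


def test_coordinate_consistency_outside_events(small_sim):
    """Non-event positions lift through the block map to the identical base."""
    _, genome_a, genome_b, truth = small_sim
    index = _BlockIndex(truth.alignment_blocks)
    snp_positions = {(s.chrom, s.pos0) for s in truth.snps}
    rng = np.random.default_rng(0)
    checked = 0
    for chrom, seq in genome_a.items():
        for pos in rng.integers(0, len(seq), size=300):
            if (chrom, int(pos)) in snp_positions:
                continue  # substituted base: covered by a planted SNP
            hit = liftover(chrom, int(pos), index)
            if hit is None:
                continue  # inside a planted event's footprint
            block, _ = index.locate(chrom, int(pos))
            if block.strand != "+":
                continue  # inverted span: bases are complemented by design
            qc, qp = hit
            assert genome_b[qc][qp] == seq[int(pos)]
            checked += 1
    assert checked > 400


def test_truth_reapplication_reconstructs_genome_b(small_sim):
    _, genome_a, genome_b, truth = small_sim
    assert apply_truth(genome_a, truth) == genome_b


def test_emit_round_trip_reproduces_truth(small_bundle, small_sim):
    _, genome_a, genome_b, truth = small_sim
    ga, gb, loaded = load_bundle(small_bundle)
    assert ga == genome_a and gb == genome_b
    assert loaded.snps == truth.snps
    assert loaded.indels == truth.indels
    assert loaded.svs == truth.svs
    assert loaded.te_moves == truth.te_moves
    assert loaded.alignment_blocks == truth.alignment_blocks
    assert loaded.te_annotations_A == truth.te_annotations_A
    assert loaded.te_annotations_B == truth.te_annotations_B
    # and the reloaded truth still reconstructs genome B
    assert apply_truth(ga, loaded) == gb


def test_vcf_positions_are_one_based(small_bundle, small_sim):
    _, _, _, truth = small_sim
    records = read_vcf(small_bundle / "variants_B_vs_A.vcf")
    vcf_snps = {(r.chrom, r.pos) for r in records if r.var_class == "snp"}
    assert vcf_snps == {(s.chrom, s.pos0 + 1) for s in truth.snps}


def test_te_placement_avoids_exons(small_sim):
    cfg, _, _, truth = small_sim
    coding = [e for g in truth.genes for e in g.exons + g.utrs]
    for te in truth.te_annotations_A:
        assert not any(te.interval.overlaps(c) for c in coding)


def test_oversized_request_raises_sizing_error():
    with pytest.raises(SizingError):
        build_ancestor(small_config(n_te_copies=5_000))


def test_arm_fraction_of_variants_feeds_domain_partition(small_sim):
    """Smoke: truth SNP positions can be classified against the partition."""
    cfg, genome_a, _, truth = small_sim
    chrom = next(iter(genome_a))
    part = classify_domains(chrom, len(genome_a[chrom]), cfg.arm_fraction)
    sites = [GenomicInterval(chrom, s.pos0, s.pos0 + 1) for s in truth.snps
             if s.chrom == chrom]
    frac = domain_fraction(sites, part)
    assert 0 < frac["arms"] < 1
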