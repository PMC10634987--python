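"""Fingerprinting, matching, liftover, and movement calls."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from wormdrift.errors import CoordinateMismatchError
from wormdrift.io_formats import (
    HOMOZYGOUS,
    AlignmentBlock,
    GenomicInterval,
    VariantRecord,
    filter_variants,
    reverse_complement,
    split_variants,
)
from wormdrift.te_tracking import (
    CALL_DUP,
    CALL_INTER,
    CALL_INTRA,
    CALL_UNMOVED,
    TEAnnotation,
    TEMatch,
    TrackingConfig,
    call_movement,
    expected_query_position,
    fingerprint_tes,
    invert_blocks,
    liftover,
    match_fingerprints,
    sequence_identity,
    track,
)

iv = GenomicInterval


def _te(te_id, chrom, start, seq, family="Zator"):
    return TEAnnotation(
        te_id, chrom, iv(chrom, start, start + len(seq)), "+", family, "II", seq
    )


def _snp(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, alt, 60.0, 45, 50, HOMOZYGOUS)


# ---------------------------------------------------------------------------
# Fingerprinting
# ---------------------------------------------------------------------------


def test_fingerprint_substitutes_alt_at_offset():
    te = _te("t1", "I", 100, "ACGTACGTAC")
    fps = fingerprint_tes([te], [_snp("I", 105, "A", "G")])
    assert len(fps) == 1
    assert fps[0].fingerprint == "ACGTGCGTAC"
    assert fps[0].applied_snps == ((4, "A", "G"),)
    assert fps[0].is_unique


def test_snpless_te_is_not_fingerprinted():
    a = _te("t1", "I", 100, "ACGTACGTAC")
    b = _te("t2", "I", 500, "ACGTACGTAC")
    fps = fingerprint_tes([a, b], [_snp("I", 105, "A", "G")])
    assert [fp.te.te_id for fp in fps] == ["t1"]


def test_identical_fingerprints_are_flagged_not_unique():
    a = _te("t1", "I", 100, "ACGTACGTAC")
    b = _te("t2", "I", 500, "ACGTACGTAC")
    snps = [_snp("I", 105, "A", "G"), _snp("I", 505, "A", "G")]
    fps = fingerprint_tes([a, b], snps)
    assert len(fps) == 2
    assert all(not fp.is_unique for fp in fps)
    # but uniqueness is per family: a same-string fingerprint in another
    # family does not clash when same_family_only is on
    c = _te("t3", "II", 100, "ACGTACGTAC", family="Sola")
    fps = fingerprint_tes([a, c], [_snp("I", 105, "A", "G"), _snp("II", 105, "A", "G")])
    assert all(fp.is_unique for fp in fps)


def test_ref_mismatch_raises_naming_te():
    te = _te("t9", "I", 100, "ACGTACGTAC")
    with pytest.raises(CoordinateMismatchError, match="t9"):
        fingerprint_tes([te], [_snp("I", 105, "C", "G")])


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def test_exact_match_and_multiplicity():
    te = _te("t1", "I", 100, "ACGTACGTAC")
    fps = fingerprint_tes([te], [_snp("I", 105, "A", "G")])
    q1 = _te("q1", "II", 0, "ACGTGCGTAC")
    q2 = _te("q2", "II", 900, "ACGTGCGTAC")
    matches = match_fingerprints(fps, [q1, q2], TrackingConfig())
    assert matches == [TEMatch("t1", ("q1", "q2"), 1.0)]


def test_match_respects_min_identity_hamming():
    te = _te("t1", "I", 100, "ACGTACGTAC")
    fps = fingerprint_tes([te], [_snp("I", 105, "A", "G")])
    # query differs from the fingerprint at exactly 1 of 10 positions
    q = _te("q1", "II", 0, "ACGTGCGTAA")
    assert sequence_identity(fps[0].fingerprint, q.sequence) == pytest.approx(0.9)
    assert match_fingerprints(fps, [q], TrackingConfig()) == []
    matches = match_fingerprints(fps, [q], TrackingConfig(min_identity=0.9))
    assert matches and matches[0].identity == pytest.approx(0.9)


def test_reverse_complement_orientation_is_found():
    te = _te("t1", "I", 100, "ACGTGCGTAC")
    fps = fingerprint_tes([te], [_snp("I", 105, "G", "A")])
    rc = reverse_complement(fps[0].fingerprint)
    q = _te("q1", "II", 0, rc)
    assert match_fingerprints(fps, [q], TrackingConfig()) == [TEMatch("t1", ("q1",), 1.0)]
    assert match_fingerprints(fps, [q], TrackingConfig(try_reverse_complement=False)) == []


def test_unequal_lengths_never_match_exactly():
    assert sequence_identity("ACGT", "ACGTA") == pytest.approx(4 / 5)
    te = _te("t1", "I", 100, "ACGTACGTAC")
    fps = fingerprint_tes([te], [_snp("I", 105, "A", "G")])
    q = _te("q1", "II", 0, fps[0].fingerprint + "AA")
    assert match_fingerprints(fps, [q], TrackingConfig()) == []


# ---------------------------------------------------------------------------
# Liftover
# ---------------------------------------------------------------------------


def test_liftover_identity_map():
    blocks = [AlignmentBlock(iv("chrI", 0, 100_000), iv("chrI", 0, 100_000), "+")]
    assert liftover("chrI", 20_000, blocks) == ("chrI", 20_000)


def test_liftover_minus_strand_formula():
    blocks = [AlignmentBlock(iv("chrI", 1_000, 2_000), iv("chrII", 5_000, 6_000), "-")]
    assert liftover("chrI", 1_500, blocks) == ("chrII", 5_499)
    assert liftover("chrI", 1_000, blocks) == ("chrII", 5_999)
    assert liftover("chrI", 1_999, blocks) == ("chrII", 5_000)


def test_liftover_gap_is_absent():
    blocks = [AlignmentBlock(iv("chrI", 0, 100), iv("chrI", 0, 100), "+")]
    assert liftover("chrI", 150, blocks) is None
    assert liftover("chrII", 10, blocks) is None


@given(st.integers(0, 999))
def test_liftover_round_trip_through_reciprocal_blocks(offset):
    """Lifting a position and lifting back through the swapped map is identity."""
    blocks = [
        AlignmentBlock(iv("I", 100, 1_100), iv("II", 5_000, 6_000), "+"),
        AlignmentBlock(iv("I", 2_000, 3_000), iv("I", 0, 1_000), "-"),
    ]
    inverse = invert_blocks(blocks)
    for block in blocks:
        pos = block.ref.start + offset
        chrom_q, pos_q = liftover(block.ref.chrom, pos, blocks)
        assert liftover(chrom_q, pos_q, inverse) == (block.ref.chrom, pos)


def test_expected_position_at_clean_deletion_gap_is_junction():
    # reference [100,200) is absent from the query: flanks are query-adjacent
    blocks = [
        AlignmentBlock(iv("I", 0, 100), iv("I", 0, 100), "+"),
        AlignmentBlock(iv("I", 200, 300), iv("I", 100, 200), "+"),
    ]
    assert expected_query_position("I", 150, blocks) == ("I", 100)
    assert expected_query_position("I", 50, blocks) == ("I", 50)  # inside a block


def test_expected_position_at_divergent_gap_is_unresolvable():
    # the query side jumps across the gap (NOTAL-style divergence)
    blocks = [
        AlignmentBlock(iv("I", 0, 100), iv("I", 0, 100), "+"),
        AlignmentBlock(iv("I", 200, 300), iv("I", 250, 350), "+"),
    ]
    assert expected_query_position("I", 150, blocks) is None
    # flanks on different query chromosomes: also unresolvable
    blocks = [
        AlignmentBlock(iv("I", 0, 100), iv("I", 0, 100), "+"),
        AlignmentBlock(iv("I", 200, 300), iv("II", 100, 200), "+"),
    ]
    assert expected_query_position("I", 150, blocks) is None


# ---------------------------------------------------------------------------
# Movement calls
# ---------------------------------------------------------------------------


def _identity_blocks():
    return [AlignmentBlock(iv("I", 0, 100_000), iv("I", 0, 100_000), "+"),
            AlignmentBlock(iv("II", 0, 100_000), iv("II", 0, 100_000), "+")]


def test_call_unmoved_within_tolerance():
    ref = _te("t1", "I", 20_000, "ACGTACGTAC")
    qry = _te("q1", "I", 20_030, "ACGTGCGTAC")
    calls = call_movement([TEMatch("t1", ("q1",), 1.0)], [ref], [qry], _identity_blocks())
    assert calls[0].call == CALL_UNMOVED
    assert calls[0].displacement == 30


def test_call_intrachromosomal_beyond_tolerance():
    ref = _te("t1", "I", 20_000, "ACGTACGTAC")
    qry = _te("q1", "I", 80_000, "ACGTGCGTAC")
    calls = call_movement([TEMatch("t1", ("q1",), 1.0)], [ref], [qry], _identity_blocks())
    assert calls[0].call == CALL_INTRA
    assert calls[0].displacement == 60_000


def test_call_interchromosomal_on_chromosome_mismatch():
    ref = _te("t1", "I", 20_000, "ACGTACGTAC")
    qry = _te("q1", "II", 20_000, "ACGTGCGTAC")
    calls = call_movement([TEMatch("t1", ("q1",), 1.0)], [ref], [qry], _identity_blocks())
    assert calls[0].call == CALL_INTER


def test_call_duplicated_when_multiple_query_copies():
    ref = _te("t1", "I", 20_000, "ACGTACGTAC")
    q1 = _te("q1", "I", 20_000, "ACGTGCGTAC")
    q2 = _te("q2", "II", 50_000, "ACGTGCGTAC")
    calls = call_movement([TEMatch("t1", ("q1", "q2"), 1.0)], [ref], [q1, q2], _identity_blocks())
    assert calls[0].call == CALL_DUP
    assert calls[0].n_query_copies == 2


def test_call_movement_rejects_unknown_te_id():
    with pytest.raises(KeyError, match="ghost"):
        call_movement([TEMatch("ghost", ("q1",), 1.0)], [], [], _identity_blocks())


def test_tolerance_monotonicity():
    ref = _te("t1", "I", 20_000, "ACGTACGTAC")
    qry = _te("q1", "I", 21_500, "ACGTGCGTAC")
    matches = [TEMatch("t1", ("q1",), 1.0)]
    n_intra = []
    for tol in (100, 1_000, 2_000, 10_000):
        calls = call_movement(matches, [ref], [qry], _identity_blocks(),
                              TrackingConfig(tolerance_bp=tol))
        n_intra.append(sum(c.call == CALL_INTRA for c in calls))
    assert n_intra == sorted(n_intra, reverse=True)


# ---------------------------------------------------------------------------
# Full tracking against the simulator's truth
# ---------------------------------------------------------------------------


def test_track_recovers_planted_moves_exactly(small_sim):
    cfg, _, _, truth = small_sim
    snps, _ = split_variants(filter_variants(truth.to_variant_records()))
    calls, summary = track(
        truth.te_annotations_A, truth.te_annotations_B, snps,
        truth.alignment_blocks, TrackingConfig(tolerance_bp=1_000),
    )
    assert len(calls) == summary["n_matched"]
    by_id = {c.ref_te_id: c for c in calls}
    kinds = {"intra": CALL_INTRA, "inter": CALL_INTER, "duplication": CALL_DUP}
    for mv in truth.te_moves:
        assert by_id[mv.te_id].call == kinds[mv.kind], mv
    assert summary["calls"][CALL_INTRA] == cfg.n_te_moves_intra
    assert summary["calls"][CALL_INTER] == cfg.n_te_moves_inter
    assert summary["calls"][CALL_DUP] == cfg.n_te_dups


def test_track_with_no_snps_yields_no_calls(small_sim):
    _, _, _, truth = small_sim
    calls, summary = track(
        truth.te_annotations_A, truth.te_annotations_B, [], truth.alignment_blocks
    )
    assert calls == []
    assert summary["n_fingerprinted"] == 0


def test_interchromosomal_calls_are_definitional(small_sim):
    """A call is interchromosomal iff observed chrom differs from liftover chrom."""
    _, _, _, truth = small_sim
    snps, _ = split_variants(filter_variants(truth.to_variant_records()))
    calls, _ = track(truth.te_annotations_A, truth.te_annotations_B, snps,
                     truth.alignment_blocks)
    for c in calls:
        if c.expected_qry_chrom is not None and c.n_query_copies == 1:
            assert (c.call == CALL_INTER) == (c.observed_qry_chrom != c.expected_qry_chrom)
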