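"""Domain classification, binning, and the permutation enrichment test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wormdrift.io_formats import GenomicInterval
from wormdrift.landscape import (
    EnrichmentConfig,
    bin_counts,
    classify_domains,
    domain_enrichment,
    enrichment_test,
    randomize_intervals,
)

iv = GenomicInterval


# ---------------------------------------------------------------------------
# Domains
# ---------------------------------------------------------------------------


def test_classify_domains_terminal_thirds():
    part = classify_domains("I", 9_000_000)
    assert part.left_arm == iv("I", 0, 3_000_000)
    assert part.center == iv("I", 3_000_000, 6_000_000)
    assert part.right_arm == iv("I", 6_000_000, 9_000_000)


def test_classify_domains_floor_convention():
    part = classify_domains("I", 10)
    assert (part.left_arm, part.center, part.right_arm) == (
        iv("I", 0, 3), iv("I", 3, 7), iv("I", 7, 10)
    )


def test_classify_domains_half_fraction_empty_center():
    part = classify_domains("I", 10, arm_fraction=0.5)
    assert len(part.center) == 0


def test_classify_domains_rejects_tiny_chromosome():
    with pytest.raises(ValueError):
        classify_domains("I", 2)


@given(st.integers(3, 10_000_000), st.floats(0.01, 0.5))
def test_partition_tiles_chromosome_exactly(length, fraction):
    part = classify_domains("I", length, fraction)
    assert len(part.left_arm) + len(part.center) + len(part.right_arm) == length
    assert part.left_arm.end == part.center.start
    assert part.center.end == part.right_arm.start


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def test_bin_counts_examples():
    counts = bin_counts([50, 150_000], 250_000)
    assert counts.tolist() == [1, 1, 0]
    assert bin_counts([], 250_000).tolist() == [0, 0, 0]
    # interval spanning a boundary counts in its start bin only
    spanning = [iv("I", 99_999, 100_500)]
    assert bin_counts(spanning, 250_000).tolist() == [1, 0, 0]


def test_bin_counts_sum_equals_feature_count():
    rng = np.random.default_rng(0)
    points = rng.integers(0, 1_000_000, size=500)
    assert bin_counts(points, 1_000_000).sum() == 500


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------


def test_randomize_uniform_law():
    """A 1-bp interval in a 10-bp workspace lands on each start ~10% of draws."""
    ws = iv("I", 0, 10)
    rng = np.random.default_rng(42)
    counts = np.zeros(10)
    n = 10_000
    for _ in range(n):
        (placed,) = randomize_intervals([iv("I", 3, 4)], ws, rng)
        counts[placed.start] += 1
    freqs = counts / n
    sigma = np.sqrt(0.1 * 0.9 / n)
    assert np.all(np.abs(freqs - 0.1) < 3 * sigma + 1e-12)


def test_randomize_forced_and_deterministic():
    ws = iv("I", 5, 15)
    (placed,) = randomize_intervals([iv("I", 0, 10)], ws, seed=1)
    assert placed == ws  # length == workspace forces the start
    a = randomize_intervals([iv("I", 0, 3)] * 5, ws, seed=7)
    b = randomize_intervals([iv("I", 0, 3)] * 5, ws, seed=7)
    assert a == b
    with pytest.raises(ValueError, match="longer than workspace"):
        randomize_intervals([iv("I", 0, 11)], ws, seed=0)


# ---------------------------------------------------------------------------
# Enrichment test
# ---------------------------------------------------------------------------


def test_whole_workspace_annotation_gives_fold_one_p_one():
    ws = iv("I", 0, 1_000)
    query = [iv("I", 10, 20), iv("I", 500, 501)]
    res = enrichment_test(query, [ws], ws, EnrichmentConfig(n_iterations=200, seed=0))
    assert res.fold_enrichment == 1.0
    assert res.p_value == 1.0


def test_binomial_expectation_for_half_workspace_annotation():
    ws = iv("I", 0, 1_000_000)
    annotation = [iv("I", 0, 500_000)]
    query = [iv("I", p, p + 1) for p in range(1_000, 101_000, 1_000)]  # 100 sites inside
    res = enrichment_test(query, annotation, ws, EnrichmentConfig(n_iterations=2_000, seed=3))
    assert res.observed == 100
    assert abs(res.expected - 50) < 5
    assert 1.9 <= res.fold_enrichment <= 2.1


def test_hypergeometric_exact_small_case():
    # workspace 10 bases, annotation 5, query 2 bases both inside:
    # upper tail P(X >= 2) = C(5,2)/C(10,2) = 10/45
    ws = iv("I", 0, 10)
    res = enrichment_test(
        [iv("I", 0, 1), iv("I", 2, 3)],
        [iv("I", 0, 5)],
        ws,
        EnrichmentConfig(n_iterations=10, seed=0, p_method="hypergeometric"),
    )
    assert res.p_hypergeometric == pytest.approx(10 / 45, rel=1e-9)
    assert res.p_value == res.p_hypergeometric


def test_empty_annotation_warns_and_reports_infinite_fold():
    ws = iv("I", 0, 100)
    with pytest.warns(UserWarning, match="zero"):
        res = enrichment_test([iv("I", 5, 6)], [], ws, EnrichmentConfig(n_iterations=50, seed=0))
    assert np.isnan(res.fold_enrichment)  # observed is also zero


def test_rejects_query_outside_workspace():
    with pytest.raises(ValueError, match="outside workspace"):
        enrichment_test([iv("I", 90, 110)], [iv("I", 0, 50)], iv("I", 0, 100))


# ---------------------------------------------------------------------------
# Domain enrichment
# ---------------------------------------------------------------------------


def test_uniform_variants_give_arm_fold_near_one():
    part = classify_domains("I", 300_000)
    rng = np.random.default_rng(5)
    sites = [iv("I", int(p), int(p) + 1) for p in rng.integers(0, 300_000, 600)]
    res = domain_enrichment(sites, part, EnrichmentConfig(n_iterations=2_000, seed=9))
    assert abs(res["arms"].fold_enrichment - 1.0) < 0.1
    assert abs(res["center"].fold_enrichment - 1.0) < 0.15


def test_all_center_variants_deplete_arms():
    part = classify_domains("I", 300_000)
    sites = [iv("I", p, p + 1) for p in range(140_000, 160_000, 200)]
    res = domain_enrichment(sites, part, EnrichmentConfig(n_iterations=2_000, seed=4))
    assert res["arms"].observed == 0
    assert res["arms"].fold_enrichment == 0
    assert res["arms"].p_depletion < 0.01


def test_domain_enrichment_rejects_foreign_chromosome():
    part = classify_domains("I", 1_000)
    with pytest.raises(ValueError, match="partition"):
        domain_enrichment([iv("II", 0, 1)], part)
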