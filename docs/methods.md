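# Methods

This note documents the models, conventions, and numerical choices behind
wormdrift, in the order a comparison runs: coordinates and formats,
variant filtering and interval algebra, the landscape/enrichment machinery,
TE fingerprint tracking, the reporting arithmetic, and the synthetic
genome-pair generator that the tests exercise everything against.

## Coordinates and formats

All in-memory coordinates are 0-based half-open (`[start, end)`), the
convention under which interval arithmetic has no off-by-one cases.
Conversions happen exactly once, at format boundaries: VCF and GFF3 are
1-based inclusive as their specifications demand; structural-variant
tables are read in the 1-based inclusive dialect that SyRI-style callers
emit and converted on load; BED and the alignment-block TSV are already
0-based half-open.  The SV type vocabulary is closed
(NOTAL/DEL/INS/CPG/CPL/TDM/INV/DUP/TRANS/INVTR/HDR/SYN); unknown codes are
an error naming the code and line.  An SV's size is the larger of its
reference and query spans, which makes deletions reference-sized and
insertions query-sized.  One-sided NOTAL records carry only a reference
interval; query-side non-alignable regions come from reading the
reciprocal table produced with reference and query swapped.

## Variant filtering and indel intervals

The default filter retains calls with QUAL ≥ 30, at least 10 reads
supporting the alternate allele, at least 30 total high-quality reads, and
a homozygous genotype.  Thresholds are inclusive; records missing any of
these annotations fail closed.  Heterozygous records are retained by the
reader and excluded only by the filter, so analyses that want the larger
heterozygous-inclusive counts can have them by flipping one flag.

Indel intervals are the reference span of the REF allele:
`[POS−1, POS−1+len(REF))`.  A deletion therefore covers the deleted bases
plus the anchor; an insertion contributes only its 1-bp anchor.  Whether
the anchor base belongs in the interval is a genuine convention choice;
this one is base-accurate (removing the named bases and re-inserting ALT
reproduces the edited sequence) and is applied uniformly.

Introns are computed per gene as the gene span minus the union of its exon
and UTR intervals, with features associated to genes by containment; a
feature that pokes beyond its gene is an error naming the gene, and a gene
with no features at all is emitted whole as one intron with a warning.
Intergenic space is the per-chromosome complement of the gene union.  Both
operations are verified in the test suite against a per-base boolean-mask
oracle on randomized toy annotation sets.

## Chromosome landscape and enrichment

*C. elegans* chromosomes carry most of their sequence variation, repeats,
and recombination on their terminal thirds.  `classify_domains` partitions
`[0, L)` into `[0, a)`, `[a, L−a)`, `[L−a, L)` with
`a = floor(arm_fraction · L)` and `arm_fraction = 1/3` by default;
`arm_fraction = 0.5` legally produces a zero-length center.  Density
binning uses 100-kb windows; an interval is counted in the bin containing
its start, so counts always sum to the number of features.

The enrichment test mirrors GAT-style association testing.  The observed
overlap between query intervals and an annotation (bases by default, or
the count of overlapping query intervals) is compared with the overlap
distribution over `n_iterations` placements (default 20,000) in which each
query interval keeps its length and its start is drawn uniformly over the
positions that keep it inside the workspace; placed intervals may overlap
each other.  Fold enrichment is observed over mean simulated overlap.
The empirical p-value uses the +1 pseudocount,
`p = (1 + #{sim ≥ obs}) / (n + 1)` for enrichment and symmetrically for
depletion, with the reported two-sided value `min(1, 2·min)`; it can never
be exactly zero.  A hypergeometric tail probability on base counts
(population = workspace bases, successes = annotation bases, draws = query
bases) is always computed alongside, because the two can disagree — the
permutation p is the default precisely because it matches the simulation
null.  When the expected overlap is zero the fold is reported as infinite
with a warning rather than raising.

Randomization is per chromosome (the workspace is one chromosome), the two
arms are pooled into a single annotation for domain tests, and no
multiple-testing correction is applied across chromosomes; callers see raw
p-values.  Whether overlap should be measured in bases or features, and
whether arms should be tested jointly, are genuinely open choices; the
defaults (bases, pooled arms) are documented here and configurable.

Calibration: under a uniform null (random 1-bp query sites), the two-sided
empirical p is approximately uniform; across 500 replicates of 2,000
iterations the fraction with p < 0.05 lands near 0.04, within the
0.02–0.08 band the test suite enforces.  The permutation machinery is
vectorized (annotation coverage prefix sums + searchsorted, iterations in
batches of 512), which keeps 20,000-iteration runs interactive.

## TE fingerprint tracking

A TE family's copies are near-identical, so a copy cannot be tracked by
sequence alone.  But SNPs called between the genomes that overlap a
reference copy, substituted into its sequence at offset
`snp_pos − te_start`, yield a fingerprint that is usually private to the
copy.  Only TEs overlapping at least one SNP are fingerprinted; a SNP
whose REF base disagrees with the TE sequence signals a coordinate
mismatch and raises immediately.  Uniqueness is exact string uniqueness of
the fingerprint within its family (genome-wide if `same_family_only` is
off) — the strictest reading, requiring no alignment heuristics.  Matching
against the query genome's TE set demands exact sequence identity by
default (`min_identity = 1.0`, hash lookup); at lower thresholds identity
is matching positions over the shorter length divided by the longer
length, a cheap deterministic score.  The reverse complement of each query
sequence is also tried, since an element may reinsert in either
orientation.  Indels are deliberately *not* applied to fingerprints: a
copy whose span is disrupted by an indel or SV in the query simply fails
to match and is reported unmatched rather than guessed at.

Movement classification compares the matched query position with the
position *expected* from the whole-genome alignment.  Liftover through
gap-free blocks maps `pos` to `qry_start + (pos − ref_start)` on `+`
blocks and `qry_start + (ref_end − 1 − pos)` on `−` blocks.  A moved
element is excised from its source locus, so its reference start always
falls in an alignment gap; the expectation there is taken from the gap's
flanks.  If both flanking blocks exist, map to the same query chromosome
on the forward strand, and are query-adjacent (`left.qry_end ==
right.qry_start`), the gap is a clean deletion in the query and the
expected position is that junction point.  Any other gap — a non-alignable
region where the query side also jumps, a strand switch, a translocation
breakpoint — offers no defensible expectation and the call is
`unresolvable`.  With an expectation in hand: more than one matched query
copy ⇒ `duplicated_in_query`; a different observed chromosome ⇒
`interchromosomal`; a same-chromosome displacement beyond `tolerance_bp`
⇒ `intrachromosomal`; otherwise `unmoved`.  The tolerance default of
1,000 bp sits well above alignment jitter and far below the inter-locus
distances at which transposition is biologically interesting; it is
exposed in `TrackingConfig`, and raising it can only shrink the
intrachromosomal call set (a monotonicity the tests assert).

## Reporting

Comparison tables are assembled from per-chromosome rows; the totals row
is an exact integer column sum, and percentage cells on it are recomputed
from summed numerators and denominators, never averaged.  Percent aligned
is `100 · Σ aligned / Σ length` over the reference lengths.  All stored
values are unrounded; rounding happens only at presentation.  The
published per-chromosome tables for the three lab-strain comparisons ship
in `reference_tables.py` as inputs to this arithmetic.  TE composition
reports per-chromosome family fractions of the class-II set (summing to 1
per chromosome) and relative family-count differences between genomes as
`100 · (nA − nB) / nB`.

The mutation-accumulation model is deliberately minimal:
`E = μ · L · g` with `g = years · 365 / generation_days`, defaults
μ = 2.7 × 10⁻⁹ per site per generation, L = 10⁸ sites, 3-day generations.
Years elapsed is always an explicit input — "since the 1970s" is not a
date — and the unrounded expectation is returned (≈ 788.4 over 24 years,
≈ 1,511 over 46).

## The synthetic genome-pair generator

The generator emulates what the real comparison sees, not how the real
data arose: two lineages that differ by an enumerable set of events, with
the alignment-block map a whole-genome aligner would recover at block
resolution.  An ancestral genome (uniform random sequence) receives
non-overlapping genes (1.5–4 kb, UTR–exon–intron structure with ≥ 50-bp
pieces) and TE copies drawn from a fixed consensus library spanning the
DNA-transposon families (Tc1/mariner, Zator, Sola, hAT, CMC, MITE,
Novosib, Helitron; 0.8–1.6 kb).  Each copy diverges from its consensus by
per-base substitutions at `te_private_snp_rate` (default 0.02), which is
what makes copies of a family distinguishable.  TE placements avoid exons
and UTRs; introns and intergenic space are allowed, as in real genomes.

Lineage B is genome A plus: arm-biased SNPs (a SNP falls in the pooled
arms with probability `bias·2f / (bias·2f + 1−2f)`, uniform within the
chosen domain; defaults bias = 3, f = 1/3, giving an arm fraction of
≈ 0.857 and an arm fold enrichment of ≈ 1.29); short indels (≤ 10 bp,
VCF-style anchored alleles); one planned spectrum of ≥ 50-bp SVs — DEL,
INS (random payload), INV (reverse complement in place, emitted as a
`−`-strand alignment block), DUP (tandem copy), TRANS (excision and
reinsertion on another chromosome), NOTAL (equal-length random
replacement, breaking the alignment on both sides) — and TE moves:
excision of a copy from its A-locus context with reinsertion elsewhere
(same chromosome for intra, different for inter; duplications leave the
source intact).  The same `te_private_snp_rate` also plants B-lineage
substitutions *inside* every TE copy; these are real truth SNPs, they are
what makes copies fingerprintable from the VCF, and because structural
payloads are taken from the SNP-substituted sequence, a moved copy carries
its fingerprint to its destination — exactly the signal the tracking
procedure keys on.

All event footprints are kept mutually disjoint by rejection-resampling
against an interval tree with a bounded retry count (default 1,000;
exhaustion raises a sizing error naming the constraint).  Genome-wide SNPs
avoid other events' footprints but may fall inside TE and DUP spans, where
they are consistent by construction.  Planted move destinations are at
least `min_move_displacement` (default 20 kb) from the source so that,
even after coordinate shifts from other events, realized displacements
stay an order of magnitude above the 1-kb tracking tolerance.  One seeded
`numpy` generator per stage (derived from `SimConfig.seed`) makes the
whole bundle byte-reproducible.

Genome B and the block map are built in a single left-to-right walk:
stretches between events become `+` alignment blocks, inversions become
`−` blocks, and everything else breaks synteny.  Consequences worth
knowing: any A position outside every event footprint lifts to a B
position carrying the identical base; a TE excision leaves a clean
deletion gap whose flanks are query-adjacent (resolvable junction), while
a NOTAL gap jumps on both sides (unresolvable) — the two gap geometries
the movement caller distinguishes.

An independent re-application path, `apply_truth`, rebuilds genome B from
genome A and the truth records alone by naive string splicing
(substitutions first, then structural edits right-to-left).  It shares no
construction code with the builder and must reproduce genome B exactly;
the test suite and acceptance script both enforce this.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: sequencing reads and their errors (variant calls
are idealized, QUAL 60, depth 50, always homozygous and always correct);
alignment ambiguity in repeats (block maps are exact, so liftover never
errs); nested or overlapping events (real SVs can stack); TE placement
bias toward arms (placement is uniform, which is also why the arm-bias
closed-form checks use a TE-free configuration — with TEs present the
pooled SNP arm fraction is a mixture of the arm-biased genome-wide process
and the uniform TE-internal substitutions); base composition, repeat
families beyond the TE library, and selection.  Recovery results on this
simulator are therefore an upper bound on real-data sensitivity: they
validate the logic of fingerprinting, liftover, and classification, not
the robustness of TE annotation or alignment under real noise.

## Problem sizes used in the checks

The recovery suite runs 20 seeded replicates of the default configuration
(five 1-Mb chromosomes, 200 TE copies, 5 intra + 2 inter moves, 3
duplications, ≥ 10-kb displacements, 1-kb tolerance); calibration uses 500
null replicates of 2,000 permutation iterations; interval-algebra oracle
checks use 100 randomized 5-kb annotation sets; self-consistency uses
two-chromosome 100-kb configurations.  These sizes were chosen so the
entire suite exercises every code path in well under a minute of compute
per component while keeping Monte-Carlo error comfortably inside the
asserted bands.
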