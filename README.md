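# wormdrift

Tools for comparing two diverged genome assemblies of laboratory
*Caenorhabditis elegans* lineages — or any pair of small eukaryotic
assemblies with the same kinds of annotations.  The package implements the
bespoke computations such comparisons need once the heavy lifting
(assembly, alignment, variant calling) has been done by standard tools:

* **Variant quality filtering** of short-read SNP/indel calls
  (QUAL ≥ 30, ≥ 10 alternate reads, ≥ 30 total reads, homozygous-only by
  default) and derivation of per-chromosome indel intervals.
* **Annotation interval algebra**: introns as gene spans minus exon/UTR
  cover, intergenic space as the gene-union complement.
* **Chromosome landscape analysis**: arm-like terminal-third vs. center
  domain classification, 100-kb density binning, and a GAT-style
  permutation enrichment test (default 20,000 uniform placements) with
  empirical and hypergeometric p-values.
* **Transposable-element fingerprint tracking** — the core procedure.
  SNPs of genome B that fall inside a genome-A TE copy are substituted
  into its sequence; the resulting *fingerprint* is usually unique to that
  copy and can be searched for among genome B's TE annotations.  Comparing
  the matched position with the position expected from whole-genome
  alignment liftover classifies each element as unmoved, moved within or
  between chromosomes, or duplicated in the query genome.
* **Comparison summaries** (per-chromosome tables with exact totals,
  percent aligned, TE family composition) and a **mutation-accumulation
  model**: E[mutations] = μ · L · (365 · years / generation days), with
  μ = 2.7 × 10⁻⁹ per site per generation, L = 10⁸ sites, and a 3-day
  generation time by default.
* A **synthetic genome-pair generator**: an ancestral genome with genes
  and TE copies, two derived lineages separated by planted SNPs (arm-
  biased), indels, ≥ 50-bp structural variants (DEL/INS/INV/DUP/TRANS/
  NOTAL), and TE moves/duplications — plus truth sets and a gap-free
  alignment-block map consistent with every planted event, so the whole
  pipeline is testable without multi-gigabase inputs.

## Worked example

Simulate a small genome pair, then track its transposable elements:

```bash
$ wormdrift simulate --config sim.yaml --outdir demo --seed 1
simulated bundle written to demo

$ wormdrift track-tes --tes-a demo/te_A.bed --tes-b demo/te_B.bed \
    --genome-a demo/genome_A.fasta --genome-b demo/genome_B.fasta \
    --vcf demo/variants_B_vs_A.vcf --blocks demo/alignment_blocks.tsv \
    --out calls.tsv
{"duplicated_in_query": 1, "interchromosomal": 1, "intrachromosomal": 2, "unmoved": 8}
```

The summary line (stderr) counts movement calls: with this configuration
the simulator planted 2 intrachromosomal moves, 1 interchromosomal move,
and 1 duplication, and tracking recovered all of them; the remaining 8
fingerprinted elements are correctly called unmoved.  `calls.tsv` has one
row per tracked element, e.g.

```
ref_te_id  call              observed_qry_chrom  displacement
te0002     intrachromosomal  II                  45731.0
te0003     unmoved           I                   0.0
```

meaning element `te0002` was found 45,731 bp away from the position the
alignment-block liftover predicts — a transposition — while `te0003` sits
exactly where expected.

The mutation-accumulation model:

```bash
$ wormdrift mutations --years 24
788.4 expected mutations (~790 rounded)
```

i.e. a lineage propagated since 1998 at a 3-day generation time is
expected to carry roughly 790 new single-nucleotide mutations.

Arm-vs-center enrichment of the simulated SNPs (2,000 permutations):

```
chrom  domain  observed  expected  fold    p_empirical  p_hypergeom
I      arms    149.0     131.3     1.135   0.011        0.004
I      center  48.0      65.7      0.731   0.011        0.998
```

SNPs on chromosome I overlap the arm domains 1.13-fold more than uniform
placements do — the planted arm bias, diluted by TE-internal
substitutions that follow TE placement rather than the arm-biased SNP
process.

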