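# Methods

This note documents the models, parameter choices, and numerical conventions
behind `enrichmag`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Scope and data model

The package starts *after* assembly and binning: its inputs are scaffolds
(FASTA), reads (FASTQ/FASTA, nominally 250 bp), marker/SCG hit tables (TSV
with scaffold, coordinates, label, best-hit identity, bitscore, e-value), bin
membership tables, and gene annotation tables. Read QC, assembly, gene
prediction, homology search against external databases, tetranucleotide
binning, and phylogenetics are out of scope; their outputs are consumed as
tables. Coordinates are 0-based half-open throughout.

## Read mapping with a mismatch cap

Presence/absence calling requires near-exact placements: the contract is
end-to-end, ungapped alignment with at most `max_mismatches = 5`
substitutions per read (2% of a 250 bp read), each read assigned to its
single best placement over both strands, ties broken by lexicographic
scaffold id, then leftmost start, then forward strand. Clipped or gapped
placements are deliberately not produced; reads overhanging scaffold ends are
unmapped.

Implementation: non-overlapping exact k-mer seeds (default k = 31) over a
sorted-array index of every scaffold position, then full-read Hamming
verification of each candidate diagonal. By pigeonhole, a placement with at
most `floor(250/31) - 1 = 7` mismatches always retains an intact seed, so the
search is provably exact beyond the cap of 5. If reads are too short for
that guarantee (`len < 8 (max_mismatches + 1)`), the mapper switches to an
exhaustive scan of all offsets. Correctness is asserted against an
independent brute-force Hamming oracle on randomized instances.

## Breadth of coverage and presence calls

Depth is per-position read count. Because coverage decays toward scaffold
ends (reads cannot overhang), `trim = 250` bp is removed from each scaffold
end before breadth is computed; scaffolds shorter than `2 * trim` contribute
nothing to either numerator or denominator. Breadth of a bin in a sample is
a single pooled ratio — positions with depth ≥ `depth_min = 3` over the total
truncated length — not a per-scaffold average.

The presence threshold `breadth_min_pct = 50` is this package's documented
default: breadth is reported descriptively in the field and no standard
numeric cutoff exists; 50% cleanly separates genuinely present genomes
(breadth ≥ 87% already at 5× Poisson coverage) from conserved-region
cross-mapping (typically a few percent). The value is configurable and
recorded in every report.

Under uniform coverage, depth is approximately Poisson(c) per position, so
expected breadth is `100 (1 - F_Poisson(depth_min - 1; c))` — 99.7% at 10×,
87.5% at 5×, 32.3% at 2×. Tests compare simulated breadth against this
closed form. Numerical note: positions within one read are perfectly
correlated, so the binomial sampling error of breadth is computed with an
effective sample size of `truncated_length / read_length` independent reads,
not the number of positions.

## rpS3 community profiling

- **Normalisation.** Per-sample mean coverages of rpS3-carrying scaffolds are
  multiplied by `reference_reads / sample_reads`, the reference being the
  sample with the fewest reads. This is a pure library-size rescaling; it
  preserves within-sample rank order.
- **Taxonomic bands.** Species ≥ 99%, genus [88, 99), phylum [60, 88),
  domain < 60% best-hit identity, hits with e-value > 1e-5 unclassified. The
  published integer band edges leave (98, 99) and (87, 88) unassigned;
  half-open intervals close those gaps (documented divergence). Identity is
  defined as matches / alignment span from an end-gap-free global alignment,
  counting internal gap columns and excluding terminal overhangs.
- **Clustering.** Greedy incremental clustering at ≥ 99% identity: sequences
  visited by decreasing length (ties lexicographic), each joining the first
  matching representative. Deterministic and idempotent; lowering the
  threshold can only merge clusters.
- **Overlap statistics.** Detection in a sample = normalised coverage > 0.
  `core_pct` counts clusters in every sample; `unique_pct` counts clusters in
  exactly one; `low_abundance_pct` counts clusters whose *maximum* normalised
  coverage across samples is ≤ `coverage_cutoff = 4.1` (the cutoff applies to
  the max, a documented choice); `multi_sample_pct_above_cutoff` counts
  clusters above the cutoff seen in ≥ 2 samples. Unique and low-abundance
  coincide in communities whose rare tail is sample-specific, but they are
  distinct statistics and both are reported. Marker calling assumes scaffolds
  ≥ 1 kb, matching the usual gene-prediction floor.

## Single-copy-gene bin QC

Against a universe of 51 universal bacterial SCG labels:
`completeness = 100 · distinct labels present / 51`,
`contamination = 100 · labels with ≥ 2 copies / 51`. The contamination
formula mirrors common single-copy-marker practice; it is *not* CheckM's
lineage-specific estimate and the two are not comparable (CPR lineages, for
instance, genuinely lack some universal markers, deflating completeness).
Filter bounds are inclusive: keep bins with completeness ≥ 70% and
contamination ≤ 10%. Note contamination ≤ completeness is not an invariant —
a bin whose few SCGs are all duplicated inverts it — only
`duplicated ⊆ present` holds.

## Strain deconvolution

A megabin (one bin, two strains) is detected from three independent signals,
all required:

1. **Alignment** — at least two minor scaffolds mutually align at
   ≥ `min_identity = 0.95` over at least half the shorter length. Pairwise
   scaffold identity uses a strand-specific k-mer containment pre-filter
   (k = 21, ≥ 10% containment) followed by infix alignment of the full
   shorter scaffold (edit distance capped at half its length); identity =
   1 − edits / shorter length, so the coverage requirement is satisfied by
   construction.
2. **Redundant SCGs** — ≥ 1 SCG label occurring on ≥ 2 of those scaffolds
   (one shared label suffices; the signal is redundancy, not its extent).
3. **Coverage complementation** — the variant scaffolds' summed mean
   coverages match the highest-coverage (backbone) scaffold within
   `max_complementation_error = 0.10`. The worked example
   (149.7 vs 75.4 + 76.0) has a 1.1% error; 10% tolerates Poisson depth
   noise at moderate coverage while rejecting unrelated scaffold trios.

Splitting emits one strain genome per variant scaffold (backbone + variant).
Only one backbone tier is considered; recursive multi-level splitting and
read-level haplotype phasing are out of scope. The variant-region report
lists genes on variant scaffolds whose annotation is not shared by all
variants.

## Genome dereplication

Primary clustering: single linkage at `primary_ani = 0.90` on Mash-style
sketch ANI — bottom-1000 MinHash of canonical 21-mers (SplitMix64 hashing),
Jaccard estimated from the bottom sketch of the union, converted by the Mash
transform `d = -ln(2j/(1+j))/k`. Secondary clustering within multi-genome
primary clusters: average linkage at `secondary_ani = 0.99` on the *exact*
canonical k-mer-set Jaccard ANI (no sketching). Secondary id 0 encodes "no
refinement performed" (singleton primary). Representative = highest
completeness, ties broken by length then id. Thresholds follow dRep's
documented defaults; alignment-based ANI (gANI/fastANI) is not reproduced.
The sketch estimate stays within ±1.5 ANI points of the exact Jaccard value
across 0.2–8% divergence in tests.

## Synthetic-data generator

The generator emulates the study conditions of a triplicate enrichment
experiment: 40 taxa across 3 samples with membership 19 unique / 14 in two /
7 in all three; per-sample abundances are independent log-normal draws
(mu = 2, sigma = 1, i.e. median ~7×, long right tail) *per member sample*,
reproducing the observed high between-replicate abundance variability;
250 bp single-end reads (mate pairing carries no information for any
statistic computed here) with i.i.d. substitution errors at 0.002/base;
exactly one rpS3 locus per taxon and up to 51 SCG loci, mutated from a
bundled deterministic reference set to controlled identities (substitutions
only, so realised identity is exact). Read counts are Poisson(cL/r) with
uniform starts (Lander–Waterman). The strain-pair generator defaults to the
worked example's printed scale: 820 kbp backbone + two 240 kbp variants at 1%
divergence (1.3 Mbp assembled; two 1.06 Mbp strain genomes), 37 backbone
SCGs plus the same 10 SCG labels on each variant (47/51 ≈ 92% completeness
per strain), and ten genes differing between the variant regions.

Default per-taxon genome length is 20–40 kbp in 1–3 scaffolds. Every
statistic the pipeline computes — depth, breadth, identity, completeness,
overlap fractions — is per-position or per-label and therefore
length-invariant; the reduced scale keeps full-chain simulations to tens of
seconds while exercising the same mathematics. Sequences are uniform random
A/C/G/T: no ambiguity codes, GC skew, repeats, indels, chimeras, or assembly
artifacts. Consequently, passing tests demonstrate algorithmic correctness
under the stated models (Poisson coverage, substitution-only divergence,
unrelated background), not robustness to repeat-induced multi-mapping,
indel-rich divergence, or misassembly — the main caveats when applying the
pipeline to real assemblies.

## Determinism and degenerate inputs

All randomness flows from explicit integer seeds (numpy Generator); fixed
seed gives byte-identical fixtures, mappings, and reports. Ties are broken
lexicographically everywhere. Degenerate inputs have defined behaviour:
empty reads and too-short scaffolds are skipped with warnings; a bin with
zero truncated length raises (breadth undefined); zero reads in a sample
raises on normalisation; zero-divergence strain pairs and infeasible overlap
designs are configuration errors.

## Problem sizes used in checks

The test suite and acceptance script run at desk scale, chosen as realistic
exercise of every code path: mapper-oracle equivalence on 100 random
instances (2 × 5 kbp scaffolds, 9 reads each, 0–8 substitutions); breadth
closed form on a 60 kbp scaffold at 2/5/10×; full-chain recovery on the
default 40-taxon community (~100k reads over 3 samples); dereplication of 34
genomes from 19 templates of 30 kbp; strain detection at the megabin's full
printed scale (1.3 Mbp).
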