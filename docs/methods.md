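# Methods

## The pipeline and its assumptions

The package analyses aligned 24 nt small-RNA reads; alignment itself (and
read QC, adapter trimming, multimapper handling beyond a unique flag) is
upstream and out of scope. Internally every coordinate is 0-based
half-open; GFF3 (1-based closed) and cytosine reports (1-based positions)
are converted at their format boundaries and nowhere else.

**Filtering.** A read is retained when it is flagged uniquely mapped, is
exactly 24 nt long, and overlaps no structural-RNA interval by even 1 bp.
The 1 bp rule is deliberate: no overlap fraction is defensible without a
structural-RNA size model, and the strictest rule is also the cheapest to
reason about. Filtering is idempotent, and removal counts per criterion are
logged on the `ReadSet`.

**Normalization.** Abundance is expressed as reads per ten million mapped
reads, RPTM = count/L × 10⁷. The denominator L defaults to the *retained*
read count (unique, 24 nt, non-structural), which makes results fully
determined by the provided files; a pre-filter `all_mapped` basis and an
explicit override are available because the convention "total number of
mapped reads" is ambiguous about filter stage. When replicates are
combined, L is the sum of the replicates' library sizes.

**Cluster calling.** Reads from all replicates are pooled (strand ignored
— 24 nt siRNA loci are double-stranded in origin) and merged transitively
whenever the gap between an interval and the running maximum end is
≤ 100 bp, i.e. bedtools `merge -d 100` semantics. The inclusive reading of
the merge distance follows the common distance-merge convention; the
parameter is exposed. Every pooled read lands in exactly one candidate, so
candidate counts conserve the read total. Candidates with RPTM strictly
above 12 are siRNA clusters; clusters strictly above 2000 RPTM are
billionaire clusters. Both thresholds are strict "greater than": a region
at exactly 12 RPTM is not a cluster and a cluster at exactly 2000 RPTM is
a pauper. Merged candidates shorter than a read length are kept. The merge
is implemented as a vectorized sort/running-max sweep (O(n log n)), which
on two pooled 10⁶-read replicates runs in well under a second; its
equivalence with an exhaustive transitive-closure construction is asserted
over random instances in the test suite.

**Analytics.** Cumulative curves rank clusters by descending abundance
with ties broken by genomic position for determinism. The threshold sweep
reports, for each RPTM threshold t, the percent of *all retained* reads
(not just clustered reads) held by clusters above t; the denominator is a
parameter. Interval-set comparisons count a cluster as shared when it
overlaps any cluster of the other set by ≥ 1 bp (a minimum-overlap
parameter exists); because interval overlap is not one-to-one, both sides'
counts are reported and the single Venn-style number is the left-set view.
Multi-set unions join on strict ≥ 1 bp overlap, so touching intervals stay
separate, and both the merged and the summed-input counts are reported.
Cross-sample comparisons always quantify each sample's reads on one fixed
interval set with that sample's own library size. All two-group tests are
two-sided Wilcoxon rank-sum tests.

**Methylation.** The level of a region in one context is the pooled-count
ratio Σ methylated / Σ sequenced over the region's cytosines of that
context, both strands together — a read-weighted level, not the mean of
per-site levels. Zero-coverage cytosines contribute to neither sum; a
region with no covered cytosine of the context has an *undefined* level,
flagged rather than coerced to zero, and group comparisons drop (and
count) such regions. No minimum site coverage is imposed by default; the
parameter exists.

**Chromatin and genes.** ChIP enrichment is per-region RPKM
(count × 10⁹ / (length × mapped total)) with a read counted on ≥ 1 bp
overlap; the per-region metric (rather than summed base coverage) is the
documented choice where the convention is underdetermined. Controls are
20,000 random 350 bp regions, uniform over the genome with chromosomes
weighted by length and chromosomes shorter than the region excluded.
"Adjacent" genes are genes overlapping a cluster by ≥ 1 bp (a flanking-
window mode exists but is off by default); the random-gene control draws
300 genes without replacement. A gene is differentially expressed iff
|log2 FC| > log2(2) and FDR < 0.05, both strict and two-sided in
direction; genes missing from the DE table count as non-DE with a
reported tally.

## The synthetic-data generator

The generator's defaults are the study conditions the rest of the package
is exercised under: 2 chromosomes × 50 Mb; 5 billionaire loci
(1–3 kb) carrying 70% of the locus-directed read mass against 200 pauper
loci (200–800 bp); 10 structural-RNA loci receiving 5% of all reads; a 5%
genome-wide background; two replicates of 10⁶ reads; first-base
probabilities (A, C, G, T) = (0.4, 0.2, 0.2, 0.2); and a biogenesis mutant
retaining 5% of every planted locus's output. Within a class, locus masses
follow a Zipf-like law (exponent 1.0, configurable) so concentration is
tunable; reads start uniformly inside their locus; strand is a fair coin.
Background reads fall uniformly *outside* all planted loci (rejection
sampling), which gives cluster calling a noise floor to reject and makes
full depletion exactly background-only. Mutant libraries keep the
configured total read count: the mass removed from planted loci moves to
background, so per-locus expected reads scale by exactly the depletion
factor at constant sequencing depth.

The genome size matters: at 100 Mb the 5% background (≈10⁵ pooled reads)
has a mean spacing of ~1 kb, far above the 100 bp merge distance, so
background forms only scattered low-count candidates — the sparse-genome
regime in which a distance merge is meaningful. On a much smaller genome
the background chains into large merged regions and the cluster concept
degrades; the example scripts use 10 Mb genomes with proportionally fewer
reads for the same reason.

Methylomes are laid on a 25 bp grid of cytosine sites inside every planted
locus (cycling CG/CHG/CHH) plus 5,000 random background sites, with
binomial counts at coverage 50. CHH is planted at 0.30 at siRNA loci in
the wild type and 0.03 in the mutant, 0.02 elsewhere; CG (0.60) and CHG
(0.30) are planted genotype-independent, providing the context-specific
null. Gene annotations, FPKM tables and DE tables are generated with a
planted DE status (15% of genes, |log2 FC| ∈ (1, 4], FDR < 0.05) so DEG
fractions can be checked exactly. A ChIP-read simulator with per-class
rate multipliers backs the enrichment analyses.

What the generator does *not* emulate: positional read structure within a
locus (real siren loci have phased/clustered starts), sequence-dependent
first bases, multimapping ambiguity, cell-type mixtures within a tissue,
sequencing error, or any coupling between siRNA abundance and gene
expression. Passing tests therefore demonstrate that the pipeline measures
what was planted under the assumed statistical regime — not that the
biological claims hold in any particular dataset.

## Numerical and degenerate-input choices

- Thresholds at their printed values are excluded (strict `>`); the merge
  distance is inclusive (`gap ≤ d` merges, exactly d merges).
- Zero library size raises a normalization error rather than returning 0
  or NaN; empty read sets are legal and produce empty cluster sets.
- Undefined methylation levels are `None`/NaN, never 0.
- Heatmap row scaling guards zero rows (max-scaling) and constant rows
  (z-scoring) by leaving them at zero instead of dividing by zero.
- Cumulative curves and random samplers are deterministic under a fixed
  seed; ranking ties break by (−abundance, chrom, start).
- Locus placement retries up to 1000 positions per locus and raises a
  placement error when the genome cannot hold the request.

## Problem sizes used in the checks

The automated checks run the full pipeline on 20 independently seeded
default-scale studies (2 × 10⁶ reads each), which completes in well under
two minutes on a single core thanks to the vectorized merge; brute-force
oracle comparisons use 100 random instances of ≤ 200 intervals per
operation; methylation null calibration uses 20 seeds of the default
methylome. These sizes were chosen to keep sampling error well below the
effect sizes planted by the generator.

## Known limitations

- The bill/pau boundary is scale-free (RPTM), so with few planted loci
  and everything else held fixed, *pauper* loci can individually exceed
  2000 RPTM; the generator's truth ledger carries each locus's expected
  read mass so that analyses compare against expected abundance rather
  than class labels where the distinction matters.
- `quantify_on` counts a read into every interval it touches; on
  overlapping interval sets reads are intentionally double-counted.
- SAM input takes uniqueness from the NH tag only; aligner-specific
  multimapper conventions (e.g. MAPQ heuristics) are not interpreted.
- DMR calling, phasiRNA detection, 21/22 nt classes, peak calling and
  differential-expression model fitting are out of scope by design.
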