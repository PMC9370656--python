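# sirenscan

Detection and characterization of **billionaire (bill-) versus pauper
(pau-) 24 nt siRNA clusters** in plant genomes.

In plants, RNA polymerase IV and RDR2 produce 24 nt small interfering RNAs
that guide RNA-directed DNA methylation (RdDM), the pathway that writes
de novo cytosine methylation — most visibly in the CHH context. In
reproductive tissues, 24 nt siRNA production is extraordinarily
concentrated: a tiny minority of genomic loci (similar to the "siren" loci
of ovules and seed coats) can account for the large majority of all 24 nt
siRNA reads, while thousands of weaker clusters split the remainder. This
package implements the full analysis pipeline around that observation:

1. **Read filtering** — keep uniquely mapped 24 nt reads, discard reads
   touching structural RNAs (rRNA, tRNA, snRNA, snoRNA).
2. **RPTM normalization** — abundance in reads per ten million mapped
   reads: `RPTM = count / library_size × 10⁷`.
3. **Cluster calling** — pool replicates, merge reads whose gap is
   ≤ 100 bp, keep merged regions with RPTM > 12 as 24 nt siRNA clusters.
4. **Classification** — clusters with RPTM > 2000 are *billionaire*
   clusters; all others are *pauper* clusters (both thresholds strict).
5. **Analytics** — cumulative-expression curves, threshold sweeps of the
   read share captured, cross-sample quantification on fixed interval
   sets, two-sided Venn overlaps, multi-set unions, heatmap tables,
   first-base composition and length/per-bp-abundance statistics
   (two-sided Wilcoxon rank-sum throughout).
6. **Epigenome integration** — pooled per-context methylation levels
   (`Σ methylated / Σ sequenced` cytosines in a region), ChIP RPKM
   enrichment with random-region controls (20,000 × 350 bp), cluster-
   overlapping genes, random-gene controls, and DEG fractions
   (|FC| > 2 and FDR < 0.05 on a supplied table).
7. **Synthetic data** — a generator that reproduces the statistical
   structure the analysis assumes (concentration, A-biased first base,
   biogenesis-mutant depletion, CHH coupling) together with a planted
   ground truth, so every step can be scored against what was simulated.

## Worked example

`examples/` contains one short script per capability. The first one
simulates a concentrated library, filters, calls and scores clusters:

```bash
python examples/01_call_bill_clusters.py
```

```
filter log (replicate 1): {'input': 200000, 'removed_non_unique': 0, 'removed_length': 0,
                           'removed_structural': 10027, 'retained': 189973}
called 17953 siRNA clusters (204 bill, 17749 pau) from 379,967 retained reads
recovery vs planted truth: {'bill_recovery': 1.0, 'pau_recovery': 1.0,
                            'background_bill_clusters': 0, ...}
```

Reading: of 200,000 simulated reads per replicate, ~5% mapped to
structural-RNA loci and were discarded. Pooling both replicates, merging
and thresholding yields 17,953 clusters, of which 204 exceed 2000 RPTM.
Every planted billionaire locus is recovered with a bill label and no
background-only region is ever called bill. The concentration view
(`examples/02_concentration_and_sweep.py`) then shows the regime the
classification is built on:

```
top 5 of 17788 clusters hold 66.3% of total cluster abundance
clusters with RPTM >    500 capture  94.8% of all 24 nt reads
clusters with RPTM >   2000 capture  94.7% of all 24 nt reads
first-base composition over clustered reads: {'A': 0.399, 'C': 0.201, 'G': 0.202, 'T': 0.199}
```

and `examples/03_mutant_dependence.py` demonstrates the pathway
dependence: a biogenesis mutant keeps only ~5% of wild-type bill-cluster
abundance, CHH methylation on those clusters collapses with it
(rank-sum p ≈ 10⁻⁶⁸), while CG and CHG are untouched.

The same pipeline is scriptable from the shell:

```bash
sirenscan simulate --out fixtures --seed 3
sirenscan call --reads fixtures/reads_wild_type_rep1.bed \
               --reads fixtures/reads_wild_type_rep2.bed \
               --structural fixtures/structural_rna.bed --out clusters.bed
sirenscan sweep --clusters clusters.bed --library-size 190000
```

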