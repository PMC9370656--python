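"""Chromatin-mark enrichment on bill clusters, and what their neighbours do.

Simulates a heterochromatic mark laid 5x denser over bill loci, compares its
RPKM on bill clusters against 20,000 random 350 bp control regions, then
asks which genes overlap clusters and what fraction of them is
differentially expressed (|FC| > 2, FDR < 0.05) — typically few, since these
clusters sit mostly outside responsive genes.
"""

import sirenscan as ss

config = ss.SimulationConfig(chrom_length=10_000_000, total_reads=200_000, seed=51)
truth = ss.simulate_genome(config)
structural = truth.loci_of("structural")
reads = [
    ss.filter_reads(r, structural=structural)
    for r in ss.simulate_reads(truth, "wild_type")
]
clusters = ss.cluster_pipeline(reads)

chip = ss.simulate_chip_reads(
    truth, n_reads=500_000, read_length=150, enrichment={"bill": 5.0}, seed=51
)
control = ss.random_region_control(truth.chromosomes, n=20_000, length=350, seed=52)
profile = ss.rpkm_enrichment(
    chip, len(chip), truth.loci_of("bill"), control, mark="H3K9me2"
)
print(f"H3K9me2 on bill loci: median {profile.median_region:.1f} RPKM vs "
      f"{profile.median_control:.1f} RPKM on random regions "
      f"(rank-sum p = {profile.pvalue:.2e})")

genes, fpkm, de = ss.simulate_genes(truth)
adjacent = ss.adjacent_genes(clusters.group("bill"), genes)
print(f"{len(adjacent)} of {len(genes)} genes overlap a bill cluster")
if len(adjacent):
    frac = ss.deg_fraction(adjacent, de.drop(columns="planted_de"))
    print(f"DEG fraction among them: {100 * frac.fraction:.1f}% "
          f"({frac.n_de}/{frac.n_genes})")
control_genes = ss.random_gene_control(genes, n=300, seed=53)
frac_ctrl = ss.deg_fraction(control_genes, de.drop(columns="planted_de"))
print(f"DEG fraction among {frac_ctrl.n_genes} random control genes: "
      f"{100 * frac_ctrl.fraction:.1f}%")
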