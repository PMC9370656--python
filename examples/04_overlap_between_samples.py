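"""Venn-style overlap of bill clusters between two samples.

Simulates two studies that share a genome size but plant loci independently
(a stand-in for two tissues with partly different siRNA programs), calls
clusters in each, and reports two-sided overlap counts plus the multi-set
non-redundant union with per-set membership.
"""

import sirenscan as ss


def call_sample(seed):
    truth = ss.simulate_genome(
        ss.SimulationConfig(chrom_length=10_000_000, total_reads=200_000, seed=seed)
    )
    structural = truth.loci_of("structural")
    reads = [
        ss.filter_reads(r, structural=structural)
        for r in ss.simulate_reads(truth, "wild_type")
    ]
    return ss.cluster_pipeline(reads)


sample_a = call_sample(41)
sample_b = call_sample(42)

res = ss.overlap_sets(sample_a.group("bill"), sample_b.group("bill"))
print("bill-cluster overlap:", res.to_dict())
# shared_a counts A's bill clusters touching >= 1 bp of a B bill cluster;
# counts differ by side because interval overlap is not one-to-one.

union = ss.multiway_union(
    [sample_a.group("bill"), sample_b.group("bill")], labels=["tissueA", "tissueB"]
)
both = (union["in_tissueA"] & union["in_tissueB"]).sum()
print(f"non-redundant union: {union.attrs['n_merged']} intervals "
      f"(from {union.attrs['n_distinct']} inputs); shared by both: {both}")
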