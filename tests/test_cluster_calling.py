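"""Cluster merging, RPTM thresholding, bill/pau labels, and group statistics."""

import numpy as np
import pandas as pd
import pytest

import sirenscan as ss
from sirenscan.cluster_calling import merge_reads, call_clusters, classify_bill


def readset_from_intervals(intervals, replicate="rep1"):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    df["strand"] = "+"
    df["first_base"] = "A"
    df["unique"] = True
    df["replicate"] = replicate
    return ss.ReadSet(df=df, replicate=replicate, library_size=len(df), n_mapped=len(df))


def brute_force_merge(intervals, gap):
    """Transitive closure over all pairs with pairwise distance <= gap."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci != cj:
                continue
            dist = max(sj - ei, si - ej)  # negative when overlapping
            if dist <= gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    merged = sorted(
        (g[0][0], min(s for _, s, _ in g), max(e for _, _, e in g))
        for g in groups.values()
    )
    return merged


def random_intervals(rng, n, span=2000, max_len=60):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    chroms = rng.choice(["chr1", "chr2"], size=n)
    return [(c, int(s), int(s + l)) for c, s, l in zip(chroms, starts, lengths)]


class TestMergeReads:
    def test_gap_99_merges(self):
        rs = readset_from_intervals([("chr1", 100, 124), ("chr1", 223, 247)])
        cand = merge_reads([rs], merge_gap=100)
        assert len(cand) == 1
        assert (cand.iloc[0]["start"], cand.iloc[0]["end"]) == (100, 247)
        assert cand.iloc[0]["raw_count"] == 2

    def test_gap_101_splits(self):
        rs = readset_from_intervals([("chr1", 100, 124), ("chr1", 225, 249)])
        assert len(merge_reads([rs], merge_gap=100)) == 2

    def test_gap_exactly_100_merges(self):
        rs = readset_from_intervals([("chr1", 100, 124), ("chr1", 224, 248)])
        assert len(merge_reads([rs], merge_gap=100)) == 1

    def test_empty_input_gives_empty_candidates(self):
        assert len(merge_reads([readset_from_intervals([])], merge_gap=100)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_transitive_closure(self, seed):
        rng = np.random.default_rng(seed)
        intervals = random_intervals(rng, int(rng.integers(2, 120)))
        gap = int(rng.integers(0, 150))
        cand = merge_reads([readset_from_intervals(intervals)], merge_gap=gap)
        got = sorted(zip(cand["chrom"].astype(str), cand["start"], cand["end"]))
        assert got == brute_force_merge(intervals, gap)

    def test_order_invariant_over_replicates(self):
        rng = np.random.default_rng(3)
        a = readset_from_intervals(random_intervals(rng, 50), "rep1")
        b = readset_from_intervals(random_intervals(rng, 50), "rep2")
        ab = merge_reads([a, b], merge_gap=100)
        ba = merge_reads([b, a], merge_gap=100)
        pd.testing.assert_frame_equal(ab, ba)

    def test_larger_gap_never_increases_candidates(self):
        rng = np.random.default_rng(4)
        rs = readset_from_intervals(random_intervals(rng, 200, span=5000))
        sizes = [len(merge_reads([rs], merge_gap=g)) for g in (0, 10, 50, 100, 500)]
        assert sizes == sorted(sizes, reverse=True)

    def test_per_replicate_counts_sum_to_raw_count(self, study):
        cand = merge_reads(study.wt_reads, merge_gap=100)
        rep_cols = [c for c in cand.columns if c.startswith("count_")]
        assert len(rep_cols) == 2
        assert (cand[rep_cols].sum(axis=1) == cand["raw_count"]).all()


class TestCallAndClassify:
    def test_min_rptm_is_strict(self):
        # library 10M: RPTM == raw count
        cand = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, 1000], "end": [500, 1500],
             "raw_count": [12, 13]}
        )
        cs = call_clusters(cand, library_size=10_000_000, min_rptm=12)
        assert len(cs) == 1 and cs.df.iloc[0]["raw_count"] == 13

    def test_bill_threshold_is_strict(self):
        cand = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, 5000], "end": [400, 5400],
             "raw_count": [2000, 2001]}
        )
        cs = classify_bill(call_clusters(cand, library_size=10_000_000))
        by_count = cs.df.set_index("raw_count")["label"]
        assert by_count[2000] == "pau" and by_count[2001] == "bill"

    def test_all_below_threshold_gives_zero_bill(self):
        cand = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [400], "raw_count": [100]}
        )
        cs = classify_bill(call_clusters(cand, library_size=10_000_000))
        assert cs.n_bill == 0 and cs.n_pau == 1

    def test_bill_pau_partition_the_set(self, study):
        cs = study.clusters
        assert cs.n_bill + cs.n_pau == len(cs)
        assert set(cs.df["label"].unique()) <= {"bill", "pau"}

    def test_zero_library_size_rejected(self):
        cand = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [400], "raw_count": [10]}
        )
        with pytest.raises(ss.NormalizationError):
            call_clusters(cand, library_size=0)

    def test_conservation_at_min_rptm_zero(self, study):
        cand = merge_reads(study.wt_reads, merge_gap=100)
        total = sum(len(r) for r in study.wt_reads)
        assert cand["raw_count"].sum() == total
        cs = call_clusters(cand, ss.combined_library_size(study.wt_reads), min_rptm=0)
        assert cs.df["raw_count"].sum() == total

    def test_planted_bill_loci_called_bill(self, study):
        """Loci planted at expected RPTM far above threshold come out labelled bill."""
        truth = study.truth
        exp = truth.expected_rptm()
        assert (exp[truth.loci["label"] == "bill"] > 2000).all()
        rec = ss.score_recovery(truth, study.clusters)
        assert rec["bill_recovery"] == 1.0


class TestFirstBaseComposition:
    def test_all_adenine_reads(self):
        rs = readset_from_intervals([("chr1", 0, 24), ("chr1", 30, 54)])
        cs = classify_bill(
            call_clusters(merge_reads([rs], 100), library_size=10_000_000, min_rptm=0)
        )
        comp = ss.first_base_composition(cs, [rs], "all")
        assert comp.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_recovers_generator_probabilities(self, study):
        probs = np.asarray(study.truth.config.first_base_probs)
        comp = ss.first_base_composition(study.clusters, study.wt_reads, "all")
        n = sum(len(r) for r in study.wt_reads)
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(comp.to_numpy() - probs) < 3 * se + 1e-12)
        assert comp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_partition_consistency(self, study):
        """bill and pau compositions, read-weighted, recombine to the overall one."""
        cs, reads = study.clusters, study.wt_reads
        n_bill = ss.quantify_on(cs.group("bill"), reads, library_size=ss.RPTM_SCALE).sum()
        n_pau = ss.quantify_on(cs.group("pau"), reads, library_size=ss.RPTM_SCALE).sum()
        comp_bill = ss.first_base_composition(cs, reads, "bill")
        comp_pau = ss.first_base_composition(cs, reads, "pau")
        comp_all = ss.first_base_composition(cs, reads, "all")
        mix = (comp_bill * n_bill + comp_pau * n_pau) / (n_bill + n_pau)
        assert np.allclose(mix.to_numpy(), comp_all.to_numpy(), atol=1e-9)

    def test_empty_group_is_an_error(self):
        rs = readset_from_intervals([("chr1", 0, 24)])
        cs = classify_bill(
            call_clusters(merge_reads([rs], 100), library_size=10_000_000, min_rptm=0)
        )
        with pytest.raises(ValueError):
            ss.first_base_composition(cs, [rs], "bill")  # nothing above 2000 RPTM


class TestLengthAndDensity:
    def test_identical_groups_not_significant(self, study):
        g = study.clusters.group("pau")
        res = ss.length_and_density_stats(g, g)
        assert res.length_pvalue >= 0.99 and res.density_pvalue >= 0.99

    def test_planted_length_difference_detected(self, study):
        """Bill loci are planted several-fold longer than pau loci."""
        res = ss.length_and_density_stats(
            study.clusters.group("bill"), study.clusters.group("pau")
        )
        assert res.median_length_a > res.median_length_b
        assert res.length_pvalue < 0.01

    def test_per_bp_abundance_arithmetic(self):
        cand = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [400], "raw_count": [2000]}
        )
        cs = classify_bill(call_clusters(cand, library_size=10_000_000))
        res = ss.length_and_density_stats(cs.df, cs.df)
        assert res.median_density_a == pytest.approx(5.0)

    def test_empty_group_is_an_error(self, study):
        with pytest.raises(ValueError):
            ss.length_and_density_stats(study.clusters.df.iloc[:0], study.clusters.df)


def test_cluster_bed_round_trip(tmp_path, study):
    path = tmp_path / "clusters.bed"
    ss.write_clusters_bed(study.clusters, path)
    back = ss.read_clusters_bed(path, library_size=study.clusters.library_size)
    assert len(back) == len(study.clusters)
    assert back.n_bill == study.clusters.n_bill
    assert np.allclose(back.df["abundance"], study.clusters.df["abundance"])
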