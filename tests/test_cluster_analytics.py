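"""Cumulative curves, threshold sweeps, cross-sample quantification and overlaps."""

import numpy as np
import pandas as pd
import pytest

import sirenscan as ss
from sirenscan.cluster_calling import ClusterSet


def cluster_set(abundances, counts=None, length=400, library_size=10_000_000):
    n = len(abundances)
    counts = counts if counts is not None else [int(a) for a in abundances]
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 10_000,
            "end": np.arange(n) * 10_000 + length,
            "cluster_id": [f"c{i}" for i in range(n)],
            "raw_count": counts,
            "abundance": list(map(float, abundances)),
        }
    )
    df["length"] = df["end"] - df["start"]
    df["label"] = np.where(df["abundance"] > 2000, "bill", "pau")
    return ClusterSet(df=df, library_size=library_size)


def frame(intervals):
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


class TestCumulativeCurve:
    def test_single_cluster(self):
        curve = ss.cumulative_curve(cluster_set([500.0]))
        assert curve.cumulative_fraction.tolist() == [1.0]

    def test_three_cluster_arithmetic(self):
        curve = ss.cumulative_curve(cluster_set([1000.0, 8000.0, 1000.0]))
        assert np.allclose(curve.cumulative_fraction, [0.8, 0.9, 1.0])
        assert curve.abundance.tolist() == [8000.0, 1000.0, 1000.0]

    def test_fractions_monotone_and_complete(self, study):
        curve = ss.cumulative_curve(study.clusters)
        assert (np.diff(curve.cumulative_fraction) >= -1e-12).all()
        assert curve.cumulative_fraction[-1] == pytest.approx(1.0, abs=1e-9)

    def test_top_ranks_capture_planted_bill_mass(self, study):
        """The 5 most abundant clusters hold the bill loci's planted read share."""
        truth = study.truth
        curve = ss.cumulative_curve(study.clusters)
        mass = truth.loci["read_mass"].to_numpy()
        labels = truth.loci["label"].to_numpy()
        planted = mass[labels != "structural"].sum()
        oracle = mass[labels == "bill"].sum() / planted
        assert curve.mass_at_rank(truth.config.n_bill_loci) == pytest.approx(
            oracle, abs=0.02
        )

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            ss.cumulative_curve(cluster_set([]))


class TestReadFractionAbove:
    def test_threshold_zero_with_full_clustering_captures_everything(self, study):
        from sirenscan.cluster_calling import merge_reads, call_clusters, classify_bill

        lib = ss.combined_library_size(study.wt_reads)
        cs = classify_bill(
            call_clusters(merge_reads(study.wt_reads, 100), lib, min_rptm=0)
        )
        res = ss.read_fraction_above(cs, [0])
        assert res.iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_threshold_above_maximum_captures_nothing(self, study):
        top = study.clusters.df["abundance"].max()
        res = ss.read_fraction_above(study.clusters, [top + 1])
        assert res.iloc[0] == 0.0

    def test_non_increasing_over_grid(self, study):
        res = ss.read_fraction_above(study.clusters, [500, 1000, 1500, 1600, 2000])
        vals = res.to_numpy()
        assert (np.diff(vals) <= 1e-12).all()

    def test_matches_construction_oracle_at_2000(self, study):
        """Clusters above 2000 RPTM capture the planted mass of loci whose
        expected abundance exceeds 2000, within binomial sampling error."""
        truth = study.truth
        measured = ss.read_fraction_above(study.clusters, [2000]).iloc[0] / 100
        exp = truth.expected_rptm()
        mass = truth.loci["read_mass"].to_numpy()
        structural = truth.loci["label"].to_numpy() == "structural"
        retained_mass = 1.0 - mass[structural].sum()
        oracle = mass[(exp > 2000) & ~structural].sum() / retained_mass
        n = study.clusters.library_size
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert abs(measured - oracle) < 3 * se + 0.005


class TestQuantifyOn:
    def test_zero_reads_in_interval(self, study):
        far = frame([("chr1", 49_999_000, 49_999_500)])
        # an interval may hold background reads; a missing chromosome cannot
        none = frame([("chrX", 0, 1000)])
        assert ss.quantify_on(none, study.wt_reads)[0] == 0.0
        assert ss.quantify_on(far, study.wt_reads)[0] >= 0.0

    def test_self_quantification_reproduces_abundances(self, study):
        got = ss.quantify_on(
            study.clusters.df, study.wt_reads, library_size=study.clusters.library_size
        )
        assert np.allclose(got, study.clusters.df["abundance"].to_numpy(), atol=1e-9)

    def test_mutant_depleted_by_planted_factor(self, study):
        bill = study.clusters.group("bill")
        wt = ss.quantify_on(bill, study.wt_reads)
        mut = ss.quantify_on(bill, study.mut_reads)
        ratio = np.median(mut / wt)
        factor = study.truth.config.mutant_depletion_factor
        assert ratio == pytest.approx(factor, rel=0.25)

    def test_zero_library_size_rejected(self, study):
        with pytest.raises(ss.NormalizationError):
            ss.quantify_on(study.clusters.df, study.wt_reads, library_size=0)


def brute_force_overlap(a, b, min_overlap=1):
    def shared(x, y):
        count = 0
        for cx, sx, ex in x:
            if any(cy == cx and min(ex, ey) - max(sx, sy) >= min_overlap for cy, sy, ey in y):
                count += 1
        return count

    return shared(a, b), shared(b, a)


def brute_force_union(intervals):
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
            if ci == cj and min(ei, ej) - max(si, sj) >= 1:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def random_intervals(rng, n, span=3000):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, 120, size=n)
    chroms = rng.choice(["chr1", "chr2"], size=n)
    return [(str(c), int(s), int(s + l)) for c, s, l in zip(chroms, starts, lengths)]


class TestOverlapSets:
    def test_identical_sets_fully_shared(self):
        a = frame([("chr1", 0, 100), ("chr1", 500, 700)])
        res = ss.overlap_sets(a, a.copy())
        assert res.fraction_a == 1.0 and res.fraction_b == 1.0
        assert res.only_a == 0 and res.only_b == 0

    def test_disjoint_sets_share_nothing(self):
        a = frame([("chr1", 0, 100)])
        b = frame([("chr1", 200, 300), ("chr2", 0, 100)])
        res = ss.overlap_sets(a, b)
        assert res.shared_a == 0 and res.shared_b == 0

    def test_intersection_existence_is_symmetric(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = frame(random_intervals(rng, 30))
            b = frame(random_intervals(rng, 30))
            res = ss.overlap_sets(a, b)
            assert (res.shared_a > 0) == (res.shared_b > 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, int(rng.integers(1, 60)))
        b = random_intervals(rng, int(rng.integers(1, 60)))
        min_ov = int(rng.integers(1, 40))
        res = ss.overlap_sets(frame(a), frame(b), min_overlap=min_ov)
        assert (res.shared_a, res.shared_b) == brute_force_overlap(a, b, min_ov)


class TestMultiwayUnion:
    def test_disjoint_sets_add(self):
        a = frame([("chr1", 0, 100), ("chr1", 200, 300), ("chr2", 0, 50)])
        b = frame([("chr1", 400, 500)] * 1 + [("chr2", 100, 200), ("chr2", 300, 400), ("chr2", 500, 600)])
        union = ss.multiway_union([a, b], labels=["x", "y"])
        assert len(union) == 7
        assert union.attrs["n_distinct"] == 7
        assert union["in_x"].sum() == 3 and union["in_y"].sum() == 4

    def test_identical_sets_collapse(self):
        a = frame([("chr1", 0, 100), ("chr1", 200, 300)])
        union = ss.multiway_union([a, a.copy()])
        assert len(union) == 2
        assert union[["in_set1", "in_set2"]].all().all()

    def test_touching_intervals_stay_separate(self):
        a = frame([("chr1", 0, 100)])
        b = frame([("chr1", 100, 200)])
        assert len(ss.multiway_union([a, b])) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_union_find(self, seed):
        rng = np.random.default_rng(100 + seed)
        sets = [
            random_intervals(rng, int(rng.integers(1, 50))) for _ in range(int(rng.integers(2, 5)))
        ]
        union = ss.multiway_union([frame(s) for s in sets])
        assert len(union) == brute_force_union([iv for s in sets for iv in s])
        assert len(union) <= union.attrs["n_distinct"]


class TestHeatmapTable:
    def test_single_cell_equals_quantify_on(self, study):
        iv = study.clusters.group("bill").iloc[:1]
        table = ss.abundance_heatmap_table(iv, {"wt": study.wt_reads})
        assert table.shape == (1, 1)
        assert table.iloc[0, 0] == pytest.approx(
            ss.quantify_on(iv, study.wt_reads)[0]
        )

    def test_mutant_column_depleted(self, study):
        bill = study.clusters.group("bill")
        table = ss.abundance_heatmap_table(
            bill, {"wt": study.wt_reads, "mutant": study.mut_reads}
        )
        assert (table["mutant"] < table["wt"]).all()

    def test_max_scaling_handles_zero_rows(self, study):
        iv = pd.concat(
            [study.clusters.group("bill").iloc[:2], frame([("chrX", 0, 100)])],
            ignore_index=True,
        )
        table = ss.abundance_heatmap_table(iv, {"wt": study.wt_reads}, scale="max")
        assert not table.isna().any().any()
        assert table.iloc[2, 0] == 0.0


def test_binned_abundance_concentration(study):
    """Most 500 kb windows carry little signal; planted loci dominate a few."""
    bins = ss.binned_abundance(study.wt_reads, study.truth.chromosomes)
    assert len(bins) == 200
    top = bins.nlargest(10, "abundance")["abundance"].sum()
    assert top / bins["abundance"].sum() > 0.3
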