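"""Cumulative-expression curves, threshold sweeps, cross-sample
quantification, and overlap/Venn analyses of siRNA cluster sets.

These are the comparisons behind the usual questions about billionaire
clusters: how concentrated is siRNA production, what share of all 24 nt
reads do clusters above a given RPTM capture, how do two tissues' cluster
sets overlap, and how abundant is each sample on a fixed reference set of
intervals (e.g. mutant libraries quantified on wild-type bill clusters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import (
    _ChromIndex,
    max_overlap_bp,
    merge_sorted,
    overlaps_any,
)
from .read_processing import ReadSet, combined_library_size, rptm
from .cluster_calling import ClusterSet


@dataclass
class CumulativeCurve:
    """Clusters ranked by descending abundance with cumulative mass fractions."""

    abundance: np.ndarray          # descending RPTM
    cumulative_fraction: np.ndarray  # of summed cluster abundance
    sample: str
    n_clusters: int

    def mass_at_rank(self, k: int) -> float:
        """Cumulative abundance fraction captured by the top-k clusters."""
        if k <= 0:
            return 0.0
        return float(self.cumulative_fraction[min(k, self.n_clusters) - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.n_clusters + 1),
                "abundance": self.abundance,
                "cumulative_fraction": self.cumulative_fraction,
            }
        )


def cumulative_curve(clusters: ClusterSet) -> CumulativeCurve:
    """Rank clusters by abundance (descending) and accumulate their mass.

    Ties are broken by (chrom, start) so the curve is deterministic. The
    final cumulative fraction is 1 by construction.
    """
    df = clusters.df
    if len(df) == 0:
        raise ValueError("cannot build a cumulative curve from an empty cluster set")
    order = df.sort_values(
        ["abundance", "chrom", "start"], ascending=[False, True, True], kind="stable"
    )
    ab = order["abundance"].to_numpy(float)
    cum = np.cumsum(ab) / ab.sum()
    return CumulativeCurve(ab, cum, clusters.sample, len(df))


def read_fraction_above(
    clusters: ClusterSet,
    thresholds,
    total_reads: int | None = None,
) -> pd.Series:
    """Percent of all retained 24 nt reads captured by clusters above each RPTM threshold.

    ``total_reads`` (the denominator) defaults to the cluster set's combined
    library size, i.e. all retained reads — not only the clustered ones.
    Strict inequality: a cluster at exactly the threshold does not count.
    """
    if total_reads is None:
        total_reads = clusters.library_size
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    ab = clusters.df["abundance"].to_numpy(float)
    counts = clusters.df["raw_count"].to_numpy(np.int64)
    vals = {
        float(t): 100.0 * counts[ab > t].sum() / total_reads for t in thresholds
    }
    return pd.Series(vals, name="percent_of_reads")


def quantify_on(
    intervals: pd.DataFrame,
    readsets: list[ReadSet],
    library_size: int | None = None,
) -> np.ndarray:
    """Abundance (RPTM) of one sample's reads on a fixed interval set.

    Counts reads overlapping each interval by >= 1 bp and normalizes by the
    sample's combined library size. Lets any sample be quantified on any
    reference cluster set (cross-tissue or mutant-on-WT comparisons).
    """
    if isinstance(readsets, ReadSet):
        readsets = [readsets]
    if library_size is None:
        library_size = combined_library_size(readsets)
    pooled = pd.concat([rs.df[["chrom", "start", "end"]] for rs in readsets], ignore_index=True)
    index = _ChromIndex(pooled)
    counts = np.zeros(len(intervals), dtype=np.int64)
    chroms = intervals["chrom"].to_numpy()
    starts = intervals["start"].to_numpy(np.int64)
    ends = intervals["end"].to_numpy(np.int64)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        counts[mask] = index.count(chrom, starts[mask], ends[mask])
    return rptm(counts, library_size)


@dataclass
class OverlapResult:
    """Two-sided interval-overlap (Venn) summary of cluster sets A and B.

    Because interval overlap is not one-to-one, shared counts are reported
    from each side: ``shared_a`` counts A clusters overlapping >= 1 B
    cluster, ``shared_b`` the converse. Venn-style single numbers are the
    left-set (A) perspective.
    """

    n_a: int
    n_b: int
    shared_a: int
    shared_b: int

    @property
    def only_a(self) -> int:
        return self.n_a - self.shared_a

    @property
    def only_b(self) -> int:
        return self.n_b - self.shared_b

    @property
    def fraction_a(self) -> float:
        return self.shared_a / self.n_a if self.n_a else float("nan")

    @property
    def fraction_b(self) -> float:
        return self.shared_b / self.n_b if self.n_b else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "shared_a": self.shared_a,
            "shared_b": self.shared_b,
            "only_a": self.only_a,
            "only_b": self.only_b,
            "fraction_a": self.fraction_a,
            "fraction_b": self.fraction_b,
        }


def _as_frame(x) -> pd.DataFrame:
    return x.df if isinstance(x, ClusterSet) else x


def overlap_sets(a, b, min_overlap: int = 1) -> OverlapResult:
    """Count clusters shared between two sets (overlap >= ``min_overlap`` bp)."""
    fa = _as_frame(a)[["chrom", "start", "end"]]
    fb = _as_frame(b)[["chrom", "start", "end"]]
    if min_overlap <= 1:
        sa = int(overlaps_any(fa, fb).sum())
        sb = int(overlaps_any(fb, fa).sum())
    else:
        sa = int((max_overlap_bp(fa, fb) >= min_overlap).sum())
        sb = int((max_overlap_bp(fb, fa) >= min_overlap).sum())
    return OverlapResult(n_a=len(fa), n_b=len(fb), shared_a=sa, shared_b=sb)


def multiway_union(cluster_sets: list, labels: list[str] | None = None) -> pd.DataFrame:
    """Non-redundant union of several cluster sets with per-set membership flags.

    Intervals are joined on strict >= 1 bp overlap (touching intervals stay
    separate). The result carries one boolean ``in_<label>`` column per
    input set; ``attrs['n_merged']`` is the merged count and
    ``attrs['n_distinct']`` the sum of the input sizes (both conventions of
    counting a combined cluster set).
    """
    frames = [_as_frame(s) for s in cluster_sets]
    if labels is None:
        labels = [f"set{i + 1}" for i in range(len(frames))]
    pooled = pd.concat(
        [f[["chrom", "start", "end"]] for f in frames], ignore_index=True
    )
    out = []
    for chrom, sub in pooled.groupby("chrom", sort=True, observed=True):
        starts = np.sort(sub["start"].to_numpy(np.int64))
        ends = sub["end"].to_numpy(np.int64)[np.argsort(sub["start"].to_numpy(np.int64), kind="stable")]
        _, ms, me = merge_sorted(starts, ends, gap=-1)
        out.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    union = (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    for lab, frame in zip(labels, frames):
        union[f"in_{lab}"] = overlaps_any(union, frame[["chrom", "start", "end"]])
    union.attrs["n_merged"] = len(union)
    union.attrs["n_distinct"] = int(sum(len(f) for f in frames))
    return union


def abundance_heatmap_table(
    intervals: pd.DataFrame,
    samples: dict,
    scale: str = "none",
) -> pd.DataFrame:
    """Matrix of RPTM values, intervals x samples.

    ``samples`` maps a sample label to its list of (filtered) ReadSets.
    ``scale`` is 'none', 'max' (each row divided by its maximum, zero rows
    left at zero) or 'zscore' (constant rows left at zero). The scaling mode
    is recorded in ``attrs['scale']``.
    """
    if len(intervals) == 0 or not samples:
        raise ValueError("need at least one interval and one sample")
    mat = {
        label: quantify_on(intervals, readsets) for label, readsets in samples.items()
    }
    table = pd.DataFrame(mat, index=_interval_index(intervals))
    if scale == "max":
        peak = table.max(axis=1)
        table = table.div(peak.where(peak > 0, 1.0), axis=0)
    elif scale == "zscore":
        mu = table.mean(axis=1)
        sd = table.std(axis=1, ddof=0)
        table = table.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    elif scale != "none":
        raise ValueError(f"unknown scaling mode: {scale!r}")
    table.attrs["scale"] = scale
    return table


def _interval_index(intervals: pd.DataFrame) -> pd.Index:
    return pd.Index(
        [
            f"{c}:{s}-{e}"
            for c, s, e in zip(intervals["chrom"], intervals["start"], intervals["end"])
        ],
        name="interval",
    )


def binned_abundance(
    readsets: list[ReadSet],
    chromosomes: pd.DataFrame,
    bin_size: int = 500_000,
    library_size: int | None = None,
) -> pd.DataFrame:
    """Genome-wide RPTM in fixed windows (BEDGraph-style track table).

    ``chromosomes`` needs columns chrom/length. The default 500 kb windows
    give the coarse genome-distribution view that distinguishes an evenly
    spread library from one concentrated at a few loci.
    """
    rows = []
    for chrom, length in zip(chromosomes["chrom"], chromosomes["length"]):
        edges = np.arange(0, int(length) + bin_size, bin_size, dtype=np.int64)
        starts = edges[:-1]
        ends = np.minimum(edges[1:], int(length))
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    bins["abundance"] = quantify_on(bins, readsets, library_size=library_size)
    return bins
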