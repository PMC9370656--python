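"""Distance-based 24 nt siRNA cluster calling and billionaire classification.

Reads from all replicates are pooled and merged transitively whenever the
gap between them is at most ``merge_gap`` bp (100 bp by default). Merged
regions with abundance strictly above ``min_rptm`` (12 RPTM) are siRNA
clusters; clusters strictly above ``bill_threshold`` (2000 RPTM) are
"billionaire" (bill-) clusters, the rest "pauper" (pau-) clusters. Both
thresholds are strict inequalities: a region at exactly 12 RPTM is not a
cluster, a cluster at exactly 2000 RPTM is a pauper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import merge_sorted, overlaps_any
from .read_processing import ReadSet, combined_library_size, rptm

CLUSTER_COLUMNS = ["chrom", "start", "end", "cluster_id", "raw_count", "abundance", "length", "label"]


@dataclass(frozen=True)
class Cluster:
    """One called siRNA cluster (a row view of :class:`ClusterSet`)."""

    chrom: str
    start: int
    end: int
    cluster_id: str
    raw_count: int
    abundance: float
    label: str | None = None
    per_replicate_counts: dict | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ClusterSet:
    """Called siRNA clusters for one sample (replicates combined).

    ``df`` rows are non-overlapping intervals sorted by (chrom, start) with
    ``raw_count`` (pooled reads), ``abundance`` (RPTM against the combined
    library size), ``length`` and, after :func:`classify_bill`, a
    ``label`` column in {"bill", "pau"}. Per-replicate read counts live in
    ``count_<replicate>`` columns.
    """

    df: pd.DataFrame
    sample: str = "sample"
    library_size: int = 0
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        rep_cols = [c for c in self.df.columns if c.startswith("count_")]
        for row in self.df.itertuples(index=False):
            yield Cluster(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                cluster_id=row.cluster_id,
                raw_count=int(row.raw_count),
                abundance=float(row.abundance),
                label=getattr(row, "label", None),
                per_replicate_counts={
                    c.removeprefix("count_"): int(getattr(row, c)) for c in rep_cols
                },
            )

    def group(self, label: str) -> pd.DataFrame:
        """Rows of one class ('bill', 'pau' or 'all')."""
        if label == "all":
            return self.df
        if "label" not in self.df.columns:
            raise ValueError("clusters are not classified yet; run classify_bill")
        return self.df[self.df["label"] == label]

    @property
    def n_bill(self) -> int:
        return int((self.df.get("label") == "bill").sum())

    @property
    def n_pau(self) -> int:
        return int((self.df.get("label") == "pau").sum())


def merge_reads(readsets: list[ReadSet], merge_gap: int = 100) -> pd.DataFrame:
    """Pool replicate reads and merge them into candidate regions.

    Intervals whose gap (next start minus running max end) is <= ``merge_gap``
    coalesce transitively, strand ignored. Every pooled read falls in exactly
    one candidate, so candidate ``raw_count`` values sum to the pooled read
    total. Returns a frame with chrom/start/end/raw_count plus one
    ``count_<replicate>`` column per replicate.
    """
    if isinstance(readsets, ReadSet):
        readsets = [readsets]
    frames = [rs.df for rs in readsets]
    reps = sorted({str(r) for df in frames for r in df["replicate"].unique()})
    pooled = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end", "replicate"])
    )
    rep_code = {r: i for i, r in enumerate(reps)}
    chrom_codes, chrom_uniques = pd.factorize(pooled["chrom"], sort=True)
    all_starts = pooled["start"].to_numpy(np.int64)
    all_ends = pooled["end"].to_numpy(np.int64)
    all_rcodes = pd.Categorical(pooled["replicate"], categories=reps).codes
    out = []
    for i, chrom in enumerate(chrom_uniques):
        mask = chrom_codes == i
        starts = all_starts[mask]
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        ends = all_ends[mask][order]
        codes = all_rcodes[mask][order]
        idx, ms, me = merge_sorted(starts, ends, merge_gap)
        n = len(ms)
        frame = {"chrom": chrom, "start": ms, "end": me,
                 "raw_count": np.bincount(idx, minlength=n)}
        for r, c in rep_code.items():
            frame[f"count_{r}"] = np.bincount(idx[codes == c], minlength=n)
        out.append(pd.DataFrame(frame))
    if not out:
        cols = ["chrom", "start", "end", "raw_count"] + [f"count_{r}" for r in reps]
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def call_clusters(
    candidates: pd.DataFrame,
    library_size: int,
    min_rptm: float = 12.0,
    sample: str = "sample",
    merge_gap: int | None = None,
) -> ClusterSet:
    """Keep candidate regions with abundance strictly above ``min_rptm`` RPTM."""
    abundance = rptm(candidates["raw_count"].to_numpy(np.int64), library_size)
    kept = candidates.loc[abundance > min_rptm].copy()
    kept["abundance"] = abundance[abundance > min_rptm]
    kept["length"] = kept["end"] - kept["start"]
    kept = kept.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    kept.insert(3, "cluster_id", [f"cluster_{i + 1}" for i in range(len(kept))])
    return ClusterSet(
        df=kept,
        sample=sample,
        library_size=int(library_size),
        params={"min_rptm": min_rptm, "merge_gap": merge_gap},
    )


def classify_bill(clusters: ClusterSet, bill_threshold: float = 2000.0) -> ClusterSet:
    """Label clusters bill (abundance strictly > threshold) or pau."""
    df = clusters.df.copy()
    df["label"] = np.where(df["abundance"].to_numpy() > bill_threshold, "bill", "pau")
    params = dict(clusters.params)
    params["bill_threshold"] = bill_threshold
    return replace(clusters, df=df, params=params)


def cluster_pipeline(
    readsets: list[ReadSet],
    merge_gap: int = 100,
    min_rptm: float = 12.0,
    bill_threshold: float = 2000.0,
    sample: str | None = None,
    library_size: int | None = None,
) -> ClusterSet:
    """merge -> call -> classify on already-filtered replicate ReadSets.

    ``library_size`` defaults to the sum of the replicates' library sizes
    (replicates combined).
    """
    if library_size is None:
        library_size = combined_library_size(readsets)
    cands = merge_reads(readsets, merge_gap=merge_gap)
    cs = call_clusters(
        cands,
        library_size,
        min_rptm=min_rptm,
        sample=sample or readsets[0].sample,
        merge_gap=merge_gap,
    )
    return classify_bill(cs, bill_threshold=bill_threshold)


def first_base_composition(
    clusters: ClusterSet, readsets: list[ReadSet], group: str = "all"
) -> pd.Series:
    """Fraction of A/C/G/T at the 5' base of reads inside a cluster group.

    Read-weighted: each read overlapping (>= 1 bp) a cluster of the group
    counts once. Clusters are non-overlapping, so no double counting.
    """
    regions = clusters.group(group)
    if isinstance(readsets, ReadSet):
        readsets = [readsets]
    pooled = pd.concat([rs.df for rs in readsets], ignore_index=True)
    if len(regions) == 0 or len(pooled) == 0:
        raise ValueError(f"no reads or no clusters in group {group!r}")
    inside = overlaps_any(pooled[["chrom", "start", "end"]], regions[["chrom", "start", "end"]])
    hit = pooled.loc[inside, "first_base"]
    if len(hit) == 0:
        raise ValueError(f"no reads overlap clusters of group {group!r}")
    counts = hit.value_counts().reindex(list("ACGT"), fill_value=0)
    return counts / counts.sum()


@dataclass
class GroupComparison:
    """Two-group summary for cluster length and per-bp abundance."""

    median_length_a: float
    median_length_b: float
    length_pvalue: float
    median_density_a: float
    median_density_b: float
    density_pvalue: float
    n_a: int
    n_b: int


def length_and_density_stats(group_a: pd.DataFrame, group_b: pd.DataFrame) -> GroupComparison:
    """Compare lengths and per-bp abundances (RPTM/bp) of two cluster groups.

    Uses the two-sided Wilcoxon rank-sum test for both quantities.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both cluster groups must be non-empty")
    len_a = (group_a["end"] - group_a["start"]).to_numpy(float)
    len_b = (group_b["end"] - group_b["start"]).to_numpy(float)
    dens_a = group_a["abundance"].to_numpy(float) / len_a
    dens_b = group_b["abundance"].to_numpy(float) / len_b
    return GroupComparison(
        median_length_a=float(np.median(len_a)),
        median_length_b=float(np.median(len_b)),
        length_pvalue=float(stats.ranksums(len_a, len_b).pvalue),
        median_density_a=float(np.median(dens_a)),
        median_density_b=float(np.median(dens_b)),
        density_pvalue=float(stats.ranksums(dens_a, dens_b).pvalue),
        n_a=len(group_a),
        n_b=len(group_b),
    )


def write_clusters_bed(clusters: ClusterSet, path) -> None:
    """BED6+2: chrom, start, end, cluster_id, abundance, '.', raw_count, label."""
    df = clusters.df
    out = pd.DataFrame(
        {
            0: df["chrom"],
            1: df["start"],
            2: df["end"],
            3: df["cluster_id"],
            4: df["abundance"],
            5: ".",
            6: df["raw_count"],
            7: df["label"] if "label" in df.columns else ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_clusters_bed(path, sample: str = "sample", library_size: int = 0) -> ClusterSet:
    """Read back a cluster BED written by :func:`write_clusters_bed`."""
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["chrom", "start", "end", "cluster_id", "abundance", "score", "raw_count", "label"][: df.shape[1]]
    df = df.drop(columns=[c for c in ("score",) if c in df.columns])
    df["length"] = df["end"] - df["start"]
    return ClusterSet(df=df, sample=sample, library_size=library_size)
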