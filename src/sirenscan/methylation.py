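"""Per-context DNA methylation levels over interval sets.

Levels follow the pooled-count definition: within a region, the total number
of methylated cytosine calls divided by the total number of sequenced
cytosine calls of that context (both strands pooled) — a read-weighted
level, not the mean of per-site levels. Cytosines with zero coverage
contribute to neither numerator nor denominator; a region with no covered
cytosine of the requested context has an undefined (not zero) level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

CONTEXTS = ("CG", "CHG", "CHH")
CX_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]


@dataclass
class RegionMethylation:
    """Methylation summary of one interval in one context."""

    chrom: str
    start: int
    end: int
    context: str
    level: float | None        # None when no covered cytosine in the region
    covered_cytosines: int
    total_reads: int

    @property
    def defined(self) -> bool:
        return self.level is not None


def load_cx_report(path) -> pd.DataFrame:
    """Read a cytosine report (TSV: chrom, 1-based pos, strand, context, counts).

    Positions are converted to the package's internal 0-based convention.
    Both strands are retained. Unknown context tokens or methylated counts
    exceeding totals are parse errors.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=CX_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str},
        comment="#",
    )
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: unknown context {df['context'].iloc[i]!r} at line {i + 1}"
        )
    if (df["count_methylated"] > df["count_total"]).any():
        i = int(np.flatnonzero((df["count_methylated"] > df["count_total"]).to_numpy())[0])
        raise ValueError(f"{path}: methylated > total at line {i + 1}")
    if (df[["count_methylated", "count_total"]] < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    df["pos"] = df["pos"].astype(np.int64) - 1
    return df


def write_cx_report(records: pd.DataFrame, path) -> None:
    """Write records back to the 1-based TSV cytosine-report format."""
    out = records.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


class MethylationIndex:
    """Prefix-sum index for fast pooled levels over many intervals."""

    def __init__(self, records: pd.DataFrame, context: str):
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        sub = records[records["context"] == context]
        self.context = context
        self._chrom = {}
        for chrom, grp in sub.groupby("chrom", sort=False, observed=True):
            pos = grp["pos"].to_numpy(np.int64)
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            m = grp["count_methylated"].to_numpy(np.int64)[order]
            t = grp["count_total"].to_numpy(np.int64)[order]
            self._chrom[chrom] = (
                pos,
                np.concatenate(([0], np.cumsum(m))),
                np.concatenate(([0], np.cumsum(t))),
                np.concatenate(([0], np.cumsum((t > 0).astype(np.int64)))),
            )

    def sums(self, chrom, starts: np.ndarray, ends: np.ndarray):
        """(methylated, total, covered_sites) pooled per interval."""
        entry = self._chrom.get(chrom)
        n = len(starts)
        if entry is None:
            z = np.zeros(n, dtype=np.int64)
            return z, z.copy(), z.copy()
        pos, cm, ct, cc = entry
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="left")
        return cm[i1] - cm[i0], ct[i1] - ct[i0], cc[i1] - cc[i0]


def region_level(
    records: pd.DataFrame, interval, context: str
) -> RegionMethylation:
    """Pooled methylation level of one interval: sum(methylated)/sum(total).

    ``interval`` is (chrom, start, end) or any object with those attributes.
    """
    chrom, start, end = _interval_tuple(interval)
    idx = MethylationIndex(records, context)
    m, t, c = idx.sums(chrom, np.array([start]), np.array([end]))
    level = float(m[0]) / float(t[0]) if t[0] > 0 else None
    return RegionMethylation(
        chrom=chrom, start=int(start), end=int(end), context=context,
        level=level, covered_cytosines=int(c[0]), total_reads=int(t[0]),
    )


def region_levels(
    records: pd.DataFrame, intervals: pd.DataFrame, context: str
) -> pd.DataFrame:
    """Vectorized :func:`region_level` over an interval frame.

    Returns intervals plus ``level`` (NaN when undefined),
    ``covered_cytosines`` and ``total_reads`` columns.
    """
    idx = MethylationIndex(records, context)
    out = intervals[["chrom", "start", "end"]].reset_index(drop=True).copy()
    level = np.full(len(out), np.nan)
    covered = np.zeros(len(out), dtype=np.int64)
    total = np.zeros(len(out), dtype=np.int64)
    chroms = out["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        m, t, c = idx.sums(
            chrom,
            out.loc[mask, "start"].to_numpy(np.int64),
            out.loc[mask, "end"].to_numpy(np.int64),
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            level[mask] = np.where(t > 0, m / np.maximum(t, 1), np.nan)
        covered[mask] = c
        total[mask] = t
    out["level"] = level
    out["covered_cytosines"] = covered
    out["total_reads"] = total
    return out


@dataclass
class GroupLevels:
    """Per-group cluster-level distributions and pairwise rank-sum p-values."""

    levels: dict            # group label -> np.ndarray of defined levels
    dropped: dict           # group label -> count of undefined clusters
    pvalues: pd.DataFrame   # symmetric matrix of two-sided rank-sum p-values
    context: str


def compare_groups(groups: dict, context: str) -> GroupLevels:
    """Compare per-cluster methylation levels between groups.

    ``groups`` maps a label to a ``(records, intervals)`` pair — e.g.
    ``{"WT": (wt_cx, bill_clusters), "mutant": (mut_cx, bill_clusters)}``.
    Clusters with undefined levels are dropped (and counted); every pair of
    groups is compared with the two-sided Wilcoxon rank-sum test.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    levels, dropped = {}, {}
    for label, (records, intervals) in groups.items():
        tab = region_levels(records, intervals, context)
        vals = tab["level"].to_numpy(float)
        ok = ~np.isnan(vals)
        if not ok.any():
            raise ValueError(f"group {label!r} has no defined methylation levels")
        levels[label] = vals[ok]
        dropped[label] = int((~ok).sum())
    labels = list(levels)
    pmat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        p = float(stats.ranksums(levels[a], levels[b]).pvalue)
        pmat.loc[a, b] = pmat.loc[b, a] = p
    return GroupLevels(levels=levels, dropped=dropped, pvalues=pmat, context=context)


def _interval_tuple(interval):
    if isinstance(interval, (tuple, list)):
        return interval[0], int(interval[1]), int(interval[2])
    return interval.chrom, int(interval.start), int(interval.end)
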