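"""Vectorized genomic-interval primitives shared across the package.

All coordinates are 0-based half-open. The two workhorses are a
distance-based merge (bedtools ``merge -d`` semantics: intervals whose gap
is <= ``gap`` coalesce transitively) and searchsorted-based overlap
counting, both O(n log n) so that multi-million-read libraries stay cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: column order for interval frames used throughout the package
BED_COLS = ["chrom", "start", "end"]


def merge_sorted(starts: np.ndarray, ends: np.ndarray, gap: int = 0):
    """Merge intervals already sorted by start on one chromosome.

    Two consecutive intervals merge when ``next.start - running_max_end <= gap``.
    ``gap=-1`` gives strict-overlap union (touching intervals stay apart),
    ``gap=0`` merges bookended intervals, ``gap=d`` is a distance-d merge.

    Returns ``(cluster_index, merged_starts, merged_ends)`` where
    ``cluster_index[i]`` is the merged-interval id of input interval i.
    """
    n = len(starts)
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy()
    cummax_end = np.maximum.accumulate(ends)
    breaks = starts[1:] > cummax_end[:-1] + gap
    idx = np.concatenate(([0], np.cumsum(breaks)))
    first = np.concatenate(([True], breaks))
    merged_starts = starts[first]
    # last member of each run holds the running max end
    last = np.concatenate((breaks, [True]))
    merged_ends = cummax_end[last]
    return idx, merged_starts, merged_ends


def merge_frame(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Distance-merge an interval frame (chrom/start/end) across chromosomes."""
    out = []
    for chrom, sub in df.groupby("chrom", sort=True, observed=True):
        s = np.sort(sub["start"].to_numpy(np.int64))
        order = np.argsort(sub["start"].to_numpy(np.int64), kind="stable")
        e = sub["end"].to_numpy(np.int64)[order]
        _, ms, me = merge_sorted(s, e, gap)
        out.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    if not out:
        return pd.DataFrame(columns=BED_COLS)
    return pd.concat(out, ignore_index=True)


class _ChromIndex:
    """Per-chromosome sorted start/end arrays for overlap counting.

    Counts intervals overlapping a query [s, e) by >= 1 bp:
    ``#(start < e) - #(end <= s)`` — valid because every interval with
    end <= s also has start < e whenever s < e.
    """

    def __init__(self, df: pd.DataFrame):
        self._starts = {}
        self._ends = {}
        codes, uniques = pd.factorize(df["chrom"])
        starts = df["start"].to_numpy(np.int64)
        ends = df["end"].to_numpy(np.int64)
        for i, chrom in enumerate(uniques):
            mask = codes == i
            self._starts[chrom] = np.sort(starts[mask])
            self._ends[chrom] = np.sort(ends[mask])

    def count(self, chrom, qstart: np.ndarray, qend: np.ndarray) -> np.ndarray:
        s = self._starts.get(chrom)
        if s is None:
            return np.zeros(len(qstart), dtype=np.int64)
        e = self._ends[chrom]
        return (
            np.searchsorted(s, qend, side="left")
            - np.searchsorted(e, qstart, side="right")
        )


def count_overlaps(targets: pd.DataFrame, queries: pd.DataFrame) -> np.ndarray:
    """Count targets overlapping (>=1 bp) each query interval.

    Returns one count per row of ``queries`` (in input order).
    """
    index = _ChromIndex(targets)
    counts = np.zeros(len(queries), dtype=np.int64)
    codes, uniques = pd.factorize(queries["chrom"])
    starts = queries["start"].to_numpy(np.int64)
    ends = queries["end"].to_numpy(np.int64)
    for i, chrom in enumerate(uniques):
        mask = codes == i
        counts[mask] = index.count(chrom, starts[mask], ends[mask])
    return counts


def overlaps_any(queries: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean mask over ``queries``: does each overlap any target by >=1 bp."""
    return count_overlaps(targets, queries) > 0


def max_overlap_bp(queries: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Maximum per-query overlap length (bp) with any single target interval.

    Used for minimum-overlap membership rules (``min_overlap > 1``); linear
    scans are confined to the window of targets that can touch the query.
    """
    out = np.zeros(len(queries), dtype=np.int64)
    by_chrom = {}
    for chrom, sub in targets.groupby("chrom", sort=False, observed=True):
        order = np.argsort(sub["start"].to_numpy(np.int64), kind="stable")
        ts = sub["start"].to_numpy(np.int64)[order]
        te = sub["end"].to_numpy(np.int64)[order]
        by_chrom[chrom] = (ts, te, np.maximum.accumulate(te))
    qc = queries["chrom"].to_numpy()
    qs = queries["start"].to_numpy(np.int64)
    qe = queries["end"].to_numpy(np.int64)
    for i in range(len(queries)):
        triple = by_chrom.get(qc[i])
        if triple is None:
            continue
        ts, te, cm = triple
        hi = np.searchsorted(ts, qe[i], side="left")
        lo = np.searchsorted(cm, qs[i], side="right")
        if hi <= lo:
            continue
        ov = np.minimum(te[lo:hi], qe[i]) - np.maximum(ts[lo:hi], qs[i])
        out[i] = max(0, int(ov.max()))
    return out
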