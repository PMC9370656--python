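"""Chromatin-mark enrichment, random controls, adjacent genes and DEG fractions.

Histone-mark/Pol II occupancy over cluster groups is expressed as per-region
RPKM (reads x 1e9 / (region length in bp x mapped total)); random genomic
regions (20,000 x 350 bp by default) and random gene draws (n=300) serve as
controls. "Adjacent" genes are genes overlapping a cluster by >= 1 bp; the
differential-expression filter on a supplied DE table is |fold change| > 2
and FDR < 0.05, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import _ChromIndex, overlaps_any


def rpkm(count, length_bp, mapped_total) -> np.ndarray:
    """Reads per kilobase per million mapped reads."""
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("zero-length region in RPKM computation")
    return np.asarray(count, dtype=float) / (length_bp / 1e3) / (mapped_total / 1e6)


def region_rpkm(
    chip_reads: pd.DataFrame, regions: pd.DataFrame, mapped_total: int
) -> np.ndarray:
    """Per-region RPKM of ChIP reads (overlap >= 1 bp counts a read)."""
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    index = _ChromIndex(chip_reads[["chrom", "start", "end"]])
    counts = np.zeros(len(regions), dtype=np.int64)
    chroms = regions["chrom"].to_numpy()
    starts = regions["start"].to_numpy(np.int64)
    ends = regions["end"].to_numpy(np.int64)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        counts[mask] = index.count(chrom, starts[mask], ends[mask])
    return rpkm(counts, ends - starts, mapped_total)


@dataclass
class EnrichmentProfile:
    """Mark enrichment on an interval group versus a random-region control."""

    regions_label: str
    mark: str
    region_rpkm: np.ndarray
    control_rpkm: np.ndarray
    pvalue: float  # two-sided rank-sum, regions vs control

    @property
    def median_region(self) -> float:
        return float(np.median(self.region_rpkm))

    @property
    def median_control(self) -> float:
        return float(np.median(self.control_rpkm))


def rpkm_enrichment(
    chip_reads: pd.DataFrame,
    mapped_total: int,
    regions: pd.DataFrame,
    control_regions: pd.DataFrame,
    mark: str = "mark",
    regions_label: str = "regions",
) -> EnrichmentProfile:
    """RPKM of a ChIP mark on a region group, compared with control regions."""
    vals = region_rpkm(chip_reads, regions, mapped_total)
    ctrl = region_rpkm(chip_reads, control_regions, mapped_total)
    return EnrichmentProfile(
        regions_label=regions_label,
        mark=mark,
        region_rpkm=vals,
        control_rpkm=ctrl,
        pvalue=float(stats.ranksums(vals, ctrl).pvalue),
    )


def random_region_control(
    chromosomes: pd.DataFrame, n: int = 20_000, length: int = 350, seed: int = 0
) -> pd.DataFrame:
    """``n`` random fixed-length regions, uniform over the genome.

    Chromosomes shorter than ``length`` are excluded. Regions land on a
    chromosome with probability proportional to its length, reproducibly for
    a fixed seed.
    """
    ok = chromosomes[chromosomes["length"] >= length].reset_index(drop=True)
    if len(ok) == 0:
        raise ValueError(f"no chromosome can hold a {length} bp region")
    rng = np.random.default_rng(seed)
    weights = ok["length"].to_numpy(float)
    picks = rng.choice(len(ok), size=n, p=weights / weights.sum())
    maxstart = ok["length"].to_numpy(np.int64)[picks] - length
    starts = rng.integers(0, maxstart + 1)
    return pd.DataFrame(
        {
            "chrom": ok["chrom"].to_numpy()[picks],
            "start": starts,
            "end": starts + length,
        }
    )


def load_gff3_genes(path) -> pd.DataFrame:
    """Gene intervals from GFF3 via pyranges (converted to 0-based half-open)."""
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    genes = df[df["Feature"] == "gene"]
    out = pd.DataFrame(
        {
            "gene_id": genes["ID"].astype(str),
            "chrom": genes["Chromosome"].astype(str),
            "start": genes["Start"].astype(np.int64),
            "end": genes["End"].astype(np.int64),
            "strand": genes["Strand"].astype(str),
        }
    ).sort_values(["chrom", "start", "gene_id"], kind="stable").reset_index(drop=True)
    if out["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated gene IDs")
    return out


def load_expression_table(path) -> pd.DataFrame:
    """FPKM table: first column gene_id, remaining columns one per sample."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "gene_id"}).set_index("gene_id")
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative FPKM values")
    return df


def load_de_table(path) -> pd.DataFrame:
    """DE results: columns gene_id, log2fc, fdr."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    need = {"gene_id", "log2fc", "fdr"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(need)}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError(f"{path}: FDR outside [0, 1]")
    return df[["gene_id", "log2fc", "fdr"]]


def adjacent_genes(
    clusters, genes: pd.DataFrame, mode: str = "overlap", flank: int = 0
) -> pd.DataFrame:
    """Genes overlapping (>= 1 bp) any cluster of the group.

    ``mode='flank'`` additionally extends every cluster by ``flank`` bp on
    both sides before the overlap test (a configurable nearby-gene variant,
    off by default).
    """
    cl = clusters.df if hasattr(clusters, "df") else clusters
    cl = cl[["chrom", "start", "end"]].copy()
    if mode == "flank":
        cl["start"] = np.maximum(cl["start"] - flank, 0)
        cl["end"] = cl["end"] + flank
    elif mode != "overlap":
        raise ValueError(f"unknown adjacency mode: {mode!r}")
    hit = overlaps_any(genes[["chrom", "start", "end"]], cl)
    return genes.loc[hit].reset_index(drop=True)


def random_gene_control(genes: pd.DataFrame, n: int = 300, seed: int = 0) -> pd.DataFrame:
    """``n`` genes drawn without replacement (all genes if fewer exist)."""
    rng = np.random.default_rng(seed)
    k = min(n, len(genes))
    picks = rng.choice(len(genes), size=k, replace=False)
    return genes.iloc[np.sort(picks)].reset_index(drop=True)


@dataclass
class DegFraction:
    """Differential-expression summary for a gene set."""

    fraction: float
    n_de: int
    n_genes: int
    n_missing: int  # genes absent from the DE table, counted as non-DE


def deg_fraction(
    gene_ids,
    de: pd.DataFrame,
    fc_cutoff: float = 2.0,
    fdr_cutoff: float = 0.05,
) -> DegFraction:
    """Fraction of a gene set that is differentially expressed.

    DE iff |log2FC| > log2(fc_cutoff) and FDR < fdr_cutoff, both strict
    (fold change exactly at the cutoff is not DE). Genes missing from the
    DE table count as non-DE and are tallied separately.
    """
    ids = list(gene_ids["gene_id"]) if isinstance(gene_ids, pd.DataFrame) else list(gene_ids)
    if len(ids) == 0:
        raise ValueError("cannot compute a DEG fraction of an empty gene set")
    sub = de.set_index("gene_id").reindex(ids)
    missing = int(sub["log2fc"].isna().sum())
    is_de = (sub["log2fc"].abs() > np.log2(fc_cutoff)) & (sub["fdr"] < fdr_cutoff)
    n_de = int(is_de.fillna(False).sum())
    return DegFraction(
        fraction=n_de / len(ids), n_de=n_de, n_genes=len(ids), n_missing=missing
    )
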