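"""Synthetic genomes, siRNA libraries, methylomes and annotations with ground truth.

The generator reproduces the statistical regime the billionaire/pauper
analysis assumes: a small set of "bill" loci carrying a large majority of
the 24 nt reads, a crowd of weaker "pau" loci, structural-RNA loci whose
reads must be filtered out, a sparse genome-wide background, an A-biased
first base, siRNA-mutant libraries with near-complete locus depletion, and
CHH methylation elevated at siRNA loci in the wild type but not the mutant.
Every simulation records its planted truth so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .read_processing import READ_COLUMNS, ReadSet

GENOTYPES = ("wild_type", "mutant")
READ_LENGTH = 24


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    The defaults describe the concentrated wild-type regime: two 50 Mb
    chromosomes (large enough that the 5% background stays far sparser than
    the 100 bp merge distance), 5 bill loci holding 70% of the non-structural
    read mass against 200 pau loci, two replicates of 1e6 24 nt reads,
    an A-enriched first base, and a mutant retaining 5% of each planted
    locus's siRNA output.
    """

    n_chromosomes: int = 2
    chrom_length: int = 50_000_000
    n_bill_loci: int = 5
    n_pau_loci: int = 200
    bill_read_share: float = 0.7
    total_reads: int = 1_000_000
    n_replicates: int = 2
    first_base_probs: tuple = (0.4, 0.2, 0.2, 0.2)  # A, C, G, T
    bill_locus_length_range: tuple = (1_000, 3_000)
    pau_locus_length_range: tuple = (200, 800)
    mutant_depletion_factor: float = 0.05
    structural_rna_loci: int = 10
    structural_read_fraction: float = 0.05
    background_read_fraction: float = 0.05
    zipf_exponent: float = 1.0
    # methylome knobs: planted CHH at siRNA loci drops in the mutant while
    # CG/CHG stay flat (the RdDM-dependent context is CHH)
    chh_locus_level: float = 0.30
    chh_locus_level_mutant: float = 0.03
    chh_background_level: float = 0.02
    cg_level: float = 0.60
    chg_level: float = 0.30
    meth_coverage: int = 50
    cytosine_spacing: int = 25
    n_background_cytosines: int = 5_000
    # gene / expression knobs
    n_genes: int = 400
    gene_length_range: tuple = (1_000, 4_000)
    de_gene_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_bill_loci": self.n_bill_loci,
            "n_pau_loci": self.n_pau_loci,
            "total_reads": self.total_reads,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        probs = np.asarray(self.first_base_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("first_base_probs must be 4 non-negative values summing to 1")
        if not 0 < self.bill_read_share < 1:
            raise ValueError("bill_read_share must be in (0, 1)")
        if not 0 <= self.mutant_depletion_factor <= 1:
            raise ValueError("mutant_depletion_factor must be in [0, 1]")
        for name in ("structural_read_fraction", "background_read_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.structural_read_fraction + self.background_read_fraction >= 1:
            raise ValueError("structural + background read fractions must leave locus mass")


class PlacementError(RuntimeError):
    """Raised when planted loci cannot be placed without overlap."""


@dataclass
class SyntheticTruth:
    """Planted loci, their expected read mass and CHH levels, and the config.

    ``loci`` columns: chrom, start, end, label (bill|pau|structural),
    read_mass (expected fraction of one replicate's reads originating from
    the locus), chh_wt, chh_mut. ``chromosomes`` columns: chrom, length.
    """

    chromosomes: pd.DataFrame
    loci: pd.DataFrame
    config: SimulationConfig

    def loci_of(self, label: str) -> pd.DataFrame:
        return self.loci[self.loci["label"] == label].reset_index(drop=True)

    @property
    def background_mass(self) -> float:
        return 1.0 - float(self.loci["read_mass"].sum())

    def expected_rptm(self, genotype: str = "wild_type") -> np.ndarray:
        """Expected abundance of each planted locus under the retained-read
        RPTM basis (structural reads are filtered before normalization;
        structural loci therefore report 0)."""
        mass = self.loci["read_mass"].to_numpy(float)
        if genotype == "mutant":
            mass = mass * _mutant_scale(self.loci, self.config)
        structural = self.loci["label"].to_numpy() == "structural"
        retained = 1.0 - mass[structural].sum()
        return np.where(structural, 0.0, mass) / retained * 1e7


def _mutant_scale(loci: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    labels = loci["label"].to_numpy()
    scale = np.ones(len(loci))
    scale[(labels == "bill") | (labels == "pau")] = config.mutant_depletion_factor
    return scale


def simulate_genome(config: SimulationConfig) -> SyntheticTruth:
    """Place bill, pau and structural loci uniformly at random without overlap.

    Placement retries a bounded number of times; a genome too small for the
    requested loci raises :class:`PlacementError`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = pd.DataFrame(
        {
            "chrom": [f"chr{i + 1}" for i in range(config.n_chromosomes)],
            "length": config.chrom_length,
        }
    )
    specs = (
        [("bill", config.bill_locus_length_range)] * config.n_bill_loci
        + [("pau", config.pau_locus_length_range)] * config.n_pau_loci
        + [("structural", (500, 2_000))] * config.structural_rna_loci
    )
    lengths = np.array(
        [rng.integers(lo, hi + 1) for _, (lo, hi) in specs], dtype=np.int64
    )
    labels = [lab for lab, _ in specs]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms["chrom"]}
    rows = []
    max_tries = 1000
    for lab, length in zip(labels, lengths):
        for attempt in range(max_tries):
            ci = int(rng.integers(0, config.n_chromosomes))
            chrom = chroms["chrom"].iloc[ci]
            limit = config.chrom_length - length
            if limit < 0:
                raise PlacementError(
                    f"chromosome length {config.chrom_length} cannot hold a {length} bp locus"
                )
            start = int(rng.integers(0, limit + 1))
            end = start + int(length)
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                rows.append((chrom, start, end, lab))
                break
        else:
            raise PlacementError(
                f"could not place a {length} bp {lab} locus after {max_tries} tries"
            )
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    loci["read_mass"] = _assign_read_mass(loci, config, rng)
    is_planted = loci["label"].isin(["bill", "pau"]).to_numpy()
    loci["chh_wt"] = np.where(is_planted, config.chh_locus_level, config.chh_background_level)
    loci["chh_mut"] = np.where(is_planted, config.chh_locus_level_mutant, config.chh_background_level)
    loci = loci.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return SyntheticTruth(chromosomes=chroms, loci=loci, config=config)


def _assign_read_mass(
    loci: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Zipf-like mass within each class; class totals fixed by the config.

    Non-structural, non-background mass splits bill_read_share : (1 - share)
    between the bill and pau classes; within a class, locus k (in random
    order) carries weight k^-zipf_exponent.
    """
    locus_mass = 1.0 - config.structural_read_fraction - config.background_read_fraction
    class_mass = {
        "bill": locus_mass * config.bill_read_share,
        "pau": locus_mass * (1.0 - config.bill_read_share),
        "structural": config.structural_read_fraction,
    }
    mass = np.zeros(len(loci))
    for label, total in class_mass.items():
        idx = np.flatnonzero(loci["label"].to_numpy() == label)
        if len(idx) == 0:
            continue
        ranks = rng.permutation(len(idx)) + 1.0
        w = ranks ** (-config.zipf_exponent)
        mass[idx] = total * w / w.sum()
    return mass


def _locus_weights(truth: SyntheticTruth, genotype: str) -> np.ndarray:
    """Per-replicate sampling weights over [loci..., background].

    Mutant libraries keep the configured total read count: the mass removed
    from planted loci (scaled by the depletion factor) moves to background,
    so per-locus expected reads shrink by exactly the factor while the
    emitted total stays fixed.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    mass = truth.loci["read_mass"].to_numpy(float).copy()
    if genotype == "mutant":
        mass = mass * _mutant_scale(truth.loci, truth.config)
    background = 1.0 - mass.sum()
    return np.concatenate([mass, [background]])


def simulate_reads(
    truth: SyntheticTruth, genotype: str = "wild_type"
) -> list[ReadSet]:
    """Draw per-replicate 24 nt read tables from the planted locus masses.

    Reads start uniformly within their locus; background reads fall
    uniformly over the genome but outside every planted locus; strand is a
    fair coin and the first base i.i.d. from ``first_base_probs``. Each
    replicate emits exactly ``total_reads`` reads.
    """
    config = truth.config
    weights = _locus_weights(truth, genotype)
    base_seed = np.asarray(
        np.random.SeedSequence([config.seed, GENOTYPES.index(genotype) + 1]).generate_state(1)
    )[0]
    chrom_names = list(truth.chromosomes["chrom"])
    chrom_index = {c: i for i, c in enumerate(chrom_names)}
    loci_chrom_codes = truth.loci["chrom"].map(chrom_index).to_numpy(np.int8)
    base_cum = np.cumsum(np.asarray(config.first_base_probs, float))
    readsets = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([int(base_seed % (2**31)), rep])
        counts = rng.multinomial(config.total_reads, weights)
        chroms_out, starts_out = [], []
        lo = truth.loci["start"].to_numpy(np.int64)
        hi = np.maximum(truth.loci["end"].to_numpy(np.int64) - READ_LENGTH + 1, lo + 1)
        for j, k in enumerate(counts[:-1]):
            if k == 0:
                continue
            starts_out.append(rng.integers(lo[j], hi[j], size=k))
            chroms_out.append(np.full(k, loci_chrom_codes[j], dtype=np.int8))
        n_bg = counts[-1]
        if n_bg:
            bg_code, bg_start = _background_positions(truth, rng, int(n_bg))
            chroms_out.append(bg_code)
            starts_out.append(bg_start)
        start = (
            np.concatenate(starts_out).astype(np.int64)
            if starts_out
            else np.array([], dtype=np.int64)
        )
        codes = (
            np.concatenate(chroms_out)
            if chroms_out
            else np.array([], dtype=np.int8)
        )
        n = len(start)
        df = pd.DataFrame(
            {
                "chrom": pd.Categorical.from_codes(codes, categories=chrom_names),
                "start": start,
                "end": start + READ_LENGTH,
                "strand": pd.Categorical.from_codes(
                    (rng.random(n) < 0.5).astype(np.int8), categories=["+", "-"]
                ),
                "first_base": pd.Categorical.from_codes(
                    np.searchsorted(base_cum, rng.random(n), side="right").astype(np.int8),
                    categories=list("ACGT"),
                ),
                "unique": True,
                "replicate": pd.Categorical.from_codes(
                    np.zeros(n, dtype=np.int8), categories=[f"rep{rep + 1}"]
                ),
            }
        )
        readsets.append(
            ReadSet(
                df=df[READ_COLUMNS],
                sample=genotype,
                genotype=genotype,
                replicate=f"rep{rep + 1}",
                library_size=n,
                n_mapped=n,
            )
        )
    return readsets


def _background_positions(
    truth: SyntheticTruth, rng: np.random.Generator, n: int
):
    """Uniform genome positions rejected out of planted loci (all classes).

    Returns ``(chrom_codes, starts)`` with codes indexing
    ``truth.chromosomes`` rows.
    """
    chroms = truth.chromosomes
    lengths = chroms["length"].to_numpy(np.int64) - READ_LENGTH
    weights = lengths / lengths.sum()
    # per-chromosome sorted locus bounds for the rejection test
    bounds = [
        (
            truth.loci.loc[truth.loci["chrom"] == row.chrom, "start"].to_numpy(np.int64),
            truth.loci.loc[truth.loci["chrom"] == row.chrom, "end"].to_numpy(np.int64),
        )
        for row in chroms.itertuples()
    ]
    out_code = np.empty(n, dtype=np.int8)
    out_start = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        todo = n - filled
        ci = rng.choice(len(chroms), size=todo, p=weights)
        pos = rng.integers(0, lengths[ci] + 1)
        keep = np.ones(todo, dtype=bool)
        for c in np.unique(ci):
            ls, le = bounds[c]
            mask = ci == c
            p = pos[mask]
            # read [p, p+24) avoids loci iff no locus with start < p+24 and end > p
            i_hi = np.searchsorted(ls, p + READ_LENGTH, side="left")
            i_lo = np.searchsorted(le, p, side="right")
            keep[mask] = i_hi <= i_lo
        k = int(keep.sum())
        out_code[filled : filled + k] = ci[keep].astype(np.int8)
        out_start[filled : filled + k] = pos[keep]
        filled += k
    return out_code, out_start


def simulate_methylome(truth: SyntheticTruth, genotype: str = "wild_type") -> pd.DataFrame:
    """Per-cytosine counts (CG/CHG/CHH) around planted loci plus background.

    Cytosine sites are laid down on a regular grid inside every planted
    locus and at random background positions; methylated counts are binomial
    around the locus's expected level. CHH at bill/pau loci is high in the
    wild type and depleted in the mutant; CG and CHG are planted equal in
    both genotypes (the RdDM-independent null).
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    config = truth.config
    seed = np.random.SeedSequence(
        [config.seed, 100 + GENOTYPES.index(genotype)]
    ).generate_state(1)[0]
    rng = np.random.default_rng(int(seed % (2**31)))
    chunks = []
    chh_col = "chh_wt" if genotype == "wild_type" else "chh_mut"
    for locus in truth.loci.itertuples():
        pos = np.arange(locus.start, locus.end, config.cytosine_spacing, dtype=np.int64)
        chh = getattr(locus, chh_col)
        chunks.append(_cytosine_chunk(locus.chrom, pos, chh, config, rng))
    # sparse background sites outside loci
    n_bg = config.n_background_cytosines
    if n_bg:
        bg_code, bg_pos = _background_positions(truth, rng, n_bg)
        bg_chrom = truth.chromosomes["chrom"].to_numpy()[bg_code]
        order = np.lexsort((bg_pos, bg_chrom))
        chunks.append(
            _cytosine_chunk_mixed(
                bg_chrom[order], bg_pos[order], config.chh_background_level, config, rng
            )
        )
    table = pd.concat(chunks, ignore_index=True)
    return table.sort_values(["chrom", "pos", "context"], kind="stable").reset_index(
        drop=True
    )


def _cytosine_chunk(chrom, pos, chh_level, config, rng) -> pd.DataFrame:
    """One locus's grid of sites, cycled through the three contexts."""
    contexts = np.array(["CG", "CHG", "CHH"])[np.arange(len(pos)) % 3]
    levels = np.select(
        [contexts == "CG", contexts == "CHG"],
        [config.cg_level, config.chg_level],
        default=chh_level,
    )
    total = np.full(len(pos), config.meth_coverage, dtype=np.int64)
    meth = rng.binomial(total, levels)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": np.where(rng.random(len(pos)) < 0.5, "+", "-"),
            "context": contexts,
            "count_methylated": meth,
            "count_total": total,
        }
    )


def _cytosine_chunk_mixed(chrom, pos, chh_level, config, rng) -> pd.DataFrame:
    df = _cytosine_chunk("x", pos, chh_level, config, rng)
    df["chrom"] = chrom.astype(str)
    return df


def simulate_chip_reads(
    truth: SyntheticTruth,
    n_reads: int = 200_000,
    read_length: int = 100,
    enrichment: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """ChIP-style read intervals with configurable per-class enrichment.

    ``enrichment`` maps locus class to a per-bp rate multiplier relative to
    background (default {'bill': 5.0}); reads otherwise fall uniformly.
    Returns a plain interval frame (chrom/start/end).
    """
    config = truth.config
    enrichment = {"bill": 5.0} if enrichment is None else enrichment
    rng = np.random.default_rng(
        int(np.random.SeedSequence([config.seed if seed is None else seed, 7]).generate_state(1)[0] % (2**31))
    )
    genome = float(truth.chromosomes["length"].sum())
    labels = truth.loci["label"].to_numpy()
    lens = (truth.loci["end"] - truth.loci["start"]).to_numpy(float)
    mult = np.array([enrichment.get(lab, 1.0) for lab in labels], dtype=float)
    # weight of each locus ∝ its length × its multiplier; background ∝ rest of genome
    w_loci = lens * mult
    w_bg = genome - lens.sum()
    weights = np.concatenate([w_loci, [w_bg]])
    weights = weights / weights.sum()
    counts = rng.multinomial(n_reads, weights)
    chroms_out, starts_out = [], []
    for (_, locus), k in zip(truth.loci.iterrows(), counts[:-1]):
        if k == 0:
            continue
        hi = max(locus["end"] - read_length + 1, locus["start"] + 1)
        starts_out.append(rng.integers(locus["start"], hi, size=k))
        chroms_out.append(np.repeat(locus["chrom"], k))
    if counts[-1]:
        bg_code, bg_pos = _background_positions(truth, rng, int(counts[-1]))
        chroms_out.append(truth.chromosomes["chrom"].to_numpy()[bg_code])
        starts_out.append(bg_pos)
    start = np.concatenate(starts_out).astype(np.int64)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms_out),
            "start": start,
            "end": start + read_length,
        }
    )


def simulate_genes(truth: SyntheticTruth) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene annotation, FPKM table and DE table with planted DE status.

    Genes are placed uniformly (overlaps with siRNA loci allowed — that is
    what the adjacent-gene analysis looks for). A planted fraction of genes
    is differentially expressed: |log2FC| in (1, 4] with FDR < 0.05; the
    rest sit inside the null box (|log2FC| < 0.8, FDR >= 0.05).
    """
    config = truth.config
    rng = np.random.default_rng(
        int(np.random.SeedSequence([config.seed, 9]).generate_state(1)[0] % (2**31))
    )
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    ci = rng.integers(0, config.n_chromosomes, size=config.n_genes)
    chrom = truth.chromosomes["chrom"].to_numpy()[ci]
    start = rng.integers(0, config.chrom_length - lengths + 1)
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:04d}" for i in range(config.n_genes)],
            "chrom": chrom,
            "start": start,
            "end": start + lengths,
            "strand": np.where(rng.random(config.n_genes) < 0.5, "+", "-"),
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    is_de = rng.random(config.n_genes) < config.de_gene_fraction
    log2fc = np.where(
        is_de,
        rng.uniform(1.0 + 1e-6, 4.0, config.n_genes) * np.where(rng.random(config.n_genes) < 0.5, 1, -1),
        rng.uniform(-0.8, 0.8, config.n_genes),
    )
    fdr = np.where(
        is_de, rng.uniform(0.0, 0.05, config.n_genes), rng.uniform(0.05, 1.0, config.n_genes)
    )
    de = pd.DataFrame({"gene_id": genes["gene_id"], "log2fc": log2fc, "fdr": fdr, "planted_de": is_de})
    base = rng.lognormal(mean=2.0, sigma=1.0, size=config.n_genes)
    fpkm = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "seedling": base,
            "inflorescence": base * 2 ** (log2fc),
        }
    )
    return genes, fpkm, de


def score_recovery(truth: SyntheticTruth, clusters) -> dict:
    """Score a called ClusterSet against the planted truth.

    Reports the fraction of planted bill loci overlapped (>= 1 bp) by a
    bill-labelled cluster, the same for pau loci by any cluster, and the
    number of bill-labelled clusters touching no planted locus at all
    (background false positives).
    """
    from ._intervals import overlaps_any

    df = clusters.df if hasattr(clusters, "df") else clusters
    bill_clusters = df[df["label"] == "bill"][["chrom", "start", "end"]]
    bill_loci = truth.loci_of("bill")
    pau_loci = truth.loci_of("pau")
    bill_found = (
        overlaps_any(bill_loci[["chrom", "start", "end"]], bill_clusters).mean()
        if len(bill_loci)
        else float("nan")
    )
    pau_found = (
        overlaps_any(pau_loci[["chrom", "start", "end"]], df[["chrom", "start", "end"]]).mean()
        if len(pau_loci)
        else float("nan")
    )
    any_locus = truth.loci[["chrom", "start", "end"]]
    bg_bill = (
        int((~overlaps_any(bill_clusters, any_locus)).sum()) if len(bill_clusters) else 0
    )
    return {
        "bill_recovery": float(bill_found),
        "pau_recovery": float(pau_found),
        "background_bill_clusters": bg_bill,
        "n_clusters": len(df),
        "n_bill_clusters": int(len(bill_clusters)),
    }


def emit_fixtures(truth: SyntheticTruth, outdir, genotypes=GENOTYPES) -> dict:
    """Write the whole synthetic study to ``outdir`` as plain-text files.

    Produces per-replicate read BEDs for each genotype, locus/structural
    BEDs, cytosine reports, a GFF3 gene annotation, FPKM and DE tables and
    a JSON ground-truth ledger. Returns a manifest of written paths. All
    files round-trip through the package's own readers.
    """
    from .read_processing import write_reads_bed
    from .methylation import write_cx_report

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"reads": {}, "methylome": {}}
    truth.chromosomes.to_csv(out / "chromosomes.tsv", sep="\t", index=False)
    manifest["chromosomes"] = str(out / "chromosomes.tsv")

    loci_bed = out / "planted_loci.bed"
    loci = truth.loci
    pd.DataFrame(
        {
            0: loci["chrom"],
            1: loci["start"],
            2: loci["end"],
            3: loci["label"],
            4: loci["read_mass"],
            5: ".",
        }
    ).to_csv(loci_bed, sep="\t", header=False, index=False)
    manifest["loci"] = str(loci_bed)

    struct = truth.loci_of("structural")
    struct_bed = out / "structural_rna.bed"
    pd.DataFrame(
        {0: struct["chrom"], 1: struct["start"], 2: struct["end"], 3: "structural", 4: 0, 5: "."}
    ).to_csv(struct_bed, sep="\t", header=False, index=False)
    manifest["structural"] = str(struct_bed)

    for genotype in genotypes:
        paths = []
        for rs in simulate_reads(truth, genotype):
            p = out / f"reads_{genotype}_{rs.replicate}.bed"
            write_reads_bed(rs, p)
            paths.append(str(p))
        manifest["reads"][genotype] = paths
        cx = simulate_methylome(truth, genotype)
        p = out / f"cx_report_{genotype}.tsv"
        write_cx_report(cx, p)
        manifest["methylome"][genotype] = str(p)

    genes, fpkm, de = simulate_genes(truth)
    gff = out / "genes.gff3"
    write_gff3_genes(genes, gff)
    fpkm.to_csv(out / "fpkm.tsv", sep="\t", index=False)
    de.drop(columns="planted_de").to_csv(out / "de.tsv", sep="\t", index=False)
    de.to_csv(out / "de_with_truth.tsv", sep="\t", index=False)
    manifest.update(
        {
            "genes": str(gff),
            "fpkm": str(out / "fpkm.tsv"),
            "de": str(out / "de.tsv"),
        }
    )

    ledger = {
        "config": asdict(truth.config),
        "loci": truth.loci.to_dict(orient="list"),
        "chromosomes": truth.chromosomes.to_dict(orient="list"),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(ledger, fh, indent=1)
    manifest["truth"] = str(out / "truth.json")
    return manifest


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    """Minimal GFF3 (1-based closed coordinates) with gene features only."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\tsirenscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def load_truth(path) -> SyntheticTruth:
    """Read back a truth.json ledger written by :func:`emit_fixtures`."""
    with open(path) as fh:
        raw = json.load(fh)
    return SyntheticTruth(
        chromosomes=pd.DataFrame(raw["chromosomes"]),
        loci=pd.DataFrame(raw["loci"]),
        config=SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw["config"].items()
        }),
    )
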