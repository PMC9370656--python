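"""Loading and filtering of aligned small-RNA reads, and RPTM normalization.

The analysis works on uniquely mapped 24 nt reads with structural-RNA
(rRNA/tRNA/snRNA/snoRNA) mappers discarded; abundances are expressed as
reads per ten million mapped reads (RPTM). All coordinates are 0-based
half-open internally; conversions happen only at format boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._intervals import merge_frame, overlaps_any

READ_COLUMNS = ["chrom", "start", "end", "strand", "first_base", "unique", "replicate"]
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: one RPTM unit corresponds to one read in a 10-million-read library
RPTM_SCALE = 10_000_000


class NormalizationError(ValueError):
    """Raised when an abundance cannot be normalized (library size 0)."""


@dataclass
class ReadSet:
    """One aligned small-RNA library (one replicate of one sample).

    ``df`` holds one row per read with columns ``chrom, start, end, strand,
    first_base, unique, replicate``. ``library_size`` is the RPTM
    denominator; ``n_mapped`` remembers the pre-filter mapped-read count so
    the denominator basis can be switched after filtering.
    """

    df: pd.DataFrame
    sample: str = "sample"
    genotype: str = "wild_type"
    replicate: str = "rep1"
    library_size: int = 0
    n_mapped: int = 0
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in READ_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"read table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)


def rptm(count, library_size) -> float:
    """Reads per ten million mapped reads: ``count / library_size * 1e7``.

    Accepts scalars or arrays of counts. Raises :class:`NormalizationError`
    when ``library_size`` is not positive.
    """
    if library_size is None or library_size <= 0:
        raise NormalizationError(
            f"cannot normalize with library size {library_size!r}"
        )
    if np.ndim(count):
        return np.asarray(count, dtype=float) / float(library_size) * RPTM_SCALE
    return count / library_size * RPTM_SCALE


def load_reads(
    path,
    format: str = "bed",
    sample: str = "sample",
    genotype: str = "wild_type",
    replicate: str = "rep1",
) -> ReadSet:
    """Load aligned reads from a BED6(+1) file or a SAM file.

    BED records are 0-based half-open already. The BED name column may carry
    the read sequence (first base taken from it); otherwise a 7th column with
    the explicit first base is required. BED reads are assumed uniquely
    mapped (multimapper removal is an upstream aligner concern); SAM reads
    are flagged unique when the NH tag is absent or equals 1.

    Malformed lines raise ``ValueError`` naming the 1-based line number.
    """
    if format == "bed":
        df = _load_bed_reads(path)
    elif format == "sam_table":
        df = _load_sam_reads(path)
    else:
        raise ValueError(f"unknown read format: {format!r}")
    df["replicate"] = replicate
    rs = ReadSet(
        df=df[READ_COLUMNS],
        sample=sample,
        genotype=genotype,
        replicate=replicate,
        library_size=len(df),
        n_mapped=len(df),
    )
    return rs


def _load_bed_reads(path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=READ_COLUMNS)
    if raw.shape[1] < 6:
        raise ValueError(f"{path}: BED6 requires >= 6 columns, got {raw.shape[1]}")
    chrom = raw[0].astype(str)
    try:
        start = raw[1].astype(np.int64)
        end = raw[2].astype(np.int64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer coordinate ({exc})") from exc
    strand = raw[5].astype(str)
    bad = np.flatnonzero(end.to_numpy() <= start.to_numpy())
    if len(bad):
        raise ValueError(
            f"{path}: end <= start at line {bad[0] + 1} "
            f"({chrom.iloc[bad[0]]}:{start.iloc[bad[0]]}-{end.iloc[bad[0]]})"
        )
    bad = np.flatnonzero(~strand.isin(["+", "-"]).to_numpy())
    if len(bad):
        raise ValueError(f"{path}: invalid strand at line {bad[0] + 1}")
    name = raw[3].astype(str)
    seqlike = name.str.fullmatch(r"[ACGTacgt][ACGTNacgtn]*")
    first = name.str[0].str.upper().where(seqlike, other=pd.NA)
    if raw.shape[1] >= 7:
        explicit = raw[6].astype(str).str.upper()
        first = explicit.where(explicit.isin(_BASES), first)
    missing = np.flatnonzero(~first.isin(_BASES).to_numpy())
    if len(missing):
        raise ValueError(
            f"{path}: no first base derivable at line {missing[0] + 1}; "
            "name must be the read sequence or a 7th first-base column given"
        )
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": strand,
            "first_base": first,
            "unique": True,
        }
    )


def _load_sam_reads(path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            seq = aln.query_sequence or ""
            if aln.is_reverse:
                first = seq[-1:].translate(_COMPLEMENT) if seq else ""
            else:
                first = seq[:1]
            unique = (not aln.has_tag("NH")) or aln.get_tag("NH") == 1
            rows.append(
                (
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    first.upper() or "N",
                    unique,
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "first_base", "unique"]
    )


def filter_reads(
    reads: ReadSet,
    keep_length: int = 24,
    structural: pd.DataFrame | None = None,
) -> ReadSet:
    """Keep uniquely mapped reads of ``keep_length`` nt not touching structural RNAs.

    A read is discarded when it overlaps any structural interval by >= 1 bp.
    Per-criterion removal counts are recorded in ``filter_log``. The library
    size is reset to the retained count (the default RPTM basis); use
    :func:`set_library_size` to switch to the pre-filter mapped total.
    """
    df = reads.df
    n0 = len(df)
    uniq = df["unique"].to_numpy(bool)
    length_ok = (df["end"] - df["start"]).to_numpy() == keep_length
    keep = uniq & length_ok
    n_nonuniq = int(n0 - uniq.sum())
    n_badlen = int((uniq & ~length_ok).sum())
    n_struct = 0
    if structural is not None and len(structural) and keep.any():
        struct = merge_frame(structural[["chrom", "start", "end"]], gap=-1)
        sub = df.loc[keep, ["chrom", "start", "end"]]
        hit = overlaps_any(sub, struct)
        n_struct = int(hit.sum())
        keep = keep.copy()
        keep[np.flatnonzero(keep)[hit]] = False
    out = df.loc[keep].reset_index(drop=True)
    log = dict(reads.filter_log)
    log.update(
        {
            "input": n0,
            "removed_non_unique": n_nonuniq,
            "removed_length": n_badlen,
            "removed_structural": n_struct,
            "retained": len(out),
        }
    )
    return replace(
        reads, df=out, library_size=len(out), filter_log=log
    )


def set_library_size(
    reads: ReadSet, basis: str = "retained", override: int | None = None
) -> ReadSet:
    """Fix the RPTM denominator.

    ``basis='retained'`` uses the current (filtered) read count;
    ``basis='all_mapped'`` uses the pre-filter mapped total. ``override``
    wins over either when given.
    """
    if override is not None:
        if override <= 0:
            raise ValueError(f"library-size override must be positive, got {override}")
        size = int(override)
    elif basis == "retained":
        size = len(reads.df)
    elif basis == "all_mapped":
        size = int(reads.n_mapped)
    else:
        raise ValueError(f"unknown library-size basis: {basis!r}")
    log = dict(reads.filter_log)
    log["library_size_basis"] = "override" if override is not None else basis
    return replace(reads, library_size=size, filter_log=log)


def combined_library_size(readsets) -> int:
    """Pooled RPTM denominator: sum of the replicates' library sizes."""
    return int(sum(rs.library_size for rs in readsets))


def write_reads_bed(reads: ReadSet, path) -> None:
    """Write a ReadSet as BED6+1 (7th column = first base); round-trips losslessly."""
    df = reads.df
    out = pd.DataFrame(
        {
            0: df["chrom"],
            1: df["start"],
            2: df["end"],
            3: [f"read{i}" for i in range(len(df))],
            4: 0,
            5: df["strand"],
            6: df["first_base"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
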