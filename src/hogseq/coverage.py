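"""Read deduplication, strand-aware extension, pileup and TRPK normalization.

The quantification path is: dedup PCR artifacts, extend reads to the fragment
size, count fragments per region (promoter / ORF) by their midpoints, convert
to reads per kilobase (RPK), and scale samples onto a common baseline with a
trimmed-mean-of-M-values (TMM) factor, giving TRPK.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild, GeneModel, ReadSet, SampleTag, promoter_of

__all__ = [
    "CoverageTrack",
    "RegionCountTable",
    "dedup_reads",
    "extend_reads",
    "pileup",
    "to_rpm",
    "gene_regions",
    "count_regions",
    "tmm_factor",
    "trpk",
]


@dataclass
class CoverageTrack:
    """Per-base coverage vectors, raw or reads-per-million normalized."""

    data: dict[str, np.ndarray]
    n_reads: int
    norm: str = "raw"  # {"raw", "rpm"}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


@dataclass
class RegionCountTable:
    """Per-region raw counts with RPK and (after TMM scaling) TRPK columns.

    ``df`` columns: region_id, chrom, start, end, kind, length, count, rpk and
    optionally trpk.  ``total_reads`` is the sample's read count (for RPM-style
    conversions); ``tmm`` the applied scaling factor.
    """

    df: pd.DataFrame
    sample: SampleTag | None = None
    total_reads: int | None = None
    tmm: float | None = None

    def __len__(self) -> int:
        return len(self.df)

    def values(self, column: str = "rpk") -> np.ndarray:
        return self.df[column].to_numpy(dtype=float)

    @property
    def region_ids(self) -> pd.Series:
        return self.df["region_id"]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def dedup_reads(reads: ReadSet, max_per_position: int = 10) -> ReadSet:
    """Cap identical reads to reduce PCR over-amplification artifacts.

    At most ``max_per_position`` reads are kept per (chrom, start, strand)
    key; retention is first-seen in input order, so the result is
    deterministic and idempotent.
    """
    if max_per_position < 1:
        raise ValueError("max_per_position must be >= 1")
    df = reads.df
    rank = df.groupby(["chrom", "start", "strand"], sort=False, observed=True).cumcount()
    kept = df.loc[rank < max_per_position]
    return ReadSet(kept.copy(), sample=reads.sample, genome=reads.genome)


def extend_reads(
    reads: ReadSet,
    target_length: int = 250,
    genome: GenomeBuild | None = None,
) -> ReadSet:
    """Extend each read 3'-ward on its own strand to ``target_length`` bp.

    The 5' end is the anchor: plus-strand reads keep their start, minus-strand
    reads keep their end.  Unstranded reads are treated as plus.  Intervals are
    clipped at chromosome edges (or at zero when no genome is supplied).
    """
    df = reads.df
    lengths = df["end"].to_numpy() - df["start"].to_numpy()
    if (lengths > target_length).any():
        raise ValueError(
            f"target_length {target_length} shorter than longest read ({lengths.max()})"
        )
    start = df["start"].to_numpy(dtype=np.int64).copy()
    end = df["end"].to_numpy(dtype=np.int64).copy()
    minus = (df["strand"] == "-").to_numpy()
    end[~minus] = start[~minus] + target_length
    start[minus] = end[minus] - target_length
    np.clip(start, 0, None, out=start)
    genome = genome or reads.genome
    if genome is not None:
        chrom_len = df["chrom"].map(genome.lengths).to_numpy(dtype=np.int64)
        np.minimum(end, chrom_len, out=end)
    out = df.copy()
    out["start"] = start
    out["end"] = end
    return ReadSet(out, sample=reads.sample, genome=genome)


def pileup(reads: ReadSet, genome: GenomeBuild) -> CoverageTrack:
    """Per-base coverage: track[p] = number of intervals covering p.

    Mass is conserved: the sum of the track equals the sum of interval
    lengths.
    """
    data = {c: np.zeros(length, dtype=np.float64) for c, length in genome.lengths.items()}
    for chrom, sub in reads.df.groupby("chrom", sort=False, observed=True):
        diff = np.zeros(genome.length_of(str(chrom)) + 1, dtype=np.float64)
        np.add.at(diff, sub["start"].to_numpy(), 1.0)
        np.add.at(diff, sub["end"].to_numpy(), -1.0)
        data[str(chrom)] = np.cumsum(diff[:-1])
    return CoverageTrack(data, n_reads=len(reads), norm="raw")


def to_rpm(track: CoverageTrack, total_reads: int | None = None) -> CoverageTrack:
    """Convert a raw coverage track to reads per million mapped reads."""
    n = total_reads if total_reads is not None else track.n_reads
    if n <= 0:
        raise ValueError("total read count must be positive")
    scale = 1e6 / n
    return CoverageTrack(
        {c: v * scale for c, v in track.data.items()}, n_reads=track.n_reads, norm="rpm"
    )


def gene_regions(
    genes: list[GeneModel],
    genome: GenomeBuild | None = None,
    kinds: tuple[str, ...] = ("promoter", "orf"),
) -> pd.DataFrame:
    """Region table (promoter and/or ORF per gene) for counting.

    Region ids are ``<gene_id>:<kind>``.
    """
    rows = []
    for g in genes:
        if "promoter" in kinds:
            p = promoter_of(g, genome)
            rows.append((f"{g.gene_id}:promoter", g.gene_id, "promoter", p.chrom, p.start, p.end))
        if "orf" in kinds:
            rows.append((f"{g.gene_id}:orf", g.gene_id, "orf", g.chrom, g.orf.start, g.orf.end))
    return pd.DataFrame(rows, columns=["region_id", "gene_id", "kind", "chrom", "start", "end"])


def count_regions(reads: ReadSet, regions: pd.DataFrame) -> RegionCountTable:
    """Count fragments per region by midpoint and derive RPK.

    A fragment is assigned to every region its midpoint ``(start+end)//2``
    falls in (half-open), an unambiguous single assignment for disjoint
    regions.  ``regions`` needs columns region_id, chrom, start, end.
    """
    lengths = regions["end"].to_numpy() - regions["start"].to_numpy()
    if (lengths <= 0).any():
        bad = regions.loc[lengths <= 0, "region_id"].iloc[0]
        raise ValueError(f"zero-length region {bad}")
    mids_by_chrom = {
        str(chrom): np.sort((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        for chrom, sub in reads.df.groupby("chrom", sort=False, observed=True)
    }
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, (chrom, start, end) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        mids = mids_by_chrom.get(str(chrom))
        if mids is None:
            continue
        counts[i] = np.searchsorted(mids, end, side="left") - np.searchsorted(
            mids, start, side="left"
        )
    df = regions.copy().reset_index(drop=True)
    df["length"] = lengths
    df["count"] = counts
    df["rpk"] = counts / (lengths / 1000.0)
    return RegionCountTable(df, sample=reads.sample, total_reads=len(reads))


def tmm_factor(
    sample_rpk: np.ndarray | RegionCountTable,
    reference_rpk: np.ndarray | RegionCountTable,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_regions: int = 10,
) -> float:
    """Trimmed-mean-of-M-values scaling factor of a sample vs a reference.

    Regions with zero signal in either sample are excluded; the most extreme
    ``trim_m`` fraction by |M - median(M)| and then ``trim_a`` fraction by
    |A - median(A)| are trimmed; the factor is ``2**mean(M)`` over the
    survivors.  M = log2(sample/reference), A = mean of the log2 intensities.
    A pure scale offset between the tables is recovered exactly.
    """
    s = sample_rpk.values("rpk") if isinstance(sample_rpk, RegionCountTable) else np.asarray(sample_rpk, dtype=float)
    r = reference_rpk.values("rpk") if isinstance(reference_rpk, RegionCountTable) else np.asarray(reference_rpk, dtype=float)
    if s.shape != r.shape:
        raise ValueError("sample and reference must cover identical regions")
    ok = (s > 0) & (r > 0)
    s, r = s[ok], r[ok]
    if s.size < min_regions:
        raise ValueError(
            f"only {s.size} regions with positive signal in both samples (need {min_regions})"
        )
    m = np.log2(s) - np.log2(r)
    a = 0.5 * (np.log2(s) + np.log2(r))
    n = m.size
    keep_m = max(int(math.ceil((1.0 - trim_m) * n)), 2)
    order = np.argsort(np.abs(m - np.median(m)), kind="stable")[:keep_m]
    m, a = m[order], a[order]
    keep_a = max(int(math.ceil((1.0 - trim_a) * m.size)), 2)
    order = np.argsort(np.abs(a - np.median(a)), kind="stable")[:keep_a]
    factor = float(2.0 ** np.mean(m[order]))
    if not factor > 0:
        raise ValueError("non-positive TMM factor")
    return factor


def trpk(table: RegionCountTable, factor: float) -> RegionCountTable:
    """TMM-normalized RPK: divide the sample's RPK by its scaling factor."""
    if factor <= 0:
        raise ValueError("TMM factor must be positive")
    df = table.df.copy()
    df["trpk"] = df["rpk"] / factor
    return RegionCountTable(df, sample=table.sample, total_reads=table.total_reads, tmm=factor)
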