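"""Core genomic domain types and coordinate conventions.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; readers for 1-based tables convert at the boundary.  Strand is one of
``'+'``, ``'-'`` or ``'.'`` (unstranded).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROMOTER_LENGTH = 500  # bp upstream of the TSS defining the promoter window

__all__ = [
    "GenomeBuild",
    "GenomicInterval",
    "GeneModel",
    "SampleTag",
    "AlignedRead",
    "ReadSet",
    "ExpressionRecord",
    "promoter_of",
    "tss_relative",
]


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome names and lengths of a (toy) genome assembly."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(set(self.lengths)):
            raise ValueError("chromosome names must be unique")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate_against(self, genome: GenomeBuild) -> None:
        if self.end > genome.length_of(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:[{self.start},{self.end}) extends beyond "
                f"chromosome end {genome.length_of(self.chrom)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene: its ORF interval, strand and annotated TSS.

    The TSS is an input (annotation-supplied), never inferred from the ORF.  It
    must lie on the gene's 5' side: ``tss <= orf.start`` for ``+`` genes and
    ``tss >= orf.end - 1`` for ``-`` genes.
    """

    gene_id: str
    orf: GenomicInterval
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss <= self.orf.start:
            raise ValueError(f"gene {self.gene_id}: TSS {self.tss} downstream of + ORF start")
        if self.strand == "-" and not self.tss >= self.orf.end - 1:
            raise ValueError(f"gene {self.gene_id}: TSS {self.tss} downstream of - ORF end")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")

    @property
    def chrom(self) -> str:
        return self.orf.chrom


def promoter_of(
    gene: GeneModel,
    genome: GenomeBuild | None = None,
    length: int = PROMOTER_LENGTH,
) -> GenomicInterval:
    """Promoter window: `length` bp immediately upstream of the TSS.

    ``+`` strand: ``[tss - length, tss)``; ``-`` strand: ``[tss + 1, tss + 1 +
    length)``.  Clipped at chromosome edges when a genome is supplied (and at
    zero always), so edge genes never raise.
    """
    if gene.strand == "+":
        start, end = gene.tss - length, gene.tss
    else:
        start, end = gene.tss + 1, gene.tss + 1 + length
    start = max(start, 0)
    if genome is not None:
        end = min(end, genome.length_of(gene.chrom))
    if start >= end:
        # fully clipped away (TSS at position 0 of a + gene); degenerate 1-bp window
        start, end = max(end - 1, 0), max(end, 1)
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def tss_relative(position: int, gene: GeneModel) -> int:
    """Signed TSS-relative offset of a genomic position (0 at the TSS base).

    Positive offsets point into the gene body on the gene's own strand.
    """
    if gene.strand == "+":
        return position - gene.tss
    return gene.tss - position


@dataclass(frozen=True)
class SampleTag:
    """Identifies a sequencing sample: assayed factor x strain x condition."""

    factor: str
    strain: str
    condition: str

    @property
    def name(self) -> str:
        return f"{self.factor}_{self.strain}_{self.condition}"


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely mapped single-end read (multi-mappers excluded upstream)."""

    interval: GenomicInterval
    name: str = "."
    sample: SampleTag | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class ReadSet(Sequence):
    """A column-oriented collection of aligned reads from one sample.

    Stores chrom/start/end/strand as arrays for vectorized downstream
    operations while behaving like a sequence of :class:`AlignedRead`.
    Original input order is preserved.
    """

    df: pd.DataFrame  # columns: chrom, start, end, strand [, name, score]
    sample: SampleTag | None = None
    genome: GenomeBuild | None = field(default=None, repr=False)

    REQUIRED = ("chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"ReadSet frame missing column {col!r}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        chrom: np.ndarray | list,
        start: np.ndarray,
        end: np.ndarray,
        strand: np.ndarray,
        sample: SampleTag | None = None,
        genome: GenomeBuild | None = None,
        name: np.ndarray | None = None,
    ) -> "ReadSet":
        data = {
            "chrom": pd.Series(chrom, dtype="object"),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "strand": pd.Series(strand, dtype="object"),
        }
        if name is not None:
            data["name"] = pd.Series(name, dtype="object")
        return cls(pd.DataFrame(data), sample=sample, genome=genome)

    @classmethod
    def from_reads(
        cls,
        reads: Sequence[AlignedRead],
        sample: SampleTag | None = None,
        genome: GenomeBuild | None = None,
    ) -> "ReadSet":
        return cls.from_arrays(
            [r.interval.chrom for r in reads],
            np.array([r.interval.start for r in reads], dtype=np.int64),
            np.array([r.interval.end for r in reads], dtype=np.int64),
            [r.interval.strand for r in reads],
            sample=sample,
            genome=genome,
            name=[r.name for r in reads],
        )

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return ReadSet(self.df.iloc[i], sample=self.sample, genome=self.genome)
        row = self.df.iloc[i]
        name = row["name"] if "name" in self.df.columns else "."
        return AlignedRead(
            GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), row["strand"]),
            name=name,
            sample=self.sample,
        )

    @property
    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2

    def validate_against(self, genome: GenomeBuild) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False, observed=True):
            clen = genome.length_of(str(chrom))
            if (sub["end"].to_numpy() > clen).any() or (sub["start"].to_numpy() < 0).any():
                bad = sub.index[(sub["end"] > clen) | (sub["start"] < 0)][0]
                raise ValueError(
                    f"read #{bad} on {chrom} outside chromosome bounds (length {clen})"
                )


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene linear fold change upon stress in wt and hog1 strains."""

    gene_id: str
    fc_wt: float
    fc_hog1: float

    def __post_init__(self) -> None:
        if not (self.fc_wt > 0 and self.fc_hog1 > 0):
            raise ValueError(f"gene {self.gene_id}: fold changes must be positive")
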