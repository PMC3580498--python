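"""Readers and writers for the package's plain-text interchange formats.

BED6 (or BED3 + strand in column 6) for reads; tab-separated tables with a
header row for gene models and expression fold changes.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    GenomeBuild,
    GenomicInterval,
    GeneModel,
    ReadSet,
    SampleTag,
)

__all__ = [
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_expression_table",
    "write_expression_table",
]


class BedParseError(ValueError):
    """A malformed BED line; the message names the offending line number."""


def read_bed(
    path: str | os.PathLike,
    genome: GenomeBuild | None = None,
    sample: SampleTag | None = None,
) -> ReadSet:
    """Parse a BED file into a :class:`ReadSet`, preserving line order.

    Accepts BED6 lines (chrom start end name score strand) or BED3 lines with
    the strand in the fourth column; a missing strand field defaults to '.'.
    Intervals are validated (start < end, and against ``genome`` if given).
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    names: list[str] = []
    scores: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path.name}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path.name}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from None
            if not 0 <= start < end:
                raise BedParseError(
                    f"{path.name}:{lineno}: invalid interval [{start},{end}) (need 0 <= start < end)"
                )
            if len(fields) >= 6:
                name, score, strand = fields[3], fields[4], fields[5]
            elif len(fields) == 4:
                name, score, strand = ".", "0", fields[3]
            else:
                name, score, strand = ".", "0", "."
            if strand not in ("+", "-", "."):
                raise BedParseError(f"{path.name}:{lineno}: invalid strand {strand!r}")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            strands.append(strand)
            names.append(name)
            scores.append(score)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype="object"),
            "start": np.array(starts, dtype=np.int64),
            "end": np.array(ends, dtype=np.int64),
            "strand": pd.Series(strands, dtype="object"),
            "name": pd.Series(names, dtype="object"),
            "score": pd.Series(scores, dtype="object"),
        }
    )
    reads = ReadSet(df, sample=sample, genome=genome)
    if genome is not None:
        reads.validate_against(genome)
    return reads


def write_bed(reads: ReadSet, path: str | os.PathLike) -> None:
    """Write a :class:`ReadSet` as canonical BED6 (round-trips byte-wise)."""
    df = reads.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["name"] if "name" in df.columns else ".",
            "score": df["score"] if "score" in df.columns else "0",
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "orf_start", "orf_end", "tss"]


def read_gene_table(
    path: str | os.PathLike,
    genome: GenomeBuild | None = None,
    one_based: bool = False,
) -> list[GeneModel]:
    """Read a tab-separated gene-model table (header row required).

    Columns: gene_id, chrom, strand, orf_start, orf_end, tss.  With
    ``one_based=True`` the table is interpreted as 1-based closed coordinates
    (SGD-style) and converted to the internal 0-based half-open convention:
    start and tss are decremented, end is kept (inclusive 1-based end equals
    exclusive 0-based end).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} missing columns: {missing}")
    genes = []
    shift = 1 if one_based else 0
    for row in df.itertuples(index=False):
        orf = GenomicInterval(
            str(row.chrom), int(row.orf_start) - shift, int(row.orf_end), str(row.strand)
        )
        if genome is not None:
            orf.validate_against(genome)
        genes.append(
            GeneModel(str(row.gene_id), orf, int(row.tss) - shift, str(row.strand))
        )
    return genes


def write_gene_table(genes: list[GeneModel], path: str | os.PathLike) -> None:
    rows = [
        (g.gene_id, g.chrom, g.strand, g.orf.start, g.orf.end, g.tss) for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-separated expression table: gene_id, fc_wt, fc_hog1.

    Fold changes are linear (stressed / unstressed) and must be positive.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "fc_wt", "fc_hog1"):
        if col not in df.columns:
            raise ValueError(f"expression table {path} missing column {col!r}")
    if (df["fc_wt"] <= 0).any() or (df["fc_hog1"] <= 0).any():
        bad = df.loc[(df["fc_wt"] <= 0) | (df["fc_hog1"] <= 0), "gene_id"].iloc[0]
        raise ValueError(f"non-positive fold change for gene {bad}")
    return df[["gene_id", "fc_wt", "fc_hog1"]].copy()


def write_expression_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["gene_id", "fc_wt", "fc_hog1"]].to_csv(path, sep="\t", index=False)
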