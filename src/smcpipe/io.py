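"""Readers and writers for BED, bedGraph and the tabular gene/expression files.

BED is treated 0-based half-open throughout. Malformed lines raise
:class:`FormatError` carrying the 1-based line number. All round trips on
canonical (sorted, tab-separated) files are lossless.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GeneModel, GenomicInterval


class FormatError(ValueError):
    """A syntactically invalid line in a genomic text file."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------- BED


def read_bed(
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals.

    With ``chrom_sizes`` given, reading is strict: unknown chromosomes and
    out-of-bounds coordinates are errors. Empty files yield an empty list.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(path, lineno, "fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(path, lineno, f"non-integer coordinate: {exc}")
            strand = fields[5] if len(fields) >= 6 else "."
            if start < 0 or start >= end:
                raise FormatError(
                    path, lineno, f"invalid coordinates {start}-{end}"
                )
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise FormatError(path, lineno, f"unknown chrom {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise FormatError(
                        path, lineno, f"end {end} beyond chrom size"
                    )
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc))
    return out


def write_bed(
    path: str | os.PathLike,
    intervals: Iterable[GenomicInterval],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED, sorted by (chrom, start). BED6 when names/scores given."""
    items = list(intervals)
    order = sorted(
        range(len(items)), key=lambda i: (items[i].chrom, items[i].start, items[i].end)
    )
    with open(path, "w") as fh:
        for i in order:
            iv = items[i]
            if names is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
                )


# ------------------------------------------------------------ bedGraph


def read_bedgraph(
    path: str | os.PathLike,
) -> list[tuple[GenomicInterval, float]]:
    """Read bedGraph as (interval, value) pairs."""
    out: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(path, lineno, "bedGraph needs 4 fields")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                value = float(fields[3])
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc))
            out.append((iv, value))
    return out


def write_bedgraph(
    path: str | os.PathLike,
    records: Iterable[tuple[GenomicInterval, float]],
) -> None:
    records = sorted(records, key=lambda r: (r[0].chrom, r[0].start))
    with open(path, "w") as fh:
        for iv, value in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


# ------------------------------------------------------------ gene TSV

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "start", "end"]


def read_gene_table(path: str | os.PathLike) -> list[GeneModel]:
    """Read the gene-model TSV (gene_id, chrom, strand, tss, start, end).

    ``tss`` is stored 0-based, like every other coordinate here.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(path, 1, f"missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                span=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            )
        )
    return genes


def write_gene_table(path: str | os.PathLike, genes: Iterable[GeneModel]) -> None:
    rows = [
        (g.gene_id, g.chrom, g.strand, g.tss, g.span.start, g.span.end)
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id))
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------ expression TSV


def read_counts_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample count matrix; first column is gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(path, 1, "negative counts")
    return df


def write_counts_table(path: str | os.PathLike, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")
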