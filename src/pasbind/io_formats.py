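"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: every genomic interval in this package is 0-based,
half-open ([start, end)). Converters to or from 1-based systems are the only
places offsets may change.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SelexReadSet",
    "GenomicInterval",
    "MethylationCall",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "read_methylation_table",
    "write_methylation_table",
    "read_fasta_dict",
    "write_fasta",
    "read_affinity_table",
]


@dataclass
class SelexReadSet:
    """Reads from one SELEX selection round.

    round_index 0 is the unselected input library; rounds >= 1 are selected.
    Reads containing N are retained here and excluded later at k-mer counting
    (filtering is an analysis decision, not an I/O one).
    """

    round_index: int
    reads: list[str]
    design_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.round_index < 0:
            raise ValueError("round_index must be >= 0")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def n_with_ambiguous(self) -> int:
        """Number of reads flagged as containing N."""
        return sum("N" in r.upper() for r in self.reads)

    def read_length(self) -> int:
        if not self.reads:
            raise ValueError("empty read set has no read length")
        lengths = {len(r) for r in self.reads}
        if len(lengths) != 1:
            raise ValueError(f"reads have mixed lengths: {sorted(lengths)}")
        return lengths.pop()


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional peak intensity."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.score is not None and self.score < 0:
            raise ValueError("interval score must be >= 0 when present")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MethylationCall:
    """Per-site cytosine methylation counts.

    percent methylation is defined only when coverage > 0.
    """

    chrom: str
    position: int  # 0-based
    strand: str = "+"
    context: str = "CpG"
    n_methylated: int = 0
    n_unmethylated: int = 0

    def __post_init__(self) -> None:
        if self.n_methylated < 0 or self.n_unmethylated < 0:
            raise ValueError("methylation counts must be non-negative")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def coverage(self) -> int:
        return self.n_methylated + self.n_unmethylated

    @property
    def percent(self) -> Optional[float]:
        if self.coverage == 0:
            return None
        return 100.0 * self.n_methylated / self.coverage


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, quality_min: Optional[int] = None,
               round_index: int = 0, design_ref: Optional[str] = None) -> SelexReadSet:
    """Read a FASTQ file (plain or gzip) into a SelexReadSet.

    quality_min, when given, drops reads whose minimum per-base Phred score is
    below the threshold. Reads with N are retained (flagged via
    SelexReadSet.n_with_ambiguous). A malformed record raises with the record
    number.
    """
    reads: list[str] = []
    record_no = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                record_no += 1
                if quality_min is not None:
                    quals = rec.letter_annotations.get("phred_quality", [])
                    if quals and min(quals) < quality_min:
                        continue
                reads.append(str(rec.seq).upper())
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record #{record_no + 1} in {path}: {exc}"
            ) from exc
    return SelexReadSet(round_index=round_index, reads=reads, design_ref=design_ref)


def write_fastq(path, readset: SelexReadSet) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with _open_text(path, "wt") as fh:
        for i, seq in enumerate(readset.reads):
            fh.write(f"@r{readset.round_index}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak into intervals.

    Dialect is auto-detected by column count: a 10-column file is treated as
    narrowPeak and signalValue (column 7) becomes the score; otherwise BED
    column 5 is used when present. Lines with start >= end are rejected with a
    warning; non-integer coordinates are a hard error.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from exc
            if start >= end:
                warnings.warn(f"{path}:{lineno}: start >= end, line skipped")
                continue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) >= 10:  # narrowPeak: signalValue preferred
                try:
                    score = float(fields[6])
                except ValueError:
                    score = None
            if score is None and len(fields) > 4 and fields[4] not in {".", ""}:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            intervals.append(GenomicInterval(chrom, start, end, score=score, name=name))
    return intervals


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    """Write intervals as BED6 (score column carries peak intensity)."""
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


_METH_COLUMNS = ["chrom", "position", "strand", "context", "n_methylated", "n_unmethylated"]


def read_methylation_table(path, dialect: str = "generic",
                           genome: Optional[dict] = None) -> list[MethylationCall]:
    """Read per-site methylation counts from tab-separated text.

    dialect="generic": columns chrom, position (0-based), strand, context,
    n_methylated, n_unmethylated (header optional).
    dialect="bedgraph_counts": MethylDackel-style bedGraph with columns
    chrom, start, end, percent, n_methylated, n_unmethylated (0-based start).

    When `genome` (mapping chrom -> sequence) is supplied and the dialect has
    no context column, context is assigned from the genome: CpG when the site
    and its 3' neighbour (strand-aware) form CG, else CpH.
    """
    if dialect not in {"generic", "bedgraph_counts"}:
        raise ValueError(f"unknown methylation dialect {dialect!r}")
    calls: list[MethylationCall] = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if dialect == "generic":
        first = df.iloc[0, 0] if len(df) else ""
        if isinstance(first, str) and first.lower() in {"chrom", "chr", "chromosome"}:
            df = df.iloc[1:].reset_index(drop=True)
        df = df.iloc[:, :6]
        df.columns = _METH_COLUMNS[: df.shape[1]]
        for row in df.itertuples(index=False):
            m, u = int(row.n_methylated), int(row.n_unmethylated)
            if m < 0 or u < 0:
                raise ValueError("negative methylation counts")
            calls.append(MethylationCall(
                chrom=row.chrom, position=int(row.position),
                strand=getattr(row, "strand", "+"),
                context=getattr(row, "context", "CpG"),
                n_methylated=m, n_unmethylated=u))
    else:
        df = df.iloc[:, :6]
        df.columns = ["chrom", "start", "end", "percent", "n_methylated", "n_unmethylated"]
        for row in df.itertuples(index=False):
            m, u = int(row.n_methylated), int(row.n_unmethylated)
            if m < 0 or u < 0:
                raise ValueError("negative methylation counts")
            pos = int(row.start)
            context = "CpG"
            strand = "+"
            if genome is not None and row.chrom in genome:
                seq = genome[row.chrom]
                if pos + 1 < len(seq) and seq[pos:pos + 2].upper() == "CG":
                    context, strand = "CpG", "+"
                elif pos >= 1 and seq[pos - 1:pos + 1].upper() == "CG":
                    context, strand = "CpG", "-"
                else:
                    context = "CpH"
            calls.append(MethylationCall(
                chrom=row.chrom, position=pos, strand=strand,
                context=context, n_methylated=m, n_unmethylated=u))
    return calls


def write_methylation_table(path, calls: Sequence[MethylationCall]) -> None:
    """Write calls in the generic 6-column dialect (exact round-trip)."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_METH_COLUMNS) + "\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.position}\t{c.strand}\t{c.context}"
                     f"\t{c.n_methylated}\t{c.n_unmethylated}\n")


def read_fasta_dict(path) -> dict[str, str]:
    """Load a FASTA file fully into memory as {chrom: sequence}."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, genome: dict[str, str], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_affinity_table(path) -> pd.DataFrame:
    """Read a k-mer affinity table TSV (kmer, obs, expected, enrichment, affinity)."""
    df = pd.read_csv(path, sep="\t")
    expected_cols = {"kmer", "obs", "expected", "enrichment", "affinity"}
    missing = expected_cols - set(df.columns)
    if missing:
        raise ValueError(f"affinity table missing columns: {sorted(missing)}")
    return df
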