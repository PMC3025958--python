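"""Readers and writers for the plain-text genomic formats the pipeline touches.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
Any 1-based dialect must be converted at the boundary before objects of this
module are constructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ChromSizes",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic span: the atom of all region arithmetic.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start coordinate.
    end : int
        Exclusive end coordinate; ``end - start`` is the length in bp.
    id : str, optional
        Record identifier (BED name column).
    score : float, optional
        BED score column.
    tag_count : int, optional
        Number of sequence tags supporting the site; used by the
        tag-density filter (density = tag_count / length).
    """

    chrom: str
    start: int
    end: int
    id: str | None = None
    score: float | None = None
    tag_count: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.tag_count is not None and self.tag_count < 0:
            raise ValueError("tag_count must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A transcription unit with exon structure.

    ``tss`` is strand-aware: ``tx_start`` on the + strand and
    ``tx_end - 1`` on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError(
                f"invalid TU span {self.tx_start}-{self.tx_end} for {self.gene_id}"
            )
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon ({s},{e}) in {self.gene_id}")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(
                    f"exon ({s},{e}) outside TU of {self.gene_id}"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"exons overlap or are unsorted in {self.gene_id}"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, id=self.gene_id)


class ChromSizes(dict):
    """Mapping of chromosome name to length in bp; lengths must be positive."""

    def __setitem__(self, key: str, value: int) -> None:
        if int(value) <= 0:
            raise ValueError(f"chromosome length must be > 0, got {value} for {key}")
        super().__setitem__(key, int(value))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "ChromSizes":
        sizes = cls()
        for name, length in mapping.items():
            sizes[name] = length
        return sizes


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping headers/comments."""
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            yield lineno, line


def read_bed(path: str | Path, score_is_tag_count: bool = False) -> list[GenomicInterval]:
    """Read a BED3+ file into a list of :class:`GenomicInterval`.

    Track, browser, comment, and blank lines are skipped.  Column 4 (name)
    and column 5 (score) populate ``id`` and ``score`` when present.  With
    ``score_is_tag_count=True`` the score column is interpreted as the
    integer tag count of the site.
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}, line {lineno}: expected >=3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(
                f"{path}, line {lineno}: non-integer coordinates"
            ) from exc
        if start >= end:
            raise ValueError(
                f"{path}, line {lineno}: start {start} >= end {end}"
            )
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        tag_count = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: bad score") from exc
            if score_is_tag_count:
                tag_count = int(round(score))
        intervals.append(
            GenomicInterval(chrom, start, end, id=name, score=score, tag_count=tag_count)
        )
    logger.info("read_bed: %d records from %s", len(intervals), path)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, sorted by (chrom, start, end).

    ``tag_count`` (when set) populates the score column, otherwise
    ``score``; round-trips through :func:`read_bed` losslessly for
    chrom/start/end/id.
    """
    records = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as handle:
        for iv in records:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            score_val = iv.tag_count if iv.tag_count is not None else iv.score
            if iv.id is not None or score_val is not None:
                fields.append(iv.id if iv.id is not None else ".")
            if score_val is not None:
                fields.append(f"{score_val:g}")
            handle.write("\t".join(fields) + "\n")
    logger.info("write_bed: %d records to %s", len(records), path)


def _gene_from_bed12(fields: Sequence[str], where: str) -> GeneModel:
    chrom = fields[0]
    tx_start, tx_end = int(fields[1]), int(fields[2])
    gene_id = fields[3]
    strand = fields[5]
    block_count = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != block_count or len(starts) != block_count:
        raise ValueError(f"{where}: block count mismatch")
    exons = tuple(
        (tx_start + off, tx_start + off + size) for off, size in zip(starts, sizes)
    )
    return GeneModel(gene_id, chrom, strand, tx_start, tx_end, exons)


def _gene_from_table(fields: Sequence[str], where: str) -> GeneModel:
    # gene_id chrom strand tx_start tx_end exon_starts exon_ends
    gene_id, chrom, strand = fields[0], fields[1], fields[2]
    tx_start, tx_end = int(fields[3]), int(fields[4])
    exons: tuple[tuple[int, int], ...] = ()
    if len(fields) >= 7 and fields[5] and fields[6]:
        starts = [int(x) for x in fields[5].rstrip(",").split(",")]
        ends = [int(x) for x in fields[6].rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise ValueError(f"{where}: exon start/end count mismatch")
        exons = tuple(zip(starts, ends))
    return GeneModel(gene_id, chrom, strand, tx_start, tx_end, exons)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 or a simple tab table.

    A 12-column line is parsed as BED12 (blocks become exons).  Otherwise
    the expected columns are ``gene_id chrom strand tx_start tx_end
    [exon_starts exon_ends]`` with comma-separated exon coordinate lists.
    """
    genes: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        where = f"{path}, line {lineno}"
        try:
            if len(fields) >= 12 and fields[5] in ("+", "-"):
                genes.append(_gene_from_bed12(fields, where))
            elif len(fields) >= 5:
                genes.append(_gene_from_table(fields, where))
            else:
                raise ValueError("expected BED12 or >=5 columns")
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
    logger.info("read_gene_table: %d genes from %s", len(genes), path)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models in the simple tab-table dialect of read_gene_table."""
    with open(path, "w") as handle:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            handle.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                f"\t{starts}\t{ends}\n"
            )


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column chromosome-size table (name, length)."""
    sizes = ChromSizes()
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}, line {lineno}: expected 2 columns")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, length in sizes.items():
            handle.write(f"{name}\t{length}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA file fully into memory as {name: sequence}.

    For indexed random access to large genomes use :mod:`pyfaidx` directly;
    this helper serves the synthetic fixtures and site-sequence files.
    """
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.upper())
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def validate_against_sizes(
    intervals: Iterable[GenomicInterval], sizes: Mapping[str, int]
) -> None:
    """Raise if any interval extends past its declared chromosome length."""
    for iv in intervals:
        if iv.chrom not in sizes:
            raise ValueError(f"chromosome {iv.chrom} absent from size table")
        if iv.end > sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {sizes[iv.chrom]}"
            )
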