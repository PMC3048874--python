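"""Coordinate conventions, interval algebra and file I/O shared by every stage.

All internal coordinates are 0-based half-open (BED native); 1-based
coordinates appear only at display boundaries.  A sequencing *tag* is the
uniquely mapped 5' position of a read plus its strand: for ``+`` BED records
the 5' position is the record start, for ``-`` records it is ``end - 1``
(BED ends are exclusive).

Supported formats:

* BED6 for tags and peaks,
* BED12 or a refFlat-like 8-column TSV for gene models,
* two-column ``chrom.sizes`` TSV for genomes,
* FASTA (via :mod:`pyfaidx`) for sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Genome",
    "GenomicInterval",
    "Tag",
    "GeneModel",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tags",
    "write_tags",
    "read_genes",
    "write_genes",
    "write_fasta",
    "intervals_overlap",
    "overlap_fraction",
]


class ParseError(ValueError):
    """A malformed record in an input file (message names the line)."""


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and their base-pair lengths.

    Every interval in the system must lie within ``[0, size)`` of its
    chromosome.
    """

    chrom_names: tuple[str, ...]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for name in self.chrom_names:
            size = self.chrom_sizes.get(name)
            if size is None or size <= 0:
                raise ValueError(f"chromosome {name!r} has no positive size")

    def size(self, chrom: str) -> int:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.chrom_sizes[chrom]

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes[c] for c in self.chrom_names)

    def contains(self, interval: "GenomicInterval") -> bool:
        return (
            interval.chrom in self.chrom_sizes
            and 0 <= interval.start
            and interval.end <= self.chrom_sizes[interval.chrom]
        )

    @classmethod
    def from_sizes(cls, sizes: dict[str, int]) -> "Genome":
        return cls(tuple(sizes), dict(sizes))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class Tag:
    """One uniquely mapped read: chromosome, 5'-most aligned base, strand."""

    chrom: str
    pos5p: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"tag strand must be + or -, got {self.strand!r}")
        if self.pos5p < 0:
            raise ValueError("tag position must be non-negative")


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: bounds plus sorted, non-overlapping exons."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError(f"invalid transcript bounds for {self.gene_id}")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(f"{self.gene_id}: need >=1 exon with paired bounds")
        prev_end = self.tx_start
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside transcript")
            if s < prev_end and (s, e) != (self.exon_starts[0], self.exon_ends[0]):
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)


# ---------------------------------------------------------------------------
# Interval algebra


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base.

    Adjacent intervals (``a.end == b.start``) do not overlap; intervals on
    different chromosomes never overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_fraction(n_ref: int, n_overlap: int) -> int:
    """Percentage of a reference peak set recovered in another set.

    Returns ``100 * n_overlap / n_ref`` rounded to the nearest integer
    percent, the convention used for reporting binding-site overlap between
    treatments.
    """
    if n_ref <= 0:
        raise ValueError("reference count must be positive")
    if not 0 <= n_overlap <= n_ref:
        raise ValueError("overlap count must lie in [0, n_ref]")
    return int(round(100.0 * n_overlap / n_ref))


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a two-column ``chrom<TAB>size`` file into a :class:`Genome`."""
    names: list[str] = []
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                size = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad size {parts[1]!r}") from exc
            names.append(parts[0])
            sizes[parts[0]] = size
    return Genome(tuple(names), sizes)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f"{name}\t{genome.chrom_sizes[name]}\n")


# ---------------------------------------------------------------------------
# Tags (BED6)


def read_tags(path: str | Path) -> list[Tag]:
    """Read aligned tags from BED6.

    The 5' position of a ``+`` record is its start; of a ``-`` record its
    ``end - 1``.  Record order is preserved.
    """
    tags: list[Tag] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, start_s, end_s, _name, _score, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be + or -")
            if not 0 <= start < end:
                raise ParseError(f"{path}:{lineno}: bad interval [{start},{end})")
            pos5p = start if strand == "+" else end - 1
            tags.append(Tag(chrom, pos5p, strand))
    return tags


def write_tags(tags: Iterable[Tag], path: str | Path) -> None:
    """Write tags as single-base BED6 records (round-trips with read_tags)."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags):
            fh.write(
                f"{tag.chrom}\t{tag.pos5p}\t{tag.pos5p + 1}\t"
                f"tag{i}\t0\t{tag.strand}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (BED12 or refFlat-like TSV)

_REFFLAT_COLS = 8  # gene_id chrom strand txStart txEnd exonCount exonStarts exonEnds


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 or a refFlat-like 8-column TSV.

    The format is sniffed from the column count of the first data line.
    Both are normalized to :class:`GeneModel`.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 12:
                genes.append(_parse_bed12(parts, path, lineno))
            elif len(parts) == _REFFLAT_COLS:
                genes.append(_parse_refflat(parts, path, lineno))
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 (BED12) or {_REFFLAT_COLS} "
                    f"(refFlat-like) columns, got {len(parts)}"
                )
    return genes


def _parse_bed12(parts: Sequence[str], path: str | Path, lineno: int) -> GeneModel:
    try:
        chrom = parts[0]
        start, end = int(parts[1]), int(parts[2])
        name, strand = parts[3], parts[5]
        block_sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in parts[11].rstrip(",").split(",")]
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}:{lineno}: malformed BED12 record") from exc
    exon_starts = tuple(start + off for off in block_starts)
    exon_ends = tuple(s + sz for s, sz in zip(exon_starts, block_sizes))
    return GeneModel(name, chrom, strand, start, end, exon_starts, exon_ends)


def _parse_refflat(parts: Sequence[str], path: str | Path, lineno: int) -> GeneModel:
    try:
        gene_id, chrom, strand = parts[0], parts[1], parts[2]
        tx_start, tx_end = int(parts[3]), int(parts[4])
        n_exons = int(parts[5])
        exon_starts = tuple(int(x) for x in parts[6].rstrip(",").split(","))
        exon_ends = tuple(int(x) for x in parts[7].rstrip(",").split(","))
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed gene record") from exc
    if len(exon_starts) != n_exons or len(exon_ends) != n_exons:
        raise ParseError(f"{path}:{lineno}: exonCount disagrees with exon lists")
    return GeneModel(gene_id, chrom, strand, tx_start, tx_end, exon_starts, exon_ends)


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as the refFlat-like 8-column TSV."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(g.n_exons),
                        ",".join(map(str, g.exon_starts)),
                        ",".join(map(str, g.exon_ends)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA with fixed line width (deterministic bytes)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(seqs, chrom: str, start: int, end: int) -> str:
    """Slice ``[start, end)`` out of a ``dict[str, str]`` or pyfaidx Fasta."""
    return str(seqs[chrom][start:end]).upper()
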