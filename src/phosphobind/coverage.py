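"""Library normalization, directional tag extension and window coverage.

Each tag is directionally extended to the original fragment length
(default 133 bp) and genome coverage is the per-base count of overlapping
extended fragments, averaged over fixed windows (default 10 bp) for export.
Libraries are depth-matched by uniformly removing reads until every library
has the depth of the smallest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import GenomicInterval, Genome, Tag

__all__ = [
    "TagLibrary",
    "CoverageTrack",
    "extend_tag",
    "extended_arrays",
    "compute_coverage",
    "downsample",
    "normalize_libraries",
    "write_bedgraph",
]

DEFAULT_EXTENSION = 133  # fragment length the tags are extended to, bp
DEFAULT_WINDOW = 10  # averaging window for coverage export, bp


@dataclass
class TagLibrary:
    """A sequencing library: sample identity plus its aligned tags.

    ``antibody`` is one of ``total`` (pan-p53 DO1-style), ``pS15`` or
    ``pS46``; ``condition`` names the treatment (generically ``A``/``B``).
    """

    sample_id: str
    antibody: str
    condition: str
    tags: list[Tag]

    @property
    def depth(self) -> int:
        return len(self.tags)


@dataclass
class CoverageTrack:
    """Window-averaged per-base depth, one float array per chromosome."""

    genome: Genome
    window: int
    values: dict[str, np.ndarray]

    def total_mass(self) -> float:
        """Sum of per-base depth over the genome (window means x bases)."""
        total = 0.0
        for chrom in self.genome.chrom_names:
            size = self.genome.size(chrom)
            vals = self.values[chrom]
            widths = np.full(len(vals), self.window, dtype=float)
            if size % self.window:
                widths[-1] = size % self.window
            total += float(np.dot(vals, widths))
        return total


def extend_tag(
    tag: Tag, genome: Genome, length: int = DEFAULT_EXTENSION
) -> GenomicInterval:
    """Directionally extend a tag to the fragment interval it came from.

    ``+`` tags extend rightward from the 5' base, ``-`` tags leftward:
    ``[pos5p, pos5p + L)`` and ``[pos5p - L + 1, pos5p + 1)`` respectively,
    clipped to the chromosome bounds.
    """
    if length < 1:
        raise ValueError("extension length must be >= 1")
    size = genome.size(tag.chrom)
    if not 0 <= tag.pos5p < size:
        raise ValueError(f"tag at {tag.chrom}:{tag.pos5p} is off-chromosome")
    if tag.strand == "+":
        start, end = tag.pos5p, tag.pos5p + length
    else:
        start, end = tag.pos5p - length + 1, tag.pos5p + 1
    return GenomicInterval(tag.chrom, max(0, start), min(size, end), tag.strand)


def extended_arrays(
    library: TagLibrary, genome: Genome, ext: int = DEFAULT_EXTENSION
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (sorted starts, sorted ends) of clipped extended tags.

    The two arrays are sorted independently, which is all the counting
    queries need: the number of fragments overlapping half-open ``[S, E)``
    is ``searchsorted(starts, E) - searchsorted(ends, S, side="right")``.
    """
    per_chrom: dict[str, tuple[list[int], list[int]]] = {
        c: ([], []) for c in genome.chrom_names
    }
    for tag in library.tags:
        iv = extend_tag(tag, genome, ext)
        starts, ends = per_chrom[iv.chrom]
        starts.append(iv.start)
        ends.append(iv.end)
    return {
        chrom: (
            np.sort(np.asarray(starts, dtype=np.int64)),
            np.sort(np.asarray(ends, dtype=np.int64)),
        )
        for chrom, (starts, ends) in per_chrom.items()
    }


def count_overlaps(
    arrays: tuple[np.ndarray, np.ndarray],
    query_starts: np.ndarray,
    query_ends: np.ndarray,
) -> np.ndarray:
    """Count fragments overlapping each half-open query interval (>=1 bp)."""
    starts, ends = arrays
    return np.searchsorted(starts, query_ends, side="left") - np.searchsorted(
        ends, query_starts, side="right"
    )


def compute_coverage(
    library: TagLibrary,
    genome: Genome,
    ext: int = DEFAULT_EXTENSION,
    window: int = DEFAULT_WINDOW,
) -> CoverageTrack:
    """Window-averaged count of extended fragments covering each base.

    The final partial window of a chromosome averages over the bases that
    exist, not zero-padding, so edge windows are unbiased.
    """
    values: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        size = genome.size(chrom)
        diff = np.zeros(size + 1, dtype=np.int64)
        for tag in library.tags:
            if tag.chrom != chrom:
                continue
            iv = extend_tag(tag, genome, ext)
            diff[iv.start] += 1
            diff[iv.end] -= 1
        depth = np.cumsum(diff[:-1])
        edges = np.arange(0, size, window)
        sums = np.add.reduceat(depth.astype(np.float64), edges)
        widths = np.full(len(edges), window, dtype=np.float64)
        if size % window:
            widths[-1] = size % window
        values[chrom] = sums / widths
    return CoverageTrack(genome, window, values)


def downsample(library: TagLibrary, target: int, seed: int) -> TagLibrary:
    """Uniformly remove reads to reach exactly ``target`` tags.

    The retained tags are a uniform random subset without replacement,
    reproducible for a fixed seed; input order is preserved among the
    survivors.
    """
    if not 0 <= target <= library.depth:
        raise ValueError(
            f"target {target} outside [0, {library.depth}] for {library.sample_id}"
        )
    if target == library.depth:
        return replace(library, tags=list(library.tags))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(library.depth, size=target, replace=False))
    return replace(library, tags=[library.tags[i] for i in keep])


def normalize_libraries(libraries: list[TagLibrary], seed: int) -> list[TagLibrary]:
    """Depth-match libraries by downsampling each to the minimum depth."""
    if len(libraries) < 2:
        raise ValueError("need >=2 libraries to normalize")
    target = min(lib.depth for lib in libraries)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(libraries))
    return [
        downsample(lib, target, int(s)) for lib, s in zip(libraries, sub_seeds)
    ]


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Export a coverage track as bedGraph, merging equal-valued runs and
    omitting zero windows."""
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            size = track.genome.size(chrom)
            vals = track.values[chrom]
            run_start = 0
            run_val = None
            pos = 0
            for i, v in enumerate(vals):
                start = i * track.window
                end = min(start + track.window, size)
                if run_val is None or v != run_val:
                    if run_val is not None and run_val != 0:
                        fh.write(f"{chrom}\t{run_start}\t{pos}\t{run_val:g}\n")
                    run_start, run_val = start, v
                pos = end
            if run_val is not None and run_val != 0:
                fh.write(f"{chrom}\t{run_start}\t{pos}\t{run_val:g}\n")
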