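"""Local-Poisson peak calling, artifact filtering and phospho restriction.

The caller is a deliberate simplification of model-based ChIP-seq peak
callers, at desk scale: tags are extended to the fragment length, windows of
twice the fragment length slide along the genome in steps of the coverage
window, and a window is significant when the Poisson upper tail
``P(X >= k; lambda_local)`` falls below the p-value threshold (default
1e-7).  ``lambda_local`` is the most conservative of the genome-wide rate
and rates estimated from 5 kb and 10 kb windows centred on the candidate,
all from the treatment library itself (no input/control library is used).
Overlapping or nearby significant windows merge into one peak whose summit
is the leftmost position of maximal fragment depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GenomicInterval, Genome, intervals_overlap
from .coverage import (
    DEFAULT_EXTENSION,
    DEFAULT_WINDOW,
    TagLibrary,
    count_overlaps,
    extended_arrays,
)

__all__ = [
    "Peak",
    "call_peaks",
    "filter_artifacts",
    "restrict_to_reference",
    "merge_peak_sets",
    "read_peaks_bed",
    "write_peaks_bed",
]

_TINY_P = 5e-324  # smallest positive float; keeps 0 < pvalue <= 1


@dataclass
class Peak:
    """A called binding site.

    ``summit`` is the (leftmost) position of maximal per-base fragment
    depth, ``height`` that maximal depth, ``pvalue`` the smallest window
    Poisson tail probability in the peak, and ``rpp`` a per-sample
    reads-per-peak map filled in by the occupancy stage.
    """

    interval: GenomicInterval
    summit: int
    height: int
    pvalue: float
    name: str = ""
    rpp: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit must lie inside the peak interval")
        if self.height < 1:
            raise ValueError("peak height must be >= 1")
        if not 0 < self.pvalue <= 1:
            raise ValueError("peak p-value must be in (0, 1]")


def call_peaks(
    library: TagLibrary,
    genome: Genome,
    p_threshold: float = 1e-7,
    ext: int = DEFAULT_EXTENSION,
    window_bp: int = DEFAULT_WINDOW,
    local_windows: tuple[int, ...] = (5000, 10000),
    min_height: int = 1,
    name_prefix: str = "peak",
) -> list[Peak]:
    """Call peaks from a (depth-normalized) tag library.

    Returns peaks ordered by chromosome then start.  An empty library
    yields an empty list; a library whose genome-wide rate is zero is an
    error.
    """
    if library.depth == 0:
        return []
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    arrays = extended_arrays(library, genome, ext)
    win_len = 2 * ext
    eff = win_len + ext - 1  # bases whose fragment could overlap a window
    genome_rate = library.depth / genome.total_size
    if genome_rate == 0:
        raise ValueError("genome-wide tag rate is zero")

    peaks: list[Peak] = []
    for chrom in genome.chrom_names:
        size = genome.size(chrom)
        starts, ends = arrays[chrom]
        if len(starts) == 0:
            continue
        win_starts = np.arange(0, size, window_bp, dtype=np.int64)
        win_ends = np.minimum(win_starts + win_len, size)
        k = count_overlaps((starts, ends), win_starts, win_ends)

        lam = np.full(len(win_starts), genome_rate * eff)
        centers = (win_starts + win_ends) // 2
        for L in local_windows:
            loc_s = np.maximum(centers - L // 2, 0)
            loc_e = np.minimum(centers + L // 2, size)
            loc_k = count_overlaps((starts, ends), loc_s, loc_e)
            loc_rate = loc_k / ((loc_e - loc_s) + ext - 1)
            np.maximum(lam, loc_rate * eff, out=lam)

        with np.errstate(divide="ignore"):
            pvals = stats.poisson.sf(k - 1, lam)
        sig = (k > 0) & (pvals < p_threshold)
        idx = np.nonzero(sig)[0]
        if len(idx) == 0:
            continue

        # merge significant windows separated by <= ext bp
        groups: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            prev = groups[-1][-1]
            if win_starts[i] <= win_ends[prev] + ext:
                groups[-1].append(i)
            else:
                groups.append([i])

        for grp in groups:
            rs = int(win_starts[grp[0]])
            re = int(win_ends[grp[-1]])
            depth = _region_depth(starts, ends, rs, re)
            summit_off = int(np.argmax(depth))  # leftmost maximum
            height = int(depth[summit_off])
            if height < min_height:
                continue
            pval = float(max(np.min(pvals[grp]), _TINY_P))
            peaks.append(
                Peak(
                    GenomicInterval(chrom, rs, re),
                    summit=rs + summit_off,
                    height=height,
                    pvalue=pval,
                )
            )
    for i, p in enumerate(peaks):
        p.name = f"{name_prefix}_{i:04d}"
    return peaks


def _region_depth(
    starts: np.ndarray, ends: np.ndarray, rs: int, re: int
) -> np.ndarray:
    """Per-base fragment depth over ``[rs, re)`` from sorted start/end arrays."""
    diff = np.zeros(re - rs + 1, dtype=np.int64)
    mask = (starts < re) & (ends > rs)
    np.add.at(diff, np.clip(starts[mask], rs, re) - rs, 1)
    np.add.at(diff, np.clip(ends[mask], rs, re) - rs, -1)
    return np.cumsum(diff[:-1])


def filter_artifacts(
    peaks: list[Peak], blacklist: list[GenomicInterval]
) -> list[Peak]:
    """Drop peaks overlapping (>=1 bp) any blacklist interval; order kept."""
    if not blacklist:
        return list(peaks)
    return [
        p
        for p in peaks
        if not any(intervals_overlap(p.interval, b) for b in blacklist)
    ]


def restrict_to_reference(
    mod_peaks: list[Peak], reference_peaks: list[Peak]
) -> list[Peak]:
    """Keep modification-specific peaks overlapping any reference peak.

    Used to analyze phospho-specific binding only at sites bound by total
    p53 in either treatment.
    """
    return [
        m
        for m in mod_peaks
        if any(intervals_overlap(m.interval, r.interval) for r in reference_peaks)
    ]


def merge_peak_sets(
    peaks_a: list[Peak], peaks_b: list[Peak], name_prefix: str = "site"
) -> list[Peak]:
    """Site-level union of two peak sets.

    Overlapping peaks (>=1 bp, transitively) collapse into one region whose
    summit/height/pvalue come from the taller member.  Result sorted by
    coordinate.
    """
    pool = sorted(
        list(peaks_a) + list(peaks_b), key=lambda p: (p.interval.chrom, p.interval.start)
    )
    merged: list[Peak] = []
    for p in pool:
        if merged and intervals_overlap(merged[-1].interval, p.interval):
            prev = merged[-1]
            best = prev if prev.height >= p.height else p
            merged[-1] = Peak(
                GenomicInterval(
                    prev.interval.chrom,
                    min(prev.interval.start, p.interval.start),
                    max(prev.interval.end, p.interval.end),
                ),
                summit=best.summit,
                height=best.height,
                pvalue=min(prev.pvalue, p.pvalue),
            )
        else:
            merged.append(
                Peak(p.interval, p.summit, p.height, p.pvalue, rpp=dict(p.rpp))
            )
    for i, p in enumerate(merged):
        p.name = f"{name_prefix}_{i:04d}"
    return merged


def read_peaks_bed(path) -> list[Peak]:
    """Read peaks written by :func:`write_peaks_bed`."""
    out: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, name, height, _strand, summit_off, pval, rpp_s = parts
            rpp = {}
            if rpp_s != ".":
                for item in rpp_s.split(";"):
                    k, v = item.split("=")
                    rpp[k] = int(v)
            out.append(
                Peak(
                    GenomicInterval(chrom, int(start), int(end)),
                    summit=int(start) + int(summit_off),
                    height=int(height),
                    pvalue=float(pval),
                    name=name,
                    rpp=rpp,
                )
            )
    return out


def write_peaks_bed(peaks: list[Peak], path) -> None:
    """Export peaks as BED6+ (score = height; extras: summit offset, p, RPP)."""
    with open(path, "w") as fh:
        for p in peaks:
            rpp = ";".join(f"{k}={v}" for k, v in sorted(p.rpp.items())) or "."
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.name}\t{p.height}\t.\t{p.summit - p.interval.start}\t"
                f"{p.pvalue:.3e}\t{rpp}\n"
            )
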