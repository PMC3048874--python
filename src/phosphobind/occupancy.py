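"""Quantitative comparison of binding between conditions and antibodies.

Occupancy at a peak is measured as RPP (reads per peak): the number of
extended, depth-normalized tags overlapping the peak interval by at least
one base.  This module computes RPP vectors and matrices, squared Pearson
correlations between treatments, the common/preferential classification of
peaks across conditions with Kolmogorov-Smirnov comparisons, random-region
background RPP, and the quintile-binned modification fractions that relate
total-binding strength to phospho-specific binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Genome, GenomicInterval, intervals_overlap
from .coverage import DEFAULT_EXTENSION, TagLibrary, count_overlaps, extended_arrays
from .peaks import Peak

__all__ = [
    "PeakClassification",
    "reads_per_peak",
    "rpp_matrix",
    "rsq",
    "classify_common_preferential",
    "ks_two_sample",
    "median_rpp_report",
    "background_rpp",
    "binned_modification_fraction",
]


def reads_per_peak(
    peaks: list[Peak],
    library: TagLibrary,
    genome: Genome,
    ext: int = DEFAULT_EXTENSION,
) -> np.ndarray:
    """RPP vector aligned with ``peaks``: extended tags overlapping each peak."""
    arrays = extended_arrays(library, genome, ext)
    out = np.zeros(len(peaks), dtype=np.int64)
    for i, p in enumerate(peaks):
        out[i] = count_overlaps(
            arrays[p.interval.chrom],
            np.array([p.interval.start]),
            np.array([p.interval.end]),
        )[0]
    return out


def rpp_matrix(
    peaks: list[Peak],
    libraries: list[TagLibrary],
    genome: Genome,
    ext: int = DEFAULT_EXTENSION,
) -> pd.DataFrame:
    """Peaks x samples RPP matrix; also records counts on each Peak.rpp."""
    data = {}
    for lib in libraries:
        vec = reads_per_peak(peaks, lib, genome, ext)
        data[lib.sample_id] = vec
        for p, v in zip(peaks, vec):
            p.rpp[lib.sample_id] = int(v)
    index = [p.name or f"peak_{i}" for i, p in enumerate(peaks)]
    return pd.DataFrame(data, index=index)


def rsq(x, y) -> float:
    """Square of the Pearson sample correlation coefficient.

    Raises on constant vectors, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class PeakClassification:
    """Partition of two condition-specific peak sets into common and
    preferential peaks.

    A peak of condition A is *common* iff it overlaps (>=1 bp) at least one
    peak of condition B, and vice versa; one-to-many overlaps collapse to
    the site level, so the common count reported for a condition is the
    number of its peaks with a match in the other condition.
    """

    peaks_a: list[Peak]
    peaks_b: list[Peak]
    common_mask_a: np.ndarray
    common_mask_b: np.ndarray

    @property
    def n_common_a(self) -> int:
        return int(self.common_mask_a.sum())

    @property
    def n_common_b(self) -> int:
        return int(self.common_mask_b.sum())

    @property
    def preferential_a(self) -> list[Peak]:
        return [p for p, c in zip(self.peaks_a, self.common_mask_a) if not c]

    @property
    def preferential_b(self) -> list[Peak]:
        return [p for p, c in zip(self.peaks_b, self.common_mask_b) if not c]


def classify_common_preferential(
    peaks_a: list[Peak], peaks_b: list[Peak]
) -> PeakClassification:
    """Classify each condition's peaks as common or preferential."""
    mask_a = np.array(
        [any(intervals_overlap(a.interval, b.interval) for b in peaks_b) for a in peaks_a],
        dtype=bool,
    )
    mask_b = np.array(
        [any(intervals_overlap(b.interval, a.interval) for a in peaks_a) for b in peaks_b],
        dtype=bool,
    )
    return PeakClassification(list(peaks_a), list(peaks_b), mask_a, mask_b)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` where D is the supremum ECDF distance and p comes
    from the asymptotic KS distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def median_rpp_report(
    classification: PeakClassification,
    rpp_a: np.ndarray,
    rpp_b: np.ndarray,
) -> dict:
    """Medians of common vs preferential RPP per condition, with KS tests.

    ``rpp_a``/``rpp_b`` align with ``classification.peaks_a``/``peaks_b``.
    Empty classes yield ``None`` medians and no test.
    """
    report: dict = {}
    for cond, rpp, mask in (
        ("A", np.asarray(rpp_a), classification.common_mask_a),
        ("B", np.asarray(rpp_b), classification.common_mask_b),
    ):
        common = rpp[mask]
        pref = rpp[~mask]
        entry = {
            "median_common": float(np.median(common)) if common.size else None,
            "median_preferential": float(np.median(pref)) if pref.size else None,
            "n_common": int(common.size),
            "n_preferential": int(pref.size),
        }
        if common.size and pref.size:
            d, p = ks_two_sample(common, pref)
            entry["ks_D"] = d
            entry["ks_p"] = p
        report[cond] = entry
    return report


def background_rpp(
    library: TagLibrary,
    n_regions: int,
    region_length: int,
    genome: Genome,
    seed: int,
    ext: int = DEFAULT_EXTENSION,
) -> np.ndarray:
    """RPP of uniformly placed random regions: the null occupancy sample.

    Regions are placed uniformly over the genome (weighted by chromosome
    length), each of ``region_length`` bp; the same extended-tag overlap
    count as for real peaks is returned.
    """
    if region_length > min(genome.chrom_sizes.values()):
        raise ValueError("region length exceeds the smallest chromosome")
    rng = np.random.default_rng(seed)
    arrays = extended_arrays(library, genome, ext)
    sizes = np.array([genome.size(c) - region_length for c in genome.chrom_names])
    probs = sizes / sizes.sum()
    chrom_idx = rng.choice(len(sizes), size=n_regions, p=probs)
    out = np.zeros(n_regions, dtype=np.int64)
    for i, ci in enumerate(chrom_idx):
        start = int(rng.integers(0, sizes[ci] + 1))
        chrom = genome.chrom_names[ci]
        out[i] = count_overlaps(
            arrays[chrom],
            np.array([start]),
            np.array([start + region_length]),
        )[0]
    return out


def binned_modification_fraction(
    reference_peaks: list[Peak],
    reference_rpp: np.ndarray,
    mod_peaks: list[Peak],
    n_bins: int = 5,
) -> np.ndarray:
    """Fraction of reference peaks carrying a modification peak, per RPP bin.

    Reference peaks are ranked by RPP ascending (ties broken by coordinate
    for determinism) and split into ``n_bins`` near-equal bins, any
    remainder going to the lowest bins; each bin's value is the fraction of
    its peaks overlapping (>=1 bp) at least one modification-specific peak.
    """
    n = len(reference_peaks)
    if n_bins < 1:
        raise ValueError("need n_bins >= 1")
    if n < n_bins:
        raise ValueError(f"cannot split {n} peaks into {n_bins} bins")
    rpp = np.asarray(reference_rpp)
    order = sorted(
        range(n),
        key=lambda i: (
            rpp[i],
            reference_peaks[i].interval.chrom,
            reference_peaks[i].interval.start,
        ),
    )
    has_mod = np.array(
        [
            any(intervals_overlap(p.interval, m.interval) for m in mod_peaks)
            for p in reference_peaks
        ],
        dtype=bool,
    )
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    fractions = np.zeros(n_bins)
    cursor = 0
    for b, sz in enumerate(sizes):
        members = order[cursor : cursor + sz]
        fractions[b] = has_mod[members].mean()
        cursor += sz
    return fractions
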