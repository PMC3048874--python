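"""Five-category genomic annotation of peaks relative to gene models.

The genome is partitioned into:

* ``TSS_flank``      - 5 kb upstream of the TSS plus the first exon and
                       first intron (strand-aware),
* ``intragenic``     - all remaining introns and exons,
* ``downstream_5kb`` - 5 kb downstream of the last exon,
* ``flank_5_25kb``   - 5-25 kb up- or downstream of a gene,
* ``intergenic``     - everything else.

Where definitions collide (overlapping genes, isoforms, flanks) a fixed
precedence applies: TSS_flank > intragenic > downstream_5kb > flank_5_25kb
> intergenic, so promoter-like labels always win.  The genomic distribution
of a category is its nucleotide count divided by the genome size; peak
enrichment relative to that distribution is tested with a one-sided
binomial tail, Bonferroni-adjusted across the five categories.

Peaks are labelled by summit position (a single unambiguous label per
peak) and assigned to genes when the summit lies within the transcript or
a configurable flank (default 25 kb) on either side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, Genome
from .peaks import Peak

__all__ = [
    "CATEGORIES",
    "RegionMap",
    "build_region_map",
    "genomic_distribution",
    "annotate_peaks",
    "enrichment_test",
    "assign_peaks_to_genes",
]

CATEGORIES = (
    "TSS_flank",
    "intragenic",
    "downstream_5kb",
    "flank_5_25kb",
    "intergenic",
)
# label codes, painted in reverse precedence so the highest wins
_CODE = {name: i for i, name in enumerate(CATEGORIES)}
_INTERGENIC = _CODE["intergenic"]


@dataclass
class RegionMap:
    """Per-base category labels (uint8 per chromosome) forming a partition."""

    genome: Genome
    labels: dict[str, np.ndarray]

    def category_at(self, chrom: str, pos: int) -> str:
        size = self.genome.size(chrom)
        if not 0 <= pos < size:
            raise ValueError(f"position {chrom}:{pos} outside the genome")
        return CATEGORIES[self.labels[chrom][pos]]

    def nucleotide_totals(self) -> dict[str, int]:
        totals = np.zeros(len(CATEGORIES), dtype=np.int64)
        for chrom in self.genome.chrom_names:
            totals += np.bincount(self.labels[chrom], minlength=len(CATEGORIES))
        return {name: int(totals[_CODE[name]]) for name in CATEGORIES}

    def to_bed(self, path) -> None:
        """Export the partition as BED with the category in the name column."""
        with open(path, "w") as fh:
            for chrom in self.genome.chrom_names:
                lab = self.labels[chrom]
                boundaries = np.flatnonzero(np.diff(lab)) + 1
                starts = np.concatenate(([0], boundaries))
                ends = np.concatenate((boundaries, [len(lab)]))
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{CATEGORIES[lab[s]]}\n")


def _gene_regions(gene: GeneModel, tss_bp: int, far_bp: int):
    """Yield (category, start, end) for one gene, unclipped, strand-aware.

    For a ``-`` gene the layout mirrors: the TSS sits at ``tx_end``, the
    biological first exon is the last in coordinate order.
    """
    s, e = gene.tx_start, gene.tx_end
    if gene.strand == "+":
        if gene.n_exons >= 2:
            # 5 kb up + first exon + first intron ends at the 2nd exon start
            tss_end = gene.exon_starts[1]
            yield "intragenic", tss_end, e
        else:
            tss_end = e
        yield "TSS_flank", s - tss_bp, tss_end
        yield "downstream_5kb", e, e + tss_bp
        yield "flank_5_25kb", s - far_bp, s - tss_bp
        yield "flank_5_25kb", e + tss_bp, e + far_bp
    else:
        if gene.n_exons >= 2:
            tss_start = gene.exon_ends[-2]
            yield "intragenic", s, tss_start
        else:
            tss_start = s
        yield "TSS_flank", tss_start, e + tss_bp
        yield "downstream_5kb", s - tss_bp, s
        yield "flank_5_25kb", e + tss_bp, e + far_bp
        yield "flank_5_25kb", s - far_bp, s - tss_bp


def build_region_map(
    genes: list[GeneModel],
    genome: Genome,
    tss_flank_bp: int = 5000,
    far_flank_bp: int = 25000,
) -> RegionMap:
    """Partition the genome into the five annotation categories.

    Regions are built per transcript then merged under the fixed precedence;
    everything unlabelled is intergenic.  Regions running off a chromosome
    end are clipped.
    """
    labels = {
        chrom: np.full(genome.size(chrom), _INTERGENIC, dtype=np.uint8)
        for chrom in genome.chrom_names
    }
    # paint from lowest to highest precedence so later paints win
    for category in reversed(CATEGORIES[:-1]):
        code = _CODE[category]
        for gene in genes:
            size = genome.size(gene.chrom)
            for cat, rs, re in _gene_regions(gene, tss_flank_bp, far_flank_bp):
                if cat != category:
                    continue
                rs, re = max(0, rs), min(size, re)
                if rs < re:
                    labels[gene.chrom][rs:re] = code
    return RegionMap(genome, labels)


def genomic_distribution(region_map: RegionMap) -> dict[str, float]:
    """Fraction of genomic nucleotides per category (sums to 1)."""
    totals = region_map.nucleotide_totals()
    g = region_map.genome.total_size
    return {name: totals[name] / g for name in CATEGORIES}


def annotate_peaks(
    peaks: list[Peak], region_map: RegionMap
) -> tuple[list[str], dict[str, int]]:
    """Label each peak by the category of its summit; return labels + counts."""
    labels = [region_map.category_at(p.interval.chrom, p.summit) for p in peaks]
    counts = {name: 0 for name in CATEGORIES}
    for lab in labels:
        counts[lab] += 1
    return labels, counts


def enrichment_test(
    observed: dict[str, int],
    n_peaks: int,
    expected_fraction: dict[str, float],
) -> pd.DataFrame:
    """One-sided binomial enrichment of peak categories vs genomic fractions.

    For each category, tests P(X >= observed) with X ~ Binomial(n_peaks,
    genomic fraction); p-values are Bonferroni-adjusted across the five
    categories.  Returns a tidy report table.
    """
    total_frac = sum(expected_fraction.values())
    if abs(total_frac - 1.0) > 1e-9:
        raise ValueError("expected fractions must sum to 1")
    rows = []
    for name in CATEGORIES:
        obs = observed.get(name, 0)
        frac = expected_fraction[name]
        if frac >= 1.0:
            p = 1.0
        else:
            p = stats.binomtest(obs, n_peaks, frac, alternative="greater").pvalue
        p_adj = min(1.0, p * len(CATEGORIES))
        rows.append(
            {
                "category": name,
                "observed": obs,
                "expected": n_peaks * frac,
                "fraction_genome": frac,
                "p": p,
                "p_bonferroni": p_adj,
                "enriched": p_adj < 0.05 and obs > n_peaks * frac,
            }
        )
    return pd.DataFrame(rows)


def assign_peaks_to_genes(
    peaks: list[Peak],
    genes: list[GeneModel],
    flank: int = 25000,
) -> pd.DataFrame:
    """Many-to-many peak-to-gene table by summit proximity.

    A peak is assigned to a gene iff its summit lies in
    ``[tx_start - flank, tx_end + flank)`` — within the transcript or the
    flank on either side.  Returns columns ``peak``, ``gene_id``,
    ``summit``, ``chrom``.
    """
    rows = []
    for p in peaks:
        for g in genes:
            if g.chrom != p.interval.chrom:
                continue
            if g.tx_start - flank <= p.summit < g.tx_end + flank:
                rows.append(
                    {
                        "peak": p.name,
                        "gene_id": g.gene_id,
                        "chrom": p.interval.chrom,
                        "summit": p.summit,
                    }
                )
    return pd.DataFrame(rows, columns=["peak", "gene_id", "chrom", "summit"])
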