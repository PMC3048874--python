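"""Five-category region map: partition, annotation, enrichment, assignment."""

import numpy as np
import pytest

from phosphobind.core import GeneModel, Genome, GenomicInterval
from phosphobind.peaks import Peak
from phosphobind.regions import (
    CATEGORIES,
    annotate_peaks,
    assign_peaks_to_genes,
    build_region_map,
    enrichment_test,
    genomic_distribution,
)

from oracles import binomial_tail_by_summation


def make_peak(chrom, summit, half=100):
    return Peak(
        GenomicInterval(chrom, max(0, summit - half), summit + half),
        summit, 5, 1e-9,
    )


class TestBuildRegionMap:
    def test_no_genes_everything_intergenic(self, toy_gene_genome):
        rm = build_region_map([], toy_gene_genome)
        totals = rm.nucleotide_totals()
        assert totals["intergenic"] == 100_000
        assert sum(totals.values()) == 100_000

    def test_plus_strand_worked_example(self, toy_gene, toy_gene_genome):
        rm = build_region_map([toy_gene], toy_gene_genome)
        totals = rm.nucleotide_totals()
        # 5 kb upstream + first exon + first intron
        assert all(
            rm.category_at("chr1", p) == "TSS_flank" for p in (25_000, 30_500, 34_999)
        )
        assert rm.category_at("chr1", 35_000) == "intragenic"
        assert rm.category_at("chr1", 40_000) == "downstream_5kb"
        assert rm.category_at("chr1", 5_000) == "flank_5_25kb"
        assert rm.category_at("chr1", 64_999) == "flank_5_25kb"
        assert rm.category_at("chr1", 65_000) == "intergenic"
        assert totals["TSS_flank"] == 10_000
        assert totals["intragenic"] == 5_000
        assert totals["downstream_5kb"] == 5_000
        assert totals["flank_5_25kb"] == 40_000
        assert sum(totals.values()) == 100_000

    def test_minus_strand_mirrors_layout(self, toy_gene_genome):
        gene = GeneModel(
            "geneY", "chr1", "-", 30_000, 40_000, (30_000, 35_000), (31_000, 40_000)
        )
        rm = build_region_map([gene], toy_gene_genome)
        totals = rm.nucleotide_totals()
        # TSS at tx_end side: 5 kb up + first exon [35000,40000) + first intron
        assert rm.category_at("chr1", 44_999) == "TSS_flank"
        assert rm.category_at("chr1", 35_000) == "TSS_flank"
        assert rm.category_at("chr1", 31_000) == "TSS_flank"  # first intron
        assert rm.category_at("chr1", 30_999) == "intragenic"
        assert rm.category_at("chr1", 25_000) == "downstream_5kb"
        assert totals["TSS_flank"] == 14_000
        assert totals["intragenic"] == 1_000
        assert sum(totals.values()) == 100_000

    def test_single_exon_gene_has_no_intragenic(self, toy_gene_genome):
        gene = GeneModel("g1", "chr1", "+", 30_000, 33_000, (30_000,), (33_000,))
        rm = build_region_map([gene], toy_gene_genome)
        assert rm.nucleotide_totals()["intragenic"] == 0

    def test_partition_per_base_on_random_genes(self):
        # every base gets exactly one category and totals sum to genome size
        genome = Genome.from_sizes({"chr1": 200_000})
        rng = np.random.default_rng(6)
        genes = []
        for i in range(8):
            s = int(rng.integers(0, 190_000))
            e = s + int(rng.integers(2_000, 9_000))
            e = min(e, 199_000)
            mid = (s + e) // 2
            genes.append(
                GeneModel(
                    f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                    s, e, (s, mid), (mid - 500, e),
                )
            )
        rm = build_region_map(genes, genome)
        assert sum(rm.nucleotide_totals().values()) == 200_000
        # label array covers every base with a valid category code
        assert set(np.unique(rm.labels["chr1"])) <= set(range(len(CATEGORIES)))

    def test_gene_at_chromosome_edge_clipped(self):
        genome = Genome.from_sizes({"chr1": 10_000})
        gene = GeneModel("g", "chr1", "+", 1_000, 4_000, (1_000, 2_500), (2_000, 4_000))
        rm = build_region_map([gene], genome)
        assert sum(rm.nucleotide_totals().values()) == 10_000


class TestGenomicDistribution:
    def test_no_genes_intergenic_fraction_one(self, toy_gene_genome):
        rm = build_region_map([], toy_gene_genome)
        dist = genomic_distribution(rm)
        assert dist["intergenic"] == pytest.approx(1.0)

    def test_worked_example_tss_fraction(self, toy_gene, toy_gene_genome):
        dist = genomic_distribution(build_region_map([toy_gene], toy_gene_genome))
        assert dist["TSS_flank"] == pytest.approx(0.10)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


class TestAnnotatePeaks:
    def test_summit_labels_and_counts(self, toy_gene, toy_gene_genome):
        rm = build_region_map([toy_gene], toy_gene_genome)
        peaks = [make_peak("chr1", 27_000), make_peak("chr1", 90_000)]
        labels, counts = annotate_peaks(peaks, rm)
        assert labels == ["TSS_flank", "intergenic"]
        assert sum(counts.values()) == len(peaks)

    def test_gene_free_chromosome_all_intergenic(self):
        genome = Genome.from_sizes({"chrZ": 50_000})
        rm = build_region_map([], genome)
        peaks = [make_peak("chrZ", p) for p in (1_000, 20_000, 45_000)]
        labels, counts = annotate_peaks(peaks, rm)
        assert labels == ["intergenic"] * 3

    def test_order_invariance(self, toy_gene, toy_gene_genome):
        rm = build_region_map([toy_gene], toy_gene_genome)
        peaks = [make_peak("chr1", p) for p in (27_000, 36_000, 90_000)]
        _, fwd = annotate_peaks(peaks, rm)
        _, rev = annotate_peaks(peaks[::-1], rm)
        assert fwd == rev

    def test_summit_outside_genome_errors(self, toy_gene_genome):
        rm = build_region_map([], toy_gene_genome)
        bad = Peak(GenomicInterval("chr1", 99_900, 100_000), 99_950, 5, 1e-9)
        labels, _ = annotate_peaks([bad], rm)  # in range: fine
        with pytest.raises(ValueError):
            rm.category_at("chr1", 100_000)


class TestEnrichmentTest:
    def test_observed_equal_expected_not_significant(self):
        frac = {c: 0.2 for c in CATEGORIES}
        obs = {c: 20 for c in CATEGORIES}
        report = enrichment_test(obs, 100, frac)
        assert not report["enriched"].any()
        assert (report["p"] > 0.2).all()

    def test_extreme_concentration_is_significant(self):
        frac = dict.fromkeys(CATEGORIES, 0.01)
        frac["intergenic"] = 0.96
        obs = dict.fromkeys(CATEGORIES, 0)
        obs["TSS_flank"] = 100
        report = enrichment_test(obs, 100, frac).set_index("category")
        assert report.loc["TSS_flank", "p_bonferroni"] < 1e-100
        assert report.loc["TSS_flank", "enriched"]

    def test_tail_matches_exact_summation(self):
        frac = {c: 0.2 for c in CATEGORIES}
        obs = {"TSS_flank": 15, "intragenic": 8, "downstream_5kb": 9,
               "flank_5_25kb": 10, "intergenic": 8}
        report = enrichment_test(obs, 50, frac).set_index("category")
        for cat in CATEGORIES:
            exact = binomial_tail_by_summation(obs[cat], 50, 0.2)
            assert report.loc[cat, "p"] == pytest.approx(exact, rel=1e-9)


class TestAssignPeaksToGenes:
    @pytest.fixture
    def genes(self):
        return [
            GeneModel("gA", "chr1", "+", 100_000, 110_000, (100_000,), (110_000,)),
            GeneModel("gB", "chr1", "-", 200_000, 210_000, (200_000,), (210_000,)),
            GeneModel("gC", "chr2", "+", 50_000, 60_000, (50_000,), (60_000,)),
        ]

    def test_inclusive_lower_bound(self, genes):
        peak = make_peak("chr1", 75_000)  # exactly tx_start - 25 kb
        table = assign_peaks_to_genes([peak], genes, flank=25_000)
        assert table["gene_id"].tolist() == ["gA"]

    def test_exclusive_upper_bound(self, genes):
        peak = make_peak("chr1", 135_000)  # exactly tx_end + 25 kb
        table = assign_peaks_to_genes([peak], genes, flank=25_000)
        assert table.empty

    def test_matches_brute_force_distances(self, genes):
        peaks = [
            make_peak("chr1", 90_000),
            make_peak("chr1", 180_000),
            make_peak("chr2", 61_000),
            make_peak("chr2", 300_000),
        ]
        for i, p in enumerate(peaks):
            p.name = f"p{i}"
        table = assign_peaks_to_genes(peaks, genes, flank=25_000)
        expected = set()
        for p in peaks:
            for g in genes:
                if g.chrom == p.interval.chrom and (
                    g.tx_start - 25_000 <= p.summit < g.tx_end + 25_000
                ):
                    expected.add((p.name, g.gene_id))
        assert set(zip(table["peak"], table["gene_id"])) == expected
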