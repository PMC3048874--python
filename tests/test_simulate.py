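"""Synthetic study generator: determinism, structure, truth consistency."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from phosphobind.core import read_chrom_sizes, read_genes, read_tags
from phosphobind.motif import default_p53_model, scan_region
from phosphobind.occupancy import ks_two_sample, reads_per_peak
from phosphobind.peaks import Peak
from phosphobind.core import GenomicInterval
from phosphobind.simulate import (
    CONSENSUS_SITE,
    SimulationConfig,
    generate,
    recovery_report,
)


SMALL = dict(chrom_sizes={"chr1": 150_000}, n_genes=8, n_sites=16)


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = SimulationConfig(seed=3, **SMALL)
        generate(cfg, tmp_path / "a")
        generate(cfg, tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in files:
            assert filecmp.cmp(
                tmp_path / "a" / name, tmp_path / "b" / name, shallow=False
            ), name

    def test_different_seeds_differ(self, tmp_path):
        a = generate(SimulationConfig(seed=1, **SMALL))
        b = generate(SimulationConfig(seed=2, **SMALL))
        assert a.truth_sites["center"].tolist() != b.truth_sites["center"].tolist()


class TestBundleStructure:
    def test_files_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=3, **SMALL)
        bundle = generate(cfg, tmp_path)
        genome = read_chrom_sizes(bundle.paths["chrom_sizes"])
        assert genome == bundle.genome
        genes = read_genes(bundle.paths["genes"])
        assert genes == bundle.genes
        tags = read_tags(bundle.paths["tags_total_A"])
        assert tags == bundle.libraries[("total", "A")].tags
        assert Path(bundle.paths["manifest"]).exists()

    def test_zero_sites_depth_is_pure_background(self):
        cfg = SimulationConfig(
            seed=4, chrom_sizes={"chr1": 100_000}, n_genes=4, n_sites=0,
            responsive_fraction=0.0,
        )
        bundle = generate(cfg)
        depth = bundle.libraries[("total", "A")].depth
        lam = cfg.background_rate * 100_000
        assert abs(depth - lam) < 5 * np.sqrt(lam)

    def test_truth_sites_consistent_with_config(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        bundle = generate(cfg)
        sites = bundle.truth_sites
        assert len(sites) == cfg.n_sites
        n_resp = int(round(cfg.responsive_fraction * cfg.n_sites))
        assert sites["responsive"].sum() == n_resp
        # responsive sites are the strongest ones and live inside host genes
        threshold = sites["strength"].nlargest(n_resp).min()
        assert (sites.loc[sites["responsive"], "strength"] >= threshold).all()
        by_id = {g.gene_id: g for g in bundle.genes}
        for _, s in sites[sites["responsive"]].iterrows():
            host = by_id[s["host_gene"]]
            assert host.tx_start <= s["center"] < host.tx_end

    def test_motif_implanted_at_every_site(self):
        bundle = generate(SimulationConfig(seed=6, **SMALL))
        model = default_p53_model()
        for _, s in bundle.truth_sites.iterrows():
            c = int(s["center"])
            window = bundle.sequences[s["chrom"]][c - 100 : c + 100]
            hit = scan_region(model, window)
            assert hit is not None
            assert hit.score == pytest.approx(model.max_score)

    def test_motif_implant_can_be_disabled(self):
        bundle = generate(SimulationConfig(seed=6, implant_motif=False, **SMALL))
        found = 0
        for _, s in bundle.truth_sites.iterrows():
            c = int(s["center"])
            seq = bundle.sequences[s["chrom"]][c - 10 : c + 10]
            found += seq == CONSENSUS_SITE
        assert found == 0

    def test_expression_design_complete(self):
        bundle = generate(SimulationConfig(seed=7, **SMALL))
        sheet = bundle.sample_sheet
        cells = sheet.groupby(["condition", "timepoint"]).size()
        assert (cells == 2).all() and len(cells) == 4
        assert bundle.expression.shape == (SMALL["n_genes"], 8)


class TestPhosphoThinning:
    def test_null_phospho_libraries_exchangeable_across_conditions(self):
        # with f46 equal in both conditions the per-site pS46 RPP
        # distributions must be statistically indistinguishable
        pvals = []
        for seed in (21, 22, 23):
            cfg = SimulationConfig(
                seed=seed, f46_responsive_B=0.1,
                chrom_sizes={"chr1": 300_000}, n_genes=15, n_sites=40,
            )
            bundle = generate(cfg)
            site_peaks = [
                Peak(
                    GenomicInterval(s["chrom"], int(s["center"]) - 100,
                                    int(s["center"]) + 100),
                    int(s["center"]), 1, 1e-9,
                )
                for _, s in bundle.truth_sites.iterrows()
            ]
            rpp_a = reads_per_peak(
                site_peaks, bundle.libraries[("pS46", "A")], bundle.genome
            )
            rpp_b = reads_per_peak(
                site_peaks, bundle.libraries[("pS46", "B")], bundle.genome
            )
            _, p = ks_two_sample(rpp_a, rpp_b)
            pvals.append(p)
        assert max(pvals) > 0.01

    def test_phospho_site_signal_scales_with_fraction(self):
        bundle = generate(SimulationConfig(seed=9, **SMALL))
        sites = bundle.truth_sites
        strong = sites.loc[sites["responsive"]].iloc[0]
        peak = [
            Peak(
                GenomicInterval(strong["chrom"], int(strong["center"]) - 150,
                                int(strong["center"]) + 150),
                int(strong["center"]), 1, 1e-9,
            )
        ]
        total = reads_per_peak(peak, bundle.libraries[("total", "B")], bundle.genome)[0]
        ps46_b = reads_per_peak(peak, bundle.libraries[("pS46", "B")], bundle.genome)[0]
        ps46_a = reads_per_peak(peak, bundle.libraries[("pS46", "A")], bundle.genome)[0]
        assert ps46_b < total
        assert ps46_a < ps46_b  # 0.1 vs 0.5 thinning at a responsive site


class TestRecoveryReport:
    def _peaks_at(self, sites, jitter=0):
        return [
            Peak(
                GenomicInterval(s["chrom"], int(s["center"]) - 100 + jitter,
                                int(s["center"]) + 100 + jitter),
                int(s["center"]) + jitter, 5, 1e-9,
            )
            for _, s in sites.iterrows()
        ]

    def test_perfect_calls_score_perfectly(self):
        bundle = generate(SimulationConfig(seed=10, **SMALL))
        peaks = self._peaks_at(bundle.truth_sites)
        rep = recovery_report(bundle.truth_sites, peaks)
        assert rep["sensitivity"] == 1.0
        assert rep["fdr"] == 0.0

    def test_shifted_calls_score_zero(self):
        # jitter of 1.5 kb stays > 200 bp from every site: sites are >= 3 kb
        # apart, so a shifted summit is 1.5 kb from its own site and >= 1.5 kb
        # from any neighbour
        bundle = generate(SimulationConfig(seed=10, **SMALL))
        peaks = self._peaks_at(bundle.truth_sites, jitter=1_500)
        rep = recovery_report(bundle.truth_sites, peaks)
        assert rep["sensitivity"] == 0.0
        assert rep["fdr"] == 1.0

    def test_candidate_precision_recall(self):
        bundle = generate(SimulationConfig(seed=10, **SMALL))
        truth = bundle.truth_genes
        true_set = list(truth.loc[truth["candidate"], "gene_id"])
        rep = recovery_report(
            bundle.truth_sites, [],
            candidate_genes=true_set[:-1] + ["not_a_gene"],
            truth_genes=truth,
        )
        n = len(true_set)
        assert rep["candidate_recall"] == pytest.approx((n - 1) / n)
        assert rep["candidate_precision"] == pytest.approx((n - 1) / n)


def test_invalid_fractions_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(f15=1.5)
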