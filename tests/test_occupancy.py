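"""RPP quantification, correlations, classification and quintile fractions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosphobind.core import GenomicInterval, Genome, Tag
from phosphobind.coverage import TagLibrary
from phosphobind.occupancy import (
    background_rpp,
    binned_modification_fraction,
    classify_common_preferential,
    ks_two_sample,
    median_rpp_report,
    reads_per_peak,
    rsq,
)
from phosphobind.peaks import Peak

from conftest import random_tags
from oracles import ks_d_by_ecdf, pearson_by_formula, rpp_by_pairs


def make_peak(chrom, start, end, summit=None, height=5):
    summit = summit if summit is not None else (start + end) // 2
    return Peak(GenomicInterval(chrom, start, end), summit, height, 1e-9)


class TestReadsPerPeak:
    def test_no_tags_all_zero(self, toy_genome):
        peaks = [make_peak("chr1", 100, 300)]
        lib = TagLibrary("x", "total", "A", [])
        assert reads_per_peak(peaks, lib, toy_genome).tolist() == [0]

    def test_tag_inside_peak_counts_once(self, toy_genome):
        peaks = [make_peak("chr1", 100, 300)]
        lib = TagLibrary("x", "total", "A", [Tag("chr1", 150, "+")])
        assert reads_per_peak(peaks, lib, toy_genome).tolist() == [1]

    def test_matches_all_pairs_enumeration(self, toy_genome):
        rng = np.random.default_rng(21)
        tags = random_tags(rng, toy_genome, 10)
        peaks = [
            make_peak("chr1", 50, 250),
            make_peak("chr1", 400, 600),
            make_peak("chr2", 100, 350),
        ]
        lib = TagLibrary("x", "total", "A", tags)
        got = reads_per_peak(peaks, lib, toy_genome, ext=133)
        want = rpp_by_pairs(peaks, tags, toy_genome, ext=133)
        np.testing.assert_array_equal(got, want)


class TestRsq:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2, 3, 7])
        assert rsq(x, x) == pytest.approx(1.0)

    def test_sign_vanishes_under_squaring(self):
        x = np.array([1.0, 2, 3, 7])
        assert rsq(x, -x) == pytest.approx(1.0)

    def test_matches_hand_pearson(self):
        x, y = [1, 2, 3, 4], [2, 4, 5, 4]
        assert rsq(x, y) == pytest.approx(pearson_by_formula(x, y) ** 2)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rsq([1, 1, 1], [1, 2, 3])

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        c=st.floats(0.1, 10), d=st.floats(-5, 5),
    )
    def test_affine_invariance(self, a, b, c, d):
        x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 7.0, 11.0])
        assert rsq(a * x + b, c * y + d) == pytest.approx(rsq(x, y), abs=1e-9)


class TestClassification:
    def test_identical_sets_all_common(self):
        peaks = [make_peak("chr1", 0, 100), make_peak("chr1", 500, 700)]
        cls = classify_common_preferential(peaks, peaks)
        assert cls.n_common_a == cls.n_common_b == 2
        assert cls.preferential_a == [] and cls.preferential_b == []

    def test_disjoint_sets_no_common(self):
        a = [make_peak("chr1", 0, 100)]
        b = [make_peak("chr1", 200, 300)]
        cls = classify_common_preferential(a, b)
        assert cls.n_common_a == cls.n_common_b == 0

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        a = [make_peak("chr1", int(s), int(s) + 120) for s in rng.integers(0, 5000, 5)]
        b = [make_peak("chr1", int(s), int(s) + 150) for s in rng.integers(0, 5000, 4)]
        cls = classify_common_preferential(a, b)
        assert cls.n_common_a + len(cls.preferential_a) == len(a)
        assert cls.n_common_b + len(cls.preferential_b) == len(b)

    def test_two_to_one_overlap_counts_each_side_once(self):
        a = [make_peak("chr1", 0, 100), make_peak("chr1", 150, 250)]
        b = [make_peak("chr1", 50, 200)]  # overlaps both A peaks
        cls = classify_common_preferential(a, b)
        assert cls.n_common_a == 2
        assert cls.n_common_b == 1


class TestKsTwoSample:
    def test_identical_samples_have_zero_d(self):
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == pytest.approx(0.0)

    def test_disjoint_supports_have_d_one(self):
        d, p = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == pytest.approx(1.0)

    def test_interleaved_example_matches_ecdf_oracle(self):
        x, y = [1, 2, 3], [1.5, 2.5, 3.5]
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(1 / 3)
        assert d == pytest.approx(ks_d_by_ecdf(x, y))

    def test_random_samples_match_ecdf_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = rng.normal(0.5, 1.2, size=25)
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(ks_d_by_ecdf(x, y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestMedianReport:
    def test_all_common_leaves_preferential_missing(self):
        peaks = [make_peak("chr1", 0, 100), make_peak("chr1", 500, 700)]
        cls = classify_common_preferential(peaks, peaks)
        rep = median_rpp_report(cls, np.array([5, 9]), np.array([6, 10]))
        assert rep["A"]["median_preferential"] is None
        assert rep["A"]["median_common"] == 7.0

    def test_common_stronger_than_preferential(self):
        # common sites generated 3x stronger: medians must separate and KS agree
        rng = np.random.default_rng(17)
        a = [make_peak("chr1", 1000 * i, 1000 * i + 200) for i in range(60)]
        b = [make_peak("chr1", 1000 * i, 1000 * i + 200) for i in range(40)]
        rpp_a = np.concatenate([rng.poisson(30, 40), rng.poisson(10, 20)])
        rpp_b = rng.poisson(30, 40)
        cls = classify_common_preferential(a, b)
        rep = median_rpp_report(cls, rpp_a, rpp_b)
        assert rep["A"]["median_common"] > rep["A"]["median_preferential"]
        assert rep["A"]["ks_p"] < 0.01


class TestBackgroundRpp:
    def test_zero_tags_all_zero(self, toy_genome):
        lib = TagLibrary("x", "total", "A", [])
        assert background_rpp(lib, 10, 100, toy_genome, seed=0).sum() == 0

    def test_fixed_seed_reproducible(self, toy_library, toy_genome):
        a = background_rpp(toy_library, 50, 100, toy_genome, seed=3)
        b = background_rpp(toy_library, 50, 100, toy_genome, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_uniform_background_mean_matches_analytic_expectation(self):
        # a fragment overlaps a region of length L iff its extended start
        # falls in a window of L + ext - 1 bases
        genome = Genome.from_sizes({"chr1": 100_000})
        rng = np.random.default_rng(31)
        rate, ext, L, n = 0.02, 133, 200, 2000
        tags = [
            Tag("chr1", int(p), "+")
            for p in rng.integers(0, 100_000, size=int(rate * 100_000))
        ]
        lib = TagLibrary("x", "total", "A", tags)
        vals = background_rpp(lib, n, L, genome, seed=4, ext=ext)
        expected = rate * (L + ext - 1)
        se = np.sqrt(expected / n)
        assert abs(vals.mean() - expected) < 3 * se + 0.05


class TestBinnedModificationFraction:
    def _peaks(self, n):
        return [make_peak("chr1", 1000 * i, 1000 * i + 200) for i in range(n)]

    def test_self_modification_is_all_ones(self):
        peaks = self._peaks(10)
        rpp = np.arange(10)
        frac = binned_modification_fraction(peaks, rpp, peaks, n_bins=5)
        assert frac.tolist() == [1.0] * 5

    def test_no_modification_is_all_zeros(self):
        peaks = self._peaks(10)
        frac = binned_modification_fraction(peaks, np.arange(10), [], n_bins=5)
        assert frac.tolist() == [0.0] * 5

    def test_top_two_by_rpp_light_up_only_top_bin(self):
        peaks = self._peaks(10)
        rpp = np.arange(10)  # peaks 8, 9 are the strongest
        mods = [make_peak("chr1", 8000, 8200), make_peak("chr1", 9000, 9200)]
        frac = binned_modification_fraction(peaks, rpp, mods, n_bins=5)
        assert frac.tolist() == [0, 0, 0, 0, 1.0]

    def test_remainder_spread_to_lowest_bins(self):
        peaks = self._peaks(7)
        frac = binned_modification_fraction(peaks, np.arange(7), peaks, n_bins=5)
        # bins sized 2,2,1,1,1 - all fractions defined
        assert len(frac) == 5

    def test_fewer_peaks_than_bins_rejected(self):
        with pytest.raises(ValueError):
            binned_modification_fraction(self._peaks(3), np.arange(3), [], n_bins=5)
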