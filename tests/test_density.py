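from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from chipquant.density import (DensityConfig, ExtendedTags, count_tags,
                               density_table, extend_tag, fold_change_summary,
                               gene_density, rank_sum_test)
from chipquant.genome_model import (ChromSizes, GeneModel, GenomicRegion,
                                    TagAlignment, TagSet)


def tagset(positions, plus=True):
    pos = np.asarray(positions, dtype=np.int64)
    strands = np.full(pos.size, plus, dtype=bool)
    return TagSet({"chrT": (pos, strands)})


class TestExtendTag:
    def test_plus(self):
        r = extend_tag(TagAlignment("chr1", 100, "+"), 200)
        assert (r.start, r.end) == (100, 300)

    def test_minus_mirror(self):
        r = extend_tag(TagAlignment("chr1", 499, "-"), 200)
        assert (r.start, r.end) == (300, 500)

    def test_clipped_at_zero(self):
        r = extend_tag(TagAlignment("chr1", 50, "-"), 200)
        assert (r.start, r.end) == (0, 51)


class TestCounting:
    def test_overlap_vs_coverage(self, chrom_sizes):
        ext = ExtendedTags(tagset([100]), chrom_sizes, 200)
        region = GenomicRegion("chrT", 250, 400)
        assert count_tags(ext, region, "overlap") == 1
        assert count_tags(ext, region, "coverage") == 50

    def test_tag_outside(self, chrom_sizes):
        ext = ExtendedTags(tagset([100]), chrom_sizes, 200)
        assert count_tags(ext, GenomicRegion("chrT", 1000, 2000)) == 0

    def test_tiling_coverage_oracle(self, chrom_sizes):
        # 10 tags of extension 100 tile [1000, 2000) exactly once
        ext = ExtendedTags(tagset(range(1000, 2000, 100)), chrom_sizes, 100)
        region = GenomicRegion("chrT", 1000, 2000)
        assert count_tags(ext, region, "coverage") == region.length()
        assert count_tags(ext, region, "overlap") == 10


class TestGeneDensity:
    def gene(self):
        return GeneModel("g", GenomicRegion("chrT", 10_000, 11_000, "+"), 1.0)

    def test_formula(self, chrom_sizes):
        ext = ExtendedTags(tagset(np.linspace(10_100, 10_800, 100).astype(int)),
                           chrom_sizes, 200)
        rec = gene_density(self.gene(), ext, 1.0)
        assert rec.raw_count == 100
        assert rec.density == pytest.approx(1.0e7)

    def test_linearity_in_size_factor(self, chrom_sizes):
        ext = ExtendedTags(tagset(np.linspace(10_100, 10_800, 100).astype(int)),
                           chrom_sizes, 200)
        assert gene_density(self.gene(), ext, 2.0).density == pytest.approx(5.0e6)

    def test_zero_tags_zero_density(self, chrom_sizes):
        ext = ExtendedTags(tagset([50_000]), chrom_sizes, 200)
        rec = gene_density(self.gene(), ext, 1.0)
        assert rec.raw_count == 0 and rec.density == 0.0


class TestDensityTable:
    def make(self, chrom_sizes, wt_pos, ko_pos):
        genes = [GeneModel("a", GenomicRegion("chrT", 10_000, 11_000, "+"), 1.0),
                 GeneModel("b", GenomicRegion("chrT", 30_000, 31_000, "+"), 1.0)]
        tags = {"WT": tagset(wt_pos), "KO": tagset(ko_pos)}
        return density_table(genes, tags, {"WT": 1.0, "KO": 1.0}, chrom_sizes)

    def test_at_least_one_read_rule(self, chrom_sizes):
        # gene b has a read only in KO -> still kept in both tables
        df = self.make(chrom_sizes, [10_100], [10_200, 30_500])
        assert list(df.index) == ["a", "b"]
        assert df.loc["b", "raw_count_WT"] == 0

    def test_zero_everywhere_excluded(self, chrom_sizes):
        df = self.make(chrom_sizes, [10_100], [10_200])
        assert list(df.index) == ["a"]

    def test_missing_factor_rejected(self, chrom_sizes):
        genes = [GeneModel("a", GenomicRegion("chrT", 10_000, 11_000, "+"), 1.0)]
        with pytest.raises(KeyError):
            density_table(genes, {"WT": tagset([10_100])}, {}, chrom_sizes)


class TestFoldChange:
    def test_elementwise_scaling(self):
        wt = [1.0, 2.0, 5.0]
        assert fold_change_summary(wt, [6.5 * v for v in wt]) == pytest.approx(6.5)

    def test_identity(self):
        assert fold_change_summary([1, 2, 3], [1, 2, 3]) == 1.0

    def test_ratio_of_medians(self):
        assert fold_change_summary([1, 2, 3], [2, 2, 8]) == pytest.approx(1.0)

    def test_zero_wt_median_rejected(self):
        with pytest.raises(ValueError):
            fold_change_summary([0, 0, 0], [1, 2, 3])


def _ks_D(x, y):
    grid = np.sort(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
    return np.max(np.abs(fx - fy))


class TestRankSum:
    def test_equal_multisets(self):
        _, p = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)

    def test_separated_triples(self):
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_interleaved_pairs(self):
        _, p = rank_sum_test([1, 3], [2, 4])
        assert p == pytest.approx(2 / 3)

    def test_all_identical_values(self):
        _, p = rank_sum_test([5, 5], [5, 5, 5])
        assert p == 1.0

    def test_exact_path_matches_independent_implementation(self):
        """For tie-free data the enumeration must agree with the exact
        Mann-Whitney distribution (scipy's network algorithm)."""
        rng = np.random.default_rng(7)
        for n, m in [(2, 3), (3, 3), (4, 4), (5, 6), (6, 6)]:
            x = rng.normal(size=n)
            y = rng.normal(size=m) + 0.5
            _, p = rank_sum_test(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_asymptotic_matches_continuity_corrected_normal(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = rng.normal(size=40) + 0.3
        u, p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 use_continuity=True, method="asymptotic")
        assert (u, p) == (ref.statistic, pytest.approx(ref.pvalue))


def test_depth_invariance_of_density(chrom_sizes):
    """Duplicating every tag k-fold and scaling the size factor by k leaves
    the density unchanged to floating-point accuracy."""
    gene = GeneModel("g", GenomicRegion("chrT", 10_000, 14_000, "+"), 4.0)
    rng = np.random.default_rng(2)
    tags = tagset(rng.integers(9000, 15_000, size=500))
    d1 = gene_density(gene, ExtendedTags(tags, chrom_sizes, 200), 1.0).density
    d5 = gene_density(gene, ExtendedTags(tags.repeat(5), chrom_sizes, 200),
                      5.0).density
    assert d5 == pytest.approx(d1, rel=1e-12)
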