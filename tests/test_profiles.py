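import numpy as np
import pandas as pd
import pytest

from chipquant.density import ExtendedTags
from chipquant.genome_model import GeneModel, GenomicRegion, TagSet
from chipquant.profiles import (ProfileConfig, average_profile, gene_profile,
                                kmeans_profiles, metagene_matrix,
                                tss_bin_offsets, tss_profile)

from conftest import mirror_gene, mirror_tagset

CFG = ProfileConfig()


class TestGeneProfile:
    def test_flat_signal_gives_constant_bins(self, chrom_sizes, plus_gene,
                                             uniform_tags):
        ext = ExtendedTags(uniform_tags, chrom_sizes, 200)
        v = gene_profile(plus_gene, ext, 1.0, CFG)
        assert v.shape == (200,)
        assert np.allclose(v, 200.0)  # coverage 200 everywhere, sf 1

    def test_size_factor_scales_values(self, chrom_sizes, plus_gene, uniform_tags):
        ext = ExtendedTags(uniform_tags, chrom_sizes, 200)
        assert np.allclose(gene_profile(plus_gene, ext, 4.0, CFG), 50.0)

    def test_tss_pile_is_local(self, chrom_sizes, plus_gene):
        pos = np.full(500, plus_gene.tss(), dtype=np.int64)
        tags = TagSet({"chrT": (pos, np.ones(500, dtype=bool))})
        ext = ExtendedTags(tags, chrom_sizes, 200)
        v = gene_profile(plus_gene, ext, 1.0, CFG)
        # signal confined to the first body bins (bin width 50 bp here)
        assert v[20:24].sum() > 0
        assert v[30:].sum() == 0 and v[:19].sum() == 0

    def test_strand_mirror_invariance(self, chrom_sizes, plus_gene):
        L = chrom_sizes["chrT"]
        rng = np.random.default_rng(4)
        pos = rng.integers(12_000, 35_000, size=3000).astype(np.int64)
        plus = rng.random(3000) < 0.5
        tags = TagSet({"chrT": (pos, plus)})
        vp = gene_profile(plus_gene, ExtendedTags(tags, chrom_sizes, 200), 1.0, CFG)
        vm = gene_profile(mirror_gene(plus_gene, L),
                          ExtendedTags(mirror_tagset(tags, L), chrom_sizes, 200),
                          1.0, CFG)
        assert np.allclose(vp, vm)

    def test_short_gene_skipped(self, chrom_sizes, uniform_tags):
        g = GeneModel("tiny", GenomicRegion("chrT", 10_000, 10_100, "+"), 0.1)
        ext = ExtendedTags(uniform_tags, chrom_sizes, 200)
        assert gene_profile(g, ext, 1.0, CFG) is None

    def test_signal_conservation(self, chrom_sizes, plus_gene):
        rng = np.random.default_rng(9)
        pos = rng.integers(13_000, 35_000, size=2000).astype(np.int64)
        tags = TagSet({"chrT": (pos, rng.random(2000) < 0.5)})
        ext = ExtendedTags(tags, chrom_sizes, 200)
        sf = 1.7
        v = gene_profile(plus_gene, ext, sf, CFG)
        widths = np.concatenate([np.full(20, 250.0),
                                 np.diff(np.rint(np.arange(161) * 8000 / 160)),
                                 np.full(20, 250.0)])
        window = GenomicRegion("chrT", 15_000, 33_000)
        total = ext.coverage_sum(window)
        assert np.sum(v * widths * sf) == pytest.approx(total, rel=1e-9)


class TestAverageProfile:
    def test_single_gene_identity(self):
        v = np.arange(200.0)
        assert np.array_equal(average_profile([v]).values, v)

    def test_linearity(self):
        v = np.random.default_rng(0).normal(size=200)
        c = 3.0
        prof = average_profile([v, -v + 2 * c])
        assert np.allclose(prof.values, c)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_profile([])

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        vs = [rng.normal(size=200) for _ in range(7)]
        a = average_profile(vs).values
        b = average_profile(vs[::-1]).values
        assert np.allclose(a, b)


class TestTssProfile:
    def test_uniform_signal_flat(self, chrom_sizes, plus_gene, uniform_tags):
        ext = ExtendedTags(uniform_tags, chrom_sizes, 200)
        prof = tss_profile([plus_gene], ext, 1.0, CFG)
        assert prof.shape == (200,)
        assert np.allclose(prof, 200.0)

    def test_no_tags_zero_vector(self, chrom_sizes, plus_gene):
        ext = ExtendedTags(TagSet({}), chrom_sizes, 200)
        assert np.all(tss_profile([plus_gene], ext, 1.0, CFG) == 0)

    def test_offsets_centered(self):
        off = tss_bin_offsets(CFG)
        assert off[0] == -995 and off[-1] == 995 and off.size == 200

    def test_peak_bin_matches_planted_offset(self, chrom_sizes, plus_gene,
                                             minus_gene):
        # a pile of 200-bp fragments whose midpoints sit at TSS+60
        rng = np.random.default_rng(6)
        vecs = []
        for g in (plus_gene, minus_gene):
            sign = 1 if g.strand == "+" else -1
            centers = g.tss() + sign * 60 + rng.integers(-5, 6, size=4000)
            frag_start = centers - rng.integers(0, 200, size=4000)
            plus = rng.random(4000) < 0.5
            pos5 = np.where(plus, frag_start, frag_start + 199)
            tags = TagSet({"chrT": (pos5.astype(np.int64), plus)})
            ext = ExtendedTags(tags, chrom_sizes, 200)
            vecs.append(tss_profile([g], ext, 1.0, CFG))
        for v in vecs:
            peak = tss_bin_offsets(CFG)[np.argmax(v)]
            assert abs(peak - 60) <= 15  # within one 10-bp bin


class TestKmeans:
    def _matrix(self):
        rng = np.random.default_rng(5)
        high = np.tile(np.concatenate([np.zeros(180), np.full(20, 5.0)]), (50, 1))
        flat = np.zeros((50, 200))
        mat = np.vstack([high, flat]) + rng.normal(0, 0.05, (100, 200))
        return pd.DataFrame(mat, index=[f"g{i}" for i in range(100)])

    def test_k1_single_cluster(self):
        a = kmeans_profiles(self._matrix(), 1, seed=0)
        assert set(a.labels) == {1}

    def test_separated_clusters_label_ordering(self):
        a = kmeans_profiles(self._matrix(), 2, seed=0)
        # cluster 1 must be the high-signal group
        assert set(a.labels.iloc[:50]) == {1}
        assert set(a.labels.iloc[50:]) == {2}

    def test_duplicate_rows_same_label(self):
        mat = self._matrix()
        mat.iloc[99] = mat.iloc[0]
        a = kmeans_profiles(mat, 2, seed=1)
        assert a.labels.iloc[99] == a.labels.iloc[0]

    def test_determinism(self):
        m = self._matrix()
        a = kmeans_profiles(m, 2, seed=3)
        b = kmeans_profiles(m, 2, seed=3)
        assert a.labels.equals(b.labels) and a.wcss == b.wcss

    def test_k_exceeding_genes_rejected(self):
        with pytest.raises(ValueError):
            kmeans_profiles(self._matrix(), 101, seed=0)


def test_metagene_matrix_skips_short_genes(chrom_sizes, uniform_tags, plus_gene):
    tiny = GeneModel("tiny", GenomicRegion("chrT", 40_000, 40_120, "+"), 0.12)
    ext = ExtendedTags(uniform_tags, chrom_sizes, 200)
    mat = metagene_matrix([plus_gene, tiny], ext, 1.0, CFG)
    assert list(mat.index) == ["gplus"]
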