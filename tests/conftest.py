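import numpy as np
import pytest

from chipquant.genome_model import ChromSizes, GeneModel, GenomicRegion, TagSet


@pytest.fixture
def chrom_sizes():
    cs = ChromSizes()
    cs["chrT"] = 60_000
    return cs


@pytest.fixture
def plus_gene():
    return GeneModel("gplus", GenomicRegion("chrT", 20_000, 28_000, "+"), 8.0)


@pytest.fixture
def minus_gene():
    return GeneModel("gminus", GenomicRegion("chrT", 20_000, 28_000, "-"), 8.0)


@pytest.fixture
def uniform_tags(chrom_sizes):
    """One plus-strand tag starting at every position: extended coverage is
    exactly `extension_bp` everywhere at distance >= extension from the ends."""
    L = chrom_sizes["chrT"]
    pos = np.arange(L - 200, dtype=np.int64)
    return TagSet({"chrT": (pos, np.ones(pos.size, dtype=bool))})


def mirror_tagset(tags: TagSet, chrom_len: int) -> TagSet:
    """Reflect every tag through the chromosome midpoint and flip strands."""
    data = {}
    for chrom, (pos5, plus) in tags.data.items():
        data[chrom] = (chrom_len - 1 - pos5, ~plus)
    return TagSet(data)


def mirror_gene(gene: GeneModel, chrom_len: int) -> GeneModel:
    flipped = "-" if gene.strand == "+" else "+"
    span = GenomicRegion(gene.span.chrom, chrom_len - gene.span.end,
                         chrom_len - gene.span.start, flipped)
    return GeneModel(gene.gene_id + "_m", span, gene.median_tx_len_kb)
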