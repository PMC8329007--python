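"""Per-sample size factors.

Two estimators, matching the per-antibody split of the source protocol:
median-of-ratios over a region x sample count matrix (used with gene-distal
intergenic background regions, so that genuine genome-wide signal changes do
not distort the factors), and total-mapped-read factors (used for marks whose
global level is assumed stable).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .density import ExtendedTags
from .genome_model import ChromSizes, GenomicRegion, TagSet


def count_matrix(regions: Sequence[GenomicRegion],
                 sample_tags: Mapping[str, TagSet],
                 chrom_sizes: ChromSizes,
                 extension_bp: int = 200) -> pd.DataFrame:
    """Region x sample matrix of extended-tag overlap counts.

    Row index is ``chrom:start-end``; one column per sample.
    """
    cols = {}
    for sample, tags in sample_tags.items():
        ext = ExtendedTags(tags, chrom_sizes, extension_bp)
        cols[sample] = [ext.count_overlap(r) for r in regions]
    index = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    return pd.DataFrame(cols, index=index, dtype=np.int64)


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For every region with all-positive counts, each sample's count is
    divided by the row's geometric mean across samples; a sample's factor is
    the median of its ratios.  Regions containing any zero are dropped
    (their geometric mean is zero and the ratio undefined).  Factors are
    left on the estimator's natural scale (no anchoring); use
    :func:`rescale_to_reference` to pin one sample to 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("median_of_ratios needs at least 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no region with all-positive counts")
    mat = mat[positive]
    log_geomean = np.log(mat).mean(axis=1)
    ratios = np.exp(np.log(mat) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def total_read_factors(totals: Mapping[str, int]) -> pd.Series:
    """Depth factors from total mapped reads, centered so their geometric
    mean is 1 (samples treated symmetrically rather than anchored)."""
    keys = list(totals)
    vals = np.array([totals[k] for k in keys], dtype=float)
    if (vals <= 0).any():
        raise ValueError("all totals must be > 0")
    gmean = np.exp(np.log(vals).mean())
    return pd.Series(vals / gmean, index=keys, name="size_factor")


def rescale_to_reference(factors: pd.Series, reference: str) -> pd.Series:
    """Divide all factors by the reference sample's factor, so that the
    reference has factor exactly 1.  Relative densities are unchanged;
    absolute densities become comparable across re-estimations in which the
    reference sample itself did not change."""
    if reference not in factors.index:
        raise KeyError(f"unknown reference sample {reference!r}")
    return factors / factors[reference]


def write_factors(factors: pd.Series, path) -> None:
    factors.rename_axis("sample").to_frame().to_csv(path, sep="\t")


def read_factors(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["size_factor"]
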