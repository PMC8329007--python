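"""Tag extension, region counting, the density formula, fold summaries,
and the Wilcoxon rank-sum comparison of density distributions.

density = [(reads in region) / (region length in bp)] / (size_factor * 1e-8)

The 1e-8 constant puts densities for mammalian-scale libraries on a
convenient order of magnitude; it cancels from every ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import ChromSizes, GeneModel, GenomicRegion, TagAlignment, TagSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DensityConfig:
    extension_bp: int = 200
    scale_const: float = 1e-8
    min_reads_per_gene: int = 1
    counting_mode: str = "overlap"  # or "coverage"

    def __post_init__(self) -> None:
        if not self.extension_bp > 0:
            raise ValueError("extension_bp must be > 0")
        if not self.scale_const > 0:
            raise ValueError("scale_const must be > 0")
        if self.counting_mode not in ("overlap", "coverage"):
            raise ValueError(f"unknown counting_mode {self.counting_mode!r}")


@dataclass(frozen=True)
class DensityRecord:
    gene_id: str
    raw_count: float
    density: float


def extend_tag(tag: TagAlignment, extension_bp: int = 200,
               chrom_sizes: ChromSizes | None = None) -> GenomicRegion:
    """Extend a tag to ``extension_bp`` bp in the direction of the read,
    clipping at chromosome bounds when sizes are given."""
    if extension_bp <= 0:
        raise ValueError("extension_bp must be > 0")
    if tag.strand == "+":
        start, end = tag.pos5, tag.pos5 + extension_bp
    else:
        start, end = tag.pos5 - extension_bp + 1, tag.pos5 + 1
    start = max(start, 0)
    if chrom_sizes is not None:
        end = min(end, chrom_sizes[tag.chrom])
    return GenomicRegion(tag.chrom, start, end, tag.strand)


class ExtendedTags:
    """Extended-tag intervals of one sample, indexed for fast region queries.

    Supports overlap counting (how many extended tags touch a region) and
    coverage queries (summed per-bp overlap) via per-chromosome prefix sums.
    """

    def __init__(self, tags: TagSet, chrom_sizes: ChromSizes,
                 extension_bp: int = 200):
        if extension_bp <= 0:
            raise ValueError("extension_bp must be > 0")
        self.chrom_sizes = chrom_sizes
        self.extension_bp = extension_bp
        self.n_tags = len(tags)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._prefix: dict[str, np.ndarray] = {}
        for chrom, (pos5, plus) in tags.data.items():
            L = chrom_sizes[chrom]
            start = np.where(plus, pos5, pos5 - extension_bp + 1)
            end = np.where(plus, pos5 + extension_bp, pos5 + 1)
            start = np.clip(start, 0, L)
            end = np.clip(end, 0, L)
            keep = end > start
            self._starts[chrom] = np.sort(start[keep])
            self._ends[chrom] = np.sort(end[keep])

    def count_overlap(self, region: GenomicRegion) -> int:
        """Tags whose extended interval intersects the region by >= 1 bp."""
        starts = self._starts.get(region.chrom)
        if starts is None:
            return 0
        ends = self._ends[region.chrom]
        before_end = np.searchsorted(starts, region.end, side="left")
        ends_before = np.searchsorted(ends, region.start, side="right")
        return int(before_end - ends_before)

    def _prefix_for(self, chrom: str) -> np.ndarray:
        pref = self._prefix.get(chrom)
        if pref is None:
            L = self.chrom_sizes[chrom]
            diff = np.zeros(L + 1, dtype=np.int64)
            starts = self._starts.get(chrom)
            if starts is not None:
                np.add.at(diff, starts, 1)
                np.add.at(diff, self._ends[chrom], -1)
            cov = np.cumsum(diff[:-1])
            pref = np.concatenate(([0], np.cumsum(cov)))
            self._prefix[chrom] = pref
        return pref

    def coverage_sum(self, region: GenomicRegion) -> int:
        """Summed per-bp coverage of extended tags within the region."""
        pref = self._prefix_for(region.chrom)
        return int(pref[region.end] - pref[region.start])

    def bin_coverage_sums(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Coverage sums of consecutive bins given ascending bp edges."""
        pref = self._prefix_for(chrom)
        return np.diff(pref[np.asarray(edges, dtype=np.int64)])


def count_tags(ext: ExtendedTags, region: GenomicRegion,
               mode: str = "overlap") -> int:
    if mode == "overlap":
        return ext.count_overlap(region)
    if mode == "coverage":
        return ext.coverage_sum(region)
    raise ValueError(f"unknown counting mode {mode!r}")


def gene_density(gene: GeneModel, ext: ExtendedTags, size_factor: float,
                 cfg: DensityConfig = DensityConfig()) -> DensityRecord:
    """Density over the full annotated span (TSS..TES)."""
    if not size_factor > 0:
        raise ValueError("size_factor must be > 0")
    raw = count_tags(ext, gene.span, cfg.counting_mode)
    density = (raw / gene.length()) / (size_factor * cfg.scale_const)
    return DensityRecord(gene.gene_id, raw, density)


def density_table(genes: Sequence[GeneModel],
                  sample_tags: Mapping[str, TagSet],
                  factors: Mapping[str, float],
                  chrom_sizes: ChromSizes,
                  cfg: DensityConfig = DensityConfig(),
                  expressed_ids: set[str] | None = None) -> pd.DataFrame:
    """Per-gene densities for every sample of a comparison.

    Restricted to expressed genes (when a set is given) having at least
    ``cfg.min_reads_per_gene`` raw reads in at least one sample; the same
    gene set is kept across samples so fold summaries are matched.
    Columns: raw_count_<sample>, density_<sample>, indexed by gene id.
    """
    missing = [s for s in sample_tags if s not in factors]
    if missing:
        raise KeyError(f"no size factor for samples: {missing}")
    use = [g for g in genes
           if expressed_ids is None or g.gene_id in expressed_ids]
    data: dict[str, list] = {}
    for sample, tags in sample_tags.items():
        ext = ExtendedTags(tags, chrom_sizes, cfg.extension_bp)
        recs = [gene_density(g, ext, float(factors[sample]), cfg) for g in use]
        data[f"raw_count_{sample}"] = [r.raw_count for r in recs]
        data[f"density_{sample}"] = [r.density for r in recs]
    df = pd.DataFrame(data, index=[g.gene_id for g in use])
    df.index.name = "gene_id"
    raw_cols = [c for c in df.columns if c.startswith("raw_count_")]
    keep = (df[raw_cols] >= cfg.min_reads_per_gene).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("density_table: dropped %d genes below the read floor", n_dropped)
    return df[keep]


def fold_change_summary(wt: Iterable[float], ko: Iterable[float],
                        method: str = "median") -> float:
    """Cohort-level KO/WT fold change of densities over matched gene sets.

    Default is the ratio of medians (robust; matches a boxplot-style
    summary); ``method="mean"`` gives the ratio of means.
    """
    wt = np.asarray(list(wt), dtype=float)
    ko = np.asarray(list(ko), dtype=float)
    if wt.size != ko.size:
        raise ValueError("wt and ko must be matched gene sets")
    agg = {"median": np.median, "mean": np.mean}.get(method)
    if agg is None:
        raise ValueError(f"unknown method {method!r}")
    denom = agg(wt)
    if denom == 0:
        raise ValueError("WT summary density is zero")
    return float(agg(ko) / denom)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by exhaustive enumeration of all label assignments of the
    pooled sample, using the rank-sum of x (midranks for ties) as statistic."""
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n].sum()
    mu = ranks.sum() * n / (n + m)
    dev_obs = abs(w_obs - mu)
    hits = total = 0
    for idx in combinations(range(n + m), n):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_max_nm: int = 64) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (U statistic of x, p).  For n*m <= ``exact_max_nm`` the p-value
    is computed by exhaustive enumeration (valid with ties); otherwise the
    normal approximation with tie correction and 0.5 continuity correction
    is used, matching R's wilcox.test(correct = TRUE).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_stat = float(ranks[:n].sum() - n * (n + 1) / 2)
    if np.ptp(np.concatenate([x, y])) == 0:
        return u_stat, 1.0
    if n * m <= exact_max_nm:
        return u_stat, _rank_sum_exact_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             use_continuity=True, method="asymptotic")
    return u_stat, float(min(res.pvalue, 1.0))


def write_density_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def density_summary(df: pd.DataFrame, wt: str, ko: str) -> dict:
    """Median densities, fold change and Wilcoxon p for one comparison."""
    wt_d = df[f"density_{wt}"].to_numpy()
    ko_d = df[f"density_{ko}"].to_numpy()
    _, p = rank_sum_test(wt_d, ko_d)
    return {
        "n_genes": int(len(df)),
        f"median_density_{wt}": float(np.median(wt_d)),
        f"median_density_{ko}": float(np.median(ko_d)),
        "fold_change": fold_change_summary(wt_d, ko_d),
        "wilcoxon_p": p,
    }
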