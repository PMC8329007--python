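"""Derived gene sets and control regions.

Implements the expression filter (normalized reads per kb of transcript),
removal of neighboring gene units, selection of long gene-distal intergenic
regions used for background normalization, and the strand-aware TSS / gene
body windows used by the traveling-ratio statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_model import ChromSizes, DERecord, GeneModel, GenomicRegion

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Gene-filter thresholds.

    expr_min_density: expressed iff base_median / median_tx_len_kb is
        strictly greater than this (normalized reads per kb).
    tr_expr_min: same quantity, stricter, for the traveling-ratio cohort.
    tr_min_len_bp: traveling-ratio genes must be strictly longer than this.
    neighbor_window_bp: exclusion flank for non-neighboring gene sets.
    """

    expr_min_density: float = 10.0
    tr_expr_min: float = 100.0
    tr_min_len_bp: int = 1000
    neighbor_window_bp: int = 5000

    def __post_init__(self) -> None:
        for name in ("expr_min_density", "tr_expr_min", "tr_min_len_bp",
                     "neighbor_window_bp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class IntergenicConfig:
    """Selection rule for background intergenic regions: pieces of the
    genome farther than ``gene_buffer_bp`` from any gene and strictly longer
    than ``min_len_bp``."""

    min_len_bp: int = 100_000
    gene_buffer_bp: int = 10_000

    def __post_init__(self) -> None:
        if not self.min_len_bp > 0:
            raise ValueError("min_len_bp must be > 0")
        if self.gene_buffer_bp < 0:
            raise ValueError("gene_buffer_bp must be >= 0")


def filter_expressed(records: Iterable[DERecord], genes: Sequence[GeneModel],
                     cfg: FilterConfig = FilterConfig()) -> set[str]:
    """Gene ids whose base-median expression per kb of transcript strictly
    exceeds ``cfg.expr_min_density``."""
    by_id = {g.gene_id: g for g in genes}
    records = list(records)
    unknown = sorted({r.gene_id for r in records} - set(by_id))
    if unknown:
        raise KeyError(f"DE records for genes absent from annotation: {unknown}")
    kept = set()
    for r in records:
        if r.base_median / by_id[r.gene_id].median_tx_len_kb > cfg.expr_min_density:
            kept.add(r.gene_id)
    return kept


def remove_neighbors(genes: Sequence[GeneModel], window_bp: int = 5000) -> set[str]:
    """Gene ids whose span, expanded by ``window_bp`` on both sides, does not
    intersect any other gene's span.  Both members of a close pair are
    removed (symmetric rule)."""
    kept: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.span.start)
        starts = np.array([g.span.start for g in chrom_genes])
        ends = np.array([g.span.end for g in chrom_genes])
        for i, g in enumerate(chrom_genes):
            lo, hi = g.span.start - window_bp, g.span.end + window_bp
            # any other gene with start < hi and end > lo?
            clash = (starts < hi) & (ends > lo)
            clash[i] = False
            if not clash.any():
                kept.add(g.gene_id)
    return kept


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def select_intergenic(genes: Sequence[GeneModel], chrom_sizes: ChromSizes,
                      cfg: IntergenicConfig = IntergenicConfig()) -> list[GenomicRegion]:
    """Unstranded intergenic regions: the per-chromosome complement of gene
    spans expanded by ``gene_buffer_bp``, clipped to chromosome bounds, and
    kept only when strictly longer than ``min_len_bp``.  Output is disjoint
    and sorted (chromosomes in chrom_sizes order)."""
    buffered: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in genes:
        if g.span.chrom not in chrom_sizes:
            raise KeyError(f"gene {g.gene_id}: chromosome {g.span.chrom} "
                           "missing from chrom sizes")
        L = chrom_sizes[g.span.chrom]
        buffered[g.span.chrom].append(
            (max(0, g.span.start - cfg.gene_buffer_bp),
             min(L, g.span.end + cfg.gene_buffer_bp))
        )
    regions: list[GenomicRegion] = []
    for chrom, length in chrom_sizes.items():
        merged = _merge_intervals(buffered[chrom])
        cursor = 0
        for s, e in merged + [(length, length)]:
            if s - cursor > cfg.min_len_bp:
                regions.append(GenomicRegion(chrom, cursor, s, "."))
            cursor = max(cursor, e)
    return regions


def _oriented_window(gene: GeneModel, up: int, down: int,
                     name: str) -> GenomicRegion:
    if up + down <= 0:
        raise ValueError(f"{name}: window must have positive length")
    tss = gene.tss()
    if gene.strand == "+":
        start, end = tss - up, tss + down
    else:
        start, end = tss - down + 1, tss + up + 1
    if start < 0:
        log.warning("%s window of %s clipped at chromosome start", name, gene.gene_id)
        start = 0
    return GenomicRegion(gene.span.chrom, start, end, gene.strand)


def tss_window(gene: GeneModel, upstream_bp: int, downstream_bp: int) -> GenomicRegion:
    """Strand-aware window around the TSS covering ``upstream_bp`` bp before
    and ``downstream_bp`` bp after it (length = upstream + downstream)."""
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extents must be >= 0")
    return _oriented_window(gene, upstream_bp, downstream_bp, "TSS")


def body_window(gene: GeneModel, from_tss_bp: int, to_tss_bp: int) -> GenomicRegion:
    """Strand-aware gene-body window [TSS + from, TSS + to).  Deliberately
    NOT clipped at the TES: the window is defined relative to the TSS only,
    so short genes contribute signal from past their annotated end."""
    if to_tss_bp <= from_tss_bp:
        raise ValueError("to_tss_bp must exceed from_tss_bp")
    if gene.length() < to_tss_bp:
        log.debug("body window of %s extends %d bp past the TES",
                  gene.gene_id, to_tss_bp - gene.length())
    return _oriented_window(gene, -from_tss_bp, to_tss_bp, "body")
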