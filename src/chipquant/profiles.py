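"""Metagene and TSS-centered average profiles, and k-means clustering of
per-gene signal matrices.

The metagene scheme maps every gene to 200 bins: 20 fixed 250-bp bins over
the 5-kb upstream flank, 160 equal bins over the gene body (absolute bin
size depends on gene length), and 20 fixed bins over the downstream flank.
Bin values are per-bp coverage of 200-bp-extended tags, averaged over the
bin and divided by the sample's size factor, so bins of unequal width are
directly comparable and signal is conserved:
sum(bin value * bin width * size factor) == total coverage in the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .density import ExtendedTags
from .genome_model import GeneModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileConfig:
    n_body_bins: int = 160
    flank_bp: int = 5000
    n_flank_bins: int = 20
    tss_window_bp: int = 2000  # total width, centered on the TSS
    tss_bin_bp: int = 10

    def __post_init__(self) -> None:
        if self.n_body_bins < 1:
            raise ValueError("n_body_bins must be >= 1")
        if self.flank_bp % self.n_flank_bins:
            raise ValueError("flank_bp must be divisible by n_flank_bins")
        if self.tss_window_bp % (2 * self.tss_bin_bp):
            raise ValueError("tss window must split into whole, centered bins")

    @property
    def flank_bin_bp(self) -> int:
        return self.flank_bp // self.n_flank_bins

    @property
    def n_bins(self) -> int:
        return self.n_body_bins + 2 * self.n_flank_bins


@dataclass(frozen=True)
class MetageneProfile:
    """Cohort-averaged 5'->3' profile; indices [0, n_flank) are the upstream
    flank, then the body bins, then the downstream flank."""

    sample: str
    values: np.ndarray
    config: ProfileConfig


@dataclass(frozen=True)
class ClusterAssignment:
    labels: pd.Series  # gene id -> label in 1..k
    k: int
    seed: int
    wcss: float


def _metagene_edges(gene: GeneModel, cfg: ProfileConfig) -> np.ndarray:
    """Ascending genomic bp edges of the 200 bins (unclipped, 5'->3' for +)."""
    L = gene.length()
    s, e = gene.span.start, gene.span.end
    fb = cfg.flank_bin_bp
    left = s - cfg.flank_bp + fb * np.arange(cfg.n_flank_bins)
    body = s + np.rint(np.arange(cfg.n_body_bins) * L / cfg.n_body_bins).astype(np.int64)
    right = e + fb * np.arange(cfg.n_flank_bins)
    edges = np.concatenate([left, body, right, [e + cfg.flank_bp]])
    return edges


def gene_profile(gene: GeneModel, ext: ExtendedTags, size_factor: float,
                 cfg: ProfileConfig = ProfileConfig()) -> np.ndarray | None:
    """Per-gene 200-bin vector of normalized coverage per bp, oriented
    5'->3'.  Genes shorter than one bp per body bin return None (skipped by
    the cohort builders, with a logged count)."""
    if gene.length() < cfg.n_body_bins:
        return None
    edges = _metagene_edges(gene, cfg)
    widths = np.diff(edges).astype(float)
    L = ext.chrom_sizes[gene.span.chrom]
    clipped = np.clip(edges, 0, L)
    sums = ext.bin_coverage_sums(gene.span.chrom, clipped).astype(float)
    cw = np.diff(clipped).astype(float)
    vals = np.zeros_like(widths)
    nz = cw > 0
    vals[nz] = sums[nz] / cw[nz] / size_factor
    if gene.strand == "-":
        vals = vals[::-1]
    return vals


def average_profile(vectors: Sequence[np.ndarray], sample: str = "",
                    cfg: ProfileConfig = ProfileConfig()) -> MetageneProfile:
    """Unweighted arithmetic mean per bin over genes."""
    vectors = [v for v in vectors if v is not None]
    if not vectors:
        raise ValueError("no gene vectors to average")
    return MetageneProfile(sample, np.mean(np.asarray(vectors), axis=0), cfg)


def metagene_matrix(genes: Sequence[GeneModel], ext: ExtendedTags,
                    size_factor: float,
                    cfg: ProfileConfig = ProfileConfig()) -> pd.DataFrame:
    """Gene x bin matrix; genes too short for the bin scheme are dropped."""
    rows, ids, skipped = [], [], 0
    for g in genes:
        v = gene_profile(g, ext, size_factor, cfg)
        if v is None:
            skipped += 1
            continue
        rows.append(v)
        ids.append(g.gene_id)
    if skipped:
        log.info("metagene_matrix: skipped %d genes shorter than %d bp",
                 skipped, cfg.n_body_bins)
    if not rows:
        raise ValueError("no genes long enough to profile")
    df = pd.DataFrame(np.asarray(rows), index=ids)
    df.index.name = "gene_id"
    return df


def _tss_edges(gene: GeneModel, cfg: ProfileConfig) -> np.ndarray:
    half = cfg.tss_window_bp // 2
    offsets = np.arange(-half, half + 1, cfg.tss_bin_bp, dtype=np.int64)
    tss = gene.tss()
    if gene.strand == "+":
        return tss + offsets
    return (tss - offsets + 1)[::-1]


def tss_profile(genes: Sequence[GeneModel], ext: ExtendedTags,
                size_factor: float,
                cfg: ProfileConfig = ProfileConfig()) -> np.ndarray:
    """Cohort-mean normalized coverage in a window centered on each TSS,
    strand-oriented; index 0 starts at -tss_window_bp/2."""
    if not genes:
        raise ValueError("no genes")
    n_bins = cfg.tss_window_bp // cfg.tss_bin_bp
    acc = np.zeros(n_bins)
    for g in genes:
        edges = _tss_edges(g, cfg)
        L = ext.chrom_sizes[g.span.chrom]
        clipped = np.clip(edges, 0, L)
        sums = ext.bin_coverage_sums(g.span.chrom, clipped).astype(float)
        cw = np.diff(clipped).astype(float)
        vals = np.zeros(n_bins)
        nz = cw > 0
        vals[nz] = sums[nz] / cw[nz] / size_factor
        if g.strand == "-":
            vals = vals[::-1]
        acc += vals
    return acc / len(genes)


def tss_bin_offsets(cfg: ProfileConfig = ProfileConfig()) -> np.ndarray:
    """Center offset (bp from TSS) of each TSS-profile bin."""
    half = cfg.tss_window_bp // 2
    return np.arange(-half, half, cfg.tss_bin_bp) + cfg.tss_bin_bp / 2


def kmeans_profiles(matrix: pd.DataFrame, k: int, seed: int,
                    n_restarts: int = 10) -> ClusterAssignment:
    """k-means on linear bin values (squared Euclidean, k-means++ seeding),
    best of ``n_restarts`` by within-cluster sum of squares.  Labels are
    renumbered so cluster 1 has the highest mean signal."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds {len(matrix)} genes")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(matrix.to_numpy())
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw], index=matrix.index, name="cluster")
    return ClusterAssignment(labels, k, seed, float(km.inertia_))


def profile_bin_labels(cfg: ProfileConfig = ProfileConfig()) -> list[str]:
    """Human-readable genomic offset label per metagene bin."""
    labels = []
    fb = cfg.flank_bin_bp
    for i in range(cfg.n_flank_bins):
        labels.append(f"TSS{-cfg.flank_bp + i * fb}")
    for i in range(cfg.n_body_bins):
        labels.append(f"body{i}")
    for i in range(cfg.n_flank_bins):
        labels.append(f"TES+{i * fb}")
    return labels


def write_profile_tsv(profiles: Mapping[str, np.ndarray], path,
                      cfg: ProfileConfig = ProfileConfig()) -> None:
    df = pd.DataFrame(dict(profiles))
    df.insert(0, "offset", profile_bin_labels(cfg))
    df.index.name = "bin"
    df.to_csv(path, sep="\t")
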