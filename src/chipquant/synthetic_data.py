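"""Seeded generator of toy genomes, WT/KO ChIP tag sets and DE tables.

The generator plants the signal shapes the analysis is designed to measure:

* Pol II: a promoter-proximal peak of fragment midpoints at TSS+60 bp
  (Gaussian, sigma 25 bp) over a uniform gene-body rate from +300 bp on;
  the planted pausing ratio is the promoter:body per-bp intensity ratio.
* H2Bub1: a gene-body mark — a 150-bp 5' ramp up to a plateau covering the
  body, plus a bump (3x plateau, sigma 50 bp) with mode at TSS+300 bp.
  KO samples multiply each gene's H2Bub1 intensity by its planted fold.
* Pol II Ser2P: a body ramp increasing toward the TES, plus, for a planted
  subset of genes, a strong TES-centered bump (the basis of the two-cluster
  structure).
* A uniform intergenic background and per-sample library-depth factors,
  which the normalization stage must remove.

Reads are modelled as 200-bp fragments containing the signal point at a
uniform position, sequenced 50 bp single-end from a random end and emitted
as BED6.  All randomness flows from one seed through named substreams, so
every output is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de_tools import bh_adjust
from .genome_model import ChromSizes, GeneModel, GenomicRegion, TagSet

MARKS = ("PolII", "PolII_Ser2P", "H2Bub1")

_MARK_STREAM = {m: i + 1 for i, m in enumerate(MARKS)}


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    seed: int
    genes: pd.DataFrame  # indexed by gene_id; per-gene rates and folds
    samples: dict[str, dict]  # name -> {"depth": float, "condition": "WT"|"KO"}
    bg_rate: float = 0.002  # intergenic fragments per bp at depth 1
    promoter_offset: int = 60
    promoter_sigma: float = 25.0
    h2bub_mode: int = 300
    h2bub_sigma: float = 50.0
    h2bub_bump_amp: float = 3.0  # bump height relative to the body plateau
    h2bub_ramp_bp: int = 150
    body_from_bp: int = 300  # where the Pol II body rate starts
    tss_window: tuple[int, int] = (100, 300)  # promoter mass calibration
    fragment_len: int = 200
    read_len: int = 50

    def metadata(self) -> str:
        return f"seed={self.seed}"


def simulate_genome(n_genes: int, gene_len_range: tuple[int, int] = (2000, 8000),
                    gap_range: tuple[int, int] = (5000, 52000), seed: int = 0,
                    chrom: str = "chrS") -> tuple[list[GeneModel], ChromSizes]:
    """Non-overlapping genes with random lengths, gaps and strands on one
    chromosome; deterministic for a seed."""
    if gene_len_range[0] <= 0 or gap_range[0] <= 0:
        raise ValueError("length and gap ranges must be positive")
    if gene_len_range[0] > gene_len_range[1] or gap_range[0] > gap_range[1]:
        raise ValueError("ranges must be (low, high) with low <= high")
    rng = np.random.default_rng([seed, 101])
    genes: list[GeneModel] = []
    pos = 0
    for i in range(n_genes):
        pos += int(rng.integers(gap_range[0], gap_range[1] + 1))
        length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        span = GenomicRegion(chrom, pos, pos + length, strand)
        genes.append(GeneModel(f"g{i + 1:04d}", span, length / 1000.0))
        pos += length
    pos += int(rng.integers(gap_range[0], gap_range[1] + 1))
    sizes = ChromSizes()
    sizes[chrom] = pos
    return genes, sizes


def simulate_truth(genes: Sequence[GeneModel], seed: int, *,
                   body_rate_range: tuple[float, float] = (0.05, 0.2),
                   h2bub_fold: float | Sequence[float] = 6.5,
                   pausing_ratio: float | Sequence[float] = 4.0,
                   ser2p_tes_boost: float = 4.0,
                   frac_tes_cluster: float = 0.5,
                   depths: Mapping[str, float] | None = None,
                   bg_rate: float = 0.002,
                   **shape_kwargs) -> SimTruth:
    """Assign per-gene rates, folds and pausing ratios, and per-sample
    depths.  Sample names starting with "KO" are knockout; others wild type.
    """
    if depths is None:
        depths = {"WT": 1.0, "KO": 1.0}
    rng = np.random.default_rng([seed, 202])
    n = len(genes)
    body_rate = rng.uniform(*body_rate_range, size=n)
    tes_cluster = rng.random(n) < frac_tes_cluster
    df = pd.DataFrame({
        "chrom": [g.span.chrom for g in genes],
        "start": [g.span.start for g in genes],
        "end": [g.span.end for g in genes],
        "strand": [g.strand for g in genes],
        "length": [g.length() for g in genes],
        "tx_len_kb": [g.median_tx_len_kb for g in genes],
        "body_rate": body_rate,
        "h2bub_fold": np.broadcast_to(np.asarray(h2bub_fold, dtype=float), (n,)),
        "pausing_ratio": np.broadcast_to(np.asarray(pausing_ratio, dtype=float), (n,)),
        "ser2p_tes_boost": np.where(tes_cluster, ser2p_tes_boost, 0.0),
        "base_median": body_rate * 2e4,
    }, index=pd.Index([g.gene_id for g in genes], name="gene_id"))
    samples = {name: {"depth": float(d),
                      "condition": "KO" if name.upper().startswith("KO") else "WT"}
               for name, d in depths.items()}
    return SimTruth(seed=seed, genes=df, samples=samples, bg_rate=bg_rate,
                    **shape_kwargs)


def _centers_to_tags(centers: np.ndarray, truth: SimTruth, chrom_len: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fragment midpoint positions -> stranded read 5' positions."""
    c = np.rint(centers).astype(np.int64)
    frag_start = c - rng.integers(0, truth.fragment_len, size=c.size)
    plus = rng.random(c.size) < 0.5
    pos5 = np.where(plus, frag_start, frag_start + truth.fragment_len - 1)
    pos5 = np.clip(pos5, 0, chrom_len - 1)
    return pos5, plus


def _gene_centers(truth: SimTruth, row, mark: str, depth: float, is_ko: bool,
                  rng: np.random.Generator) -> np.ndarray:
    """Fragment-center offsets (bp from TSS, transcription direction) for
    one gene, one mark, one sample."""
    L = int(row.length)
    b = float(row.body_rate) * depth
    out = []
    if mark == "PolII":
        # promoter peak: per-bp intensity over the TSS window = ratio * body
        tss_len = truth.tss_window[0] + truth.tss_window[1]
        n_prom = rng.poisson(float(row.pausing_ratio) * b * tss_len)
        out.append(rng.normal(truth.promoter_offset, truth.promoter_sigma, n_prom))
        n_body = rng.poisson(b * max(L - truth.body_from_bp, 0))
        out.append(rng.uniform(truth.body_from_bp, L, n_body))
    elif mark == "H2Bub1":
        h = b * (float(row.h2bub_fold) if is_ko else 1.0)
        ramp = truth.h2bub_ramp_bp
        n_ramp = rng.poisson(h * ramp / 2.0)
        out.append(ramp * np.sqrt(rng.random(n_ramp)))
        n_plateau = rng.poisson(h * max(L - ramp, 0))
        out.append(rng.uniform(ramp, L, n_plateau))
        n_bump = rng.poisson(h * truth.h2bub_bump_amp
                             * truth.h2bub_sigma * np.sqrt(2 * np.pi))
        out.append(rng.normal(truth.h2bub_mode, truth.h2bub_sigma, n_bump))
    elif mark == "PolII_Ser2P":
        # rising body signal: 0.5*b uniform + 0.5*b triangular toward the TES
        n_unif = rng.poisson(0.5 * b * L)
        out.append(rng.uniform(0, L, n_unif))
        n_tri = rng.poisson(0.25 * b * L)
        out.append(L * np.sqrt(rng.random(n_tri)))
        boost = float(row.ser2p_tes_boost)
        if boost > 0:
            sigma = 300.0
            n_tes = rng.poisson(b * boost * sigma * np.sqrt(2 * np.pi))
            out.append(rng.normal(L, sigma, n_tes))
    else:
        raise ValueError(f"unknown mark {mark!r}")
    return np.concatenate(out) if out else np.empty(0)


def simulate_tags(truth: SimTruth, chrom_sizes: ChromSizes, sample: str,
                  mark: str) -> TagSet:
    """Tag set of one (sample, mark) library: gene signal per the planted
    shapes plus uniform intergenic background, Poisson counts throughout."""
    if sample not in truth.samples:
        raise KeyError(f"unknown sample {sample!r}")
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    meta = truth.samples[sample]
    depth = meta["depth"]
    is_ko = meta["condition"] == "KO"
    sidx = sorted(truth.samples).index(sample)
    rng = np.random.default_rng([truth.seed, 303, sidx, _MARK_STREAM[mark]])

    per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in chrom_sizes}
    per_chrom_strand: dict[str, list[np.ndarray]] = {c: [] for c in chrom_sizes}

    # background, uniform over each chromosome
    for chrom, L in chrom_sizes.items():
        n_bg = rng.poisson(truth.bg_rate * depth * L)
        pos5, plus = _centers_to_tags(rng.uniform(0, L, n_bg), truth, L, rng)
        per_chrom[chrom].append(pos5)
        per_chrom_strand[chrom].append(plus)

    for row in truth.genes.itertuples():
        offsets = _gene_centers(truth, row, mark, depth, is_ko, rng)
        if offsets.size == 0:
            continue
        if row.strand == "+":
            centers = row.start + offsets
        else:
            centers = row.end - 1 - offsets
        L = chrom_sizes[row.chrom]
        centers = np.clip(centers, 0, L - 1)
        pos5, plus = _centers_to_tags(centers, truth, L, rng)
        per_chrom[row.chrom].append(pos5)
        per_chrom_strand[row.chrom].append(plus)

    data = {}
    for chrom in chrom_sizes:
        if per_chrom[chrom]:
            pos5 = np.concatenate(per_chrom[chrom])
            plus = np.concatenate(per_chrom_strand[chrom])
            order = np.argsort(pos5, kind="stable")
            data[chrom] = (pos5[order], plus[order])
    return TagSet(data)


def simulate_de_table(n_genes: int, frac_up: float, frac_down: float,
                      effect_log2fc: float, seed: int,
                      noise_sd: float = 0.15,
                      base_median_logmean: float = 5.0) -> pd.DataFrame:
    """DE result table with planted truth labels.

    Null genes draw log2fc from centered noise and p from Uniform(0,1);
    affected genes draw log2fc around +/- effect_log2fc with tiny p-values.
    padj is Benjamini-Hochberg over the whole table.
    """
    if not (0 <= frac_up <= 1 and 0 <= frac_down <= 1 and frac_up + frac_down <= 1):
        raise ValueError("fractions must lie in [0,1] and sum to <= 1")
    rng = np.random.default_rng([seed, 404])
    n_up = int(round(n_genes * frac_up))
    n_down = int(round(n_genes * frac_down))
    truth = np.array(["up"] * n_up + ["down"] * n_down
                     + ["null"] * (n_genes - n_up - n_down))
    rng.shuffle(truth)
    log2fc = rng.normal(0.0, noise_sd, n_genes)
    log2fc[truth == "up"] += effect_log2fc
    log2fc[truth == "down"] -= effect_log2fc
    pvalue = rng.uniform(0, 1, n_genes)
    affected = truth != "null"
    pvalue[affected] = 10.0 ** (-rng.uniform(4, 10, int(affected.sum())))
    df = pd.DataFrame({
        "gene_id": [f"g{i + 1:04d}" for i in range(n_genes)],
        "base_median": np.exp(rng.normal(base_median_logmean, 1.0, n_genes)),
        "log2fc": log2fc,
        "pvalue": pvalue,
        "padj": bh_adjust(pvalue),
        "truth": truth,
    })
    return df


def write_truth_tsv(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {truth.metadata()}\n")
        truth.genes.to_csv(fh, sep="\t")


def de_table_for_truth(truth: SimTruth) -> pd.DataFrame:
    """Expression table consistent with the planted rates, shaped like an
    upstream DE result (no differential test implied: padj left missing)."""
    g = truth.genes
    return pd.DataFrame({
        "gene_id": g.index,
        "base_median": g["base_median"].to_numpy(),
        "log2fc": 0.0,
        "padj": np.nan,
        "median_tx_len_kb": g["tx_len_kb"].to_numpy(),
    })
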