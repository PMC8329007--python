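"""End-to-end analysis workflows on simulated studies.

Each function runs the full pipeline path it names — generator, intergenic
size factors, densities, profiles, traveling ratio, DE bookkeeping — and
returns the measured quantity next to the planted truth, so recovery can be
checked without touching any internal state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .annotation_ops import FilterConfig, IntergenicConfig, select_intergenic
from .de_tools import DEConfig, classify_de, fold_bin_counts
from .density import DensityConfig, density_table, fold_change_summary
from .genome_model import ChromSizes, GeneModel, GenomicRegion, TagSet, de_records
from .normalization import count_matrix, median_of_ratios, rescale_to_reference
from .pausing import (PausingConfig, cohort_traveling_ratios, ks_two_sample,
                      traveling_ratio, tr_gene_set)
from .profiles import ProfileConfig, kmeans_profiles, metagene_matrix, tss_bin_offsets, tss_profile
from .density import ExtendedTags
from .synthetic_data import de_table_for_truth, simulate_genome, simulate_tags, simulate_truth

# Study-scale constants for the simulated genome: a 300-gene, ~10-Mb toy
# chromosome.  The intergenic selector thresholds are scaled from the
# mammalian-genome values (100 kb regions, 10 kb buffer on 2.5 Gb) by
# roughly the genome-size ratio so that gene deserts of the toy genome
# qualify; the config *defaults* remain the full-scale values.
SIM_N_GENES = 300
SIM_GENE_LEN_RANGE = (2000, 8000)
SIM_GAP_RANGE = (5000, 52000)
SIM_INTERGENIC = IntergenicConfig(min_len_bp=20_000, gene_buffer_bp=5_000)


def simulate_study(seed: int, n_genes: int = SIM_N_GENES,
                   gene_len_range=SIM_GENE_LEN_RANGE,
                   gap_range=SIM_GAP_RANGE, **truth_kwargs):
    genes, chrom_sizes = simulate_genome(n_genes, gene_len_range, gap_range, seed)
    truth = simulate_truth(genes, seed, **truth_kwargs)
    return genes, chrom_sizes, truth


def intergenic_size_factors(genes, chrom_sizes, sample_tags,
                            icfg: IntergenicConfig = SIM_INTERGENIC,
                            extension_bp: int = 200) -> pd.Series:
    """Intergenic background regions -> count matrix -> median-of-ratios."""
    regions = select_intergenic(genes, chrom_sizes, icfg)
    if not regions:
        raise ValueError("no intergenic regions pass the length filter")
    counts = count_matrix(regions, sample_tags, chrom_sizes, extension_bp)
    return median_of_ratios(counts)


def fold_recovery_experiment(fold: float, seed: int,
                             depth_confound: float = 3.0,
                             n_genes: int = SIM_N_GENES) -> dict:
    """Plant a global KO/WT H2Bub1 fold plus a library-depth confound and
    recover the fold through intergenic normalization and the density
    formula.  The depth confound must not leak into the estimate."""
    genes, chrom_sizes, truth = simulate_study(
        seed, n_genes=n_genes, h2bub_fold=fold,
        depths={"WT": 1.0, "KO": depth_confound})
    tags = {s: simulate_tags(truth, chrom_sizes, s, "H2Bub1")
            for s in ("WT", "KO")}
    factors = intergenic_size_factors(genes, chrom_sizes, tags)
    dens = density_table(genes, tags, factors, chrom_sizes, DensityConfig())
    recovered = fold_change_summary(dens["density_WT"], dens["density_KO"])
    return {"planted_fold": fold, "recovered_fold": recovered,
            "n_genes": int(len(dens)),
            "factor_ratio": float(factors["KO"] / factors["WT"])}


def depth_invariance_experiment(seed: int, k: int = 5,
                                n_genes: int = 100) -> dict:
    """Duplicate one sample's tags k-fold, re-estimate intergenic factors
    (re-anchored to the untouched reference sample) and measure the largest
    relative change in any gene density."""
    genes, chrom_sizes, truth = simulate_study(seed, n_genes=n_genes,
                                               h2bub_fold=2.0)
    tags = {s: simulate_tags(truth, chrom_sizes, s, "H2Bub1")
            for s in ("WT", "KO")}
    cfg = DensityConfig()

    def _densities(sample_tags):
        f = rescale_to_reference(
            intergenic_size_factors(genes, chrom_sizes, sample_tags), "WT")
        return f, density_table(genes, sample_tags, f, chrom_sizes, cfg)

    f0, d0 = _densities(tags)
    f1, d1 = _densities({"WT": tags["WT"], "KO": tags["KO"].repeat(k)})
    cols = ["density_WT", "density_KO"]
    a, b = d0[cols].to_numpy(), d1[cols].to_numpy()
    nz = a != 0
    max_rel = float(np.max(np.abs(b[nz] - a[nz]) / a[nz])) if nz.any() else 0.0
    return {"k": k, "max_rel_density_change": max_rel,
            "factor_ratio": float(f1["KO"] / f0["KO"])}


def tr_recovery_experiment(pausing_ratio: float, seed: int,
                           n_genes: int = SIM_N_GENES) -> dict:
    """Plant a promoter:body per-bp intensity ratio and recover it as the
    cohort median traveling ratio of the filtered gene set."""
    genes, chrom_sizes, truth = simulate_study(seed, n_genes=n_genes,
                                               pausing_ratio=pausing_ratio)
    tags = simulate_tags(truth, chrom_sizes, "WT", "PolII")
    recs = de_records(de_table_for_truth(truth))
    eligible = tr_gene_set(genes, recs, FilterConfig())
    cohort = [g for g in genes if g.gene_id in eligible]
    trs, excluded = cohort_traveling_ratios(cohort, tags)
    return {"planted_ratio": pausing_ratio,
            "median_tr": float(trs.median()),
            "n_genes": int(trs.size), "n_excluded": excluded}


def uniform_tr_value(gene_length: int = 5000, offset: int = 10_000) -> float:
    """TR of a synthetic gene with exactly one tag per bp everywhere: the
    flat-signal identity check (must be exactly 1)."""
    chrom_sizes = ChromSizes()
    chrom_sizes["chrU"] = offset * 2 + gene_length
    span = GenomicRegion("chrU", offset, offset + gene_length, "+")
    gene = GeneModel("uniform", span, gene_length / 1000.0)
    pos = np.arange(chrom_sizes["chrU"], dtype=np.int64)
    tags = TagSet({"chrU": (pos, np.ones(pos.size, dtype=bool))})
    return float(traveling_ratio(gene, tags))


def ks_null_calibration(seed: int, n_rep: int = 200, n: int = 100,
                        alpha: float = 0.05) -> dict:
    """Draw WT/KO traveling-ratio cohorts from the same lognormal
    distribution and measure the KS rejection rate at ``alpha``."""
    rng = np.random.default_rng([seed, 505])
    rejected = 0
    for _ in range(n_rep):
        x = rng.lognormal(np.log(3.0), 0.5, n)
        y = rng.lognormal(np.log(3.0), 0.5, n)
        if ks_two_sample(x, y).p <= alpha:
            rejected += 1
    return {"n_rep": n_rep, "fraction_rejected": rejected / n_rep,
            "alpha": alpha}


def peak_offset_experiment(mark: str, seed: int, n_genes: int = SIM_N_GENES,
                           depth: float = 3.0,
                           cfg: ProfileConfig = ProfileConfig()) -> dict:
    """Argmax offset (bp from TSS) of the cohort TSS profile for one mark."""
    genes, chrom_sizes, truth = simulate_study(
        seed, n_genes=n_genes, depths={"WT": depth})
    tags = simulate_tags(truth, chrom_sizes, "WT", mark)
    ext = ExtendedTags(tags, chrom_sizes, 200)
    prof = tss_profile(genes, ext, 1.0, cfg)
    offsets = tss_bin_offsets(cfg)
    planted = {"PolII": truth.promoter_offset, "H2Bub1": truth.h2bub_mode}
    return {"mark": mark, "argmax_offset_bp": float(offsets[int(np.argmax(prof))]),
            "planted_offset_bp": float(planted.get(mark, np.nan)),
            "bin_bp": cfg.tss_bin_bp}


def cluster_recovery_experiment(seed: int, n_genes: int = 100,
                                depth: float = 3.0) -> dict:
    """k-means (k=2) on Ser2P metagene rows of genes half of which carry a
    planted TES-proximal signal; compared with the planted labels by
    adjusted Rand index.  Expression is held uniform across genes so the
    planted TES signal is the only between-gene structure (well-separated
    clusters); heterogeneous expression would dominate linear-scale k-means."""
    genes, chrom_sizes, truth = simulate_study(
        seed, n_genes=n_genes, depths={"WT": depth}, ser2p_tes_boost=5.0,
        body_rate_range=(0.1, 0.1))
    tags = simulate_tags(truth, chrom_sizes, "WT", "PolII_Ser2P")
    ext = ExtendedTags(tags, chrom_sizes, 200)
    mat = metagene_matrix(genes, ext, 1.0)
    assign = kmeans_profiles(mat, k=2, seed=seed)
    planted = (truth.genes.loc[assign.labels.index, "ser2p_tes_boost"] > 0)
    ari = adjusted_rand_score(planted.to_numpy(), assign.labels.to_numpy())
    return {"ari": float(ari), "k": 2, "n_genes": int(len(mat))}


def de_recovery_experiment(seed: int, n_genes: int = 1000,
                           effect_log2fc: float = 6.0) -> dict:
    """Planted up/down sets must be recovered exactly at large effect."""
    from .synthetic_data import simulate_de_table
    df = simulate_de_table(n_genes, 0.05, 0.05, effect_log2fc, seed,
                           noise_sd=0.05)
    up, down = classify_de(df, DEConfig())
    true_up = set(df.loc[df["truth"] == "up", "gene_id"])
    true_down = set(df.loc[df["truth"] == "down", "gene_id"])
    bins = fold_bin_counts(df, DEConfig())
    return {
        "up_exact": up == true_up, "down_exact": down == true_down,
        "n_up": len(up), "n_down": len(down),
        "fold_bins_monotone": bool((bins.diff().dropna() <= 0).all()),
    }
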