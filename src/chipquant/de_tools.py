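"""Bookkeeping over externally produced differential-expression tables:
significance thresholding, cumulative fold-magnitude bins, set overlaps and
cross-study log2 fold-change correlation.

The DE model fit itself (dispersion estimation, Wald test) is consumed as an
input table of (gene_id, base_median, log2fc, padj); it is never refit here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEConfig:
    padj_max: float = 0.05
    min_abs_log2fc: float = 1.0
    fold_bins: tuple[float, ...] = (2, 4, 8, 32, 64, 128, 256)

    def __post_init__(self) -> None:
        bins = self.fold_bins
        if any(b <= 1 for b in bins) or any(a >= b for a, b in zip(bins, bins[1:])):
            raise ValueError("fold_bins must be strictly increasing and > 1")


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([{"gene_id": r.gene_id, "base_median": r.base_median,
                          "log2fc": r.log2fc, "padj": r.padj}
                         for r in records])


def classify_de(records, cfg: DEConfig = DEConfig()) -> tuple[set[str], set[str]]:
    """(up, down) gene-id sets: padj <= padj_max and log2fc beyond
    +/- min_abs_log2fc, boundaries inclusive.  Records with a missing padj
    are skipped (counted in the log)."""
    df = _as_frame(records)
    missing = df["padj"].isna()
    if missing.any():
        log.info("classify_de: skipped %d records without padj",
                 int(missing.sum()))
    df = df[~missing]
    sig = df["padj"] <= cfg.padj_max
    up = set(df.loc[sig & (df["log2fc"] >= cfg.min_abs_log2fc), "gene_id"])
    down = set(df.loc[sig & (df["log2fc"] <= -cfg.min_abs_log2fc), "gene_id"])
    return up, down


def fold_bin_counts(records, cfg: DEConfig = DEConfig()) -> pd.Series:
    """Cumulative counts of significant genes per fold-magnitude bin: a gene
    with padj <= padj_max and fold magnitude 2^|log2fc| >= bin counts in
    every bin up to its magnitude, so counts are non-increasing."""
    df = _as_frame(records)
    df = df[df["padj"].notna()]
    sig = df[df["padj"] <= cfg.padj_max]
    mag = np.power(2.0, sig["log2fc"].abs().to_numpy())
    counts = {b: int((mag >= b).sum()) for b in cfg.fold_bins}
    s = pd.Series(counts, name="n_genes")
    s.index.name = "min_fold"
    return s


def overlap_counts(set_a: set, set_b: set) -> tuple[int, int, int]:
    """(only A, shared, only B) — Venn-diagram arithmetic."""
    shared = set_a & set_b
    return len(set_a - shared), len(shared), len(set_b - shared)


def log2fc_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
    """Pearson r of log2 fold changes over genes present in both tables."""
    a = _as_frame(table_a).set_index("gene_id")["log2fc"]
    b = _as_frame(table_b).set_index("gene_id")["log2fc"]
    joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
    joined = joined[np.isfinite(joined).all(axis=1)]
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} shared genes with finite "
                         "log2fc; need >= 3")
    r, _ = stats.pearsonr(joined["a"], joined["b"])
    return float(r)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (for synthetic fixtures whose
    raw p-values come from the generator rather than an external fitter)."""
    p = np.asarray(list(pvalues), dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def write_classification(records, up: set[str], down: set[str], path) -> None:
    df = _as_frame(records).copy()
    df["class"] = "ns"
    df.loc[df["gene_id"].isin(up), "class"] = "up"
    df.loc[df["gene_id"].isin(down), "class"] = "down"
    df.to_csv(path, sep="\t", index=False)
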