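"""Pol II traveling ratio (pausing index) and its cohort-level comparison.

The traveling ratio of a gene is the ratio of normalized Pol II signal in a
TSS window (-100..+300 bp around the TSS) to that in an early gene-body
window (TSS+300..TSS+2000 bp).  Window counts use read 5' ends (no
extension), so a perfectly uniform per-bp signal gives TR = 1 exactly and
the two windows cannot double-count a read.  Cohorts are compared by the
two-sample Kolmogorov-Smirnov maximal ECDF distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_ops import FilterConfig, body_window, tss_window
from .genome_model import DERecord, GeneModel, TagSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PausingConfig:
    tss_up_bp: int = 100
    tss_down_bp: int = 300
    body_from_bp: int = 300
    body_to_bp: int = 2000
    ratio_basis: str = "density"  # or "count"

    def __post_init__(self) -> None:
        if self.body_to_bp <= self.body_from_bp:
            raise ValueError("body_to_bp must exceed body_from_bp")
        if self.ratio_basis not in ("density", "count"):
            raise ValueError(f"unknown ratio_basis {self.ratio_basis!r}")

    @property
    def tss_len(self) -> int:
        return self.tss_up_bp + self.tss_down_bp

    @property
    def body_len(self) -> int:
        return self.body_to_bp - self.body_from_bp


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n: int
    m: int


def tr_gene_set(genes: Sequence[GeneModel], de_records: Sequence[DERecord],
                cfg: FilterConfig = FilterConfig()) -> set[str]:
    """Genes eligible for the traveling ratio: expression per kb of
    transcript strictly above ``tr_expr_min`` and span strictly longer than
    ``tr_min_len_bp``."""
    by_id = {g.gene_id: g for g in genes}
    kept = set()
    for r in de_records:
        g = by_id.get(r.gene_id)
        if g is None:
            continue
        if (r.base_median / g.median_tx_len_kb > cfg.tr_expr_min
                and g.length() > cfg.tr_min_len_bp):
            kept.add(r.gene_id)
    return kept


def traveling_ratio(gene: GeneModel, tags: TagSet, size_factor: float = 1.0,
                    cfg: PausingConfig = PausingConfig()) -> float | None:
    """TR of one gene, or None when the body window holds no reads.

    The size factor divides both window signals and therefore cancels; it is
    accepted so call sites can treat TR like any other normalized quantity.
    """
    if not size_factor > 0:
        raise ValueError("size_factor must be > 0")
    tss_n = tags.count_in(tss_window(gene, cfg.tss_up_bp, cfg.tss_down_bp))
    body_n = tags.count_in(body_window(gene, cfg.body_from_bp, cfg.body_to_bp))
    if body_n == 0:
        return None
    if cfg.ratio_basis == "count":
        return tss_n / body_n
    return (tss_n / cfg.tss_len) / (body_n / cfg.body_len)


def cohort_traveling_ratios(genes: Sequence[GeneModel], tags: TagSet,
                            size_factor: float = 1.0,
                            cfg: PausingConfig = PausingConfig()
                            ) -> tuple[pd.Series, int]:
    """Per-gene TRs plus the count of genes excluded for an empty body
    window."""
    vals, ids, excluded = [], [], 0
    for g in genes:
        tr = traveling_ratio(g, tags, size_factor, cfg)
        if tr is None:
            excluded += 1
            continue
        vals.append(tr)
        ids.append(g.gene_id)
    if excluded:
        log.info("traveling ratio: excluded %d genes with empty body window",
                 excluded)
    s = pd.Series(vals, index=ids, name="traveling_ratio")
    s.index.name = "gene_id"
    return s, excluded


def ecdf_points(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Support points and ECDF values for plotting cumulative TR curves."""
    x = np.sort(np.asarray(values, dtype=float))
    return x, np.arange(1, x.size + 1) / x.size


def ks_two_sample(x: Sequence[float], y: Sequence[float],
                  exact_max_nm: int = 10_000) -> KSResult:
    """Two-sample KS test: D = sup |ECDF_x - ECDF_y| plus a two-sided p.

    p is computed from the exact null distribution when n*m <= the cutoff
    and the samples share no tied value; otherwise the asymptotic
    Kolmogorov distribution with effective size nm/(n+m) is used (ties make
    the exact distribution invalid, so the switch is logged).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    cross_ties = np.intersect1d(x, y).size > 0
    if x.size * y.size <= exact_max_nm and not cross_ties:
        method = "exact"
    else:
        if cross_ties and x.size * y.size <= exact_max_nm:
            log.warning("ks_two_sample: inter-sample ties; using the "
                        "asymptotic distribution")
        method = "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return KSResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                    int(x.size), int(y.size))


def tr_summary(trs: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Cohort summary (n, median TR) per sample plus pairwise KS rows."""
    rows = []
    names = list(trs)
    for name in names:
        s = trs[name]
        rows.append({"comparison": name, "n": int(s.size),
                     "median_tr": float(s.median()), "D": np.nan, "p": np.nan})
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ks = ks_two_sample(trs[a].to_numpy(), trs[b].to_numpy())
            rows.append({"comparison": f"{a}_vs_{b}", "n": ks.n + ks.m,
                         "median_tr": np.nan, "D": ks.D, "p": ks.p})
    return pd.DataFrame(rows)
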