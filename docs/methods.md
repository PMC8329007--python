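# Methods

## Scope and data model

All coordinates are 0-based half-open internally; GTF input (1-based closed)
is converted at the file boundary. A tag is a stranded 5' position; the 5'
end of a minus-strand BED interval [start, end) is end−1. Genes are stranded
spans with a median transcript length in kb (taken from an expression table
when available, otherwise span length / 1000). Alignment itself is out of
scope: tags arrive as BED6 (a BAM can be converted with
`bedtools bamtobed`).

## Normalization

`median_of_ratios` implements the median-of-ratios estimator over a
region × sample count matrix. Regions containing any zero count are dropped
(their geometric mean is zero). Factors are reported on the estimator's
natural scale — ratios to the geometric-mean pseudo-reference — because that
is the scale on which the constant-ratio identities hold (two samples, odd
region count: the factors multiply to exactly 1). `rescale_to_reference`
divides all factors by one sample's factor; this matters for *absolute*
comparability across re-estimations: if one sample's library is duplicated
k-fold and factors are re-estimated, unanchored factors rescale every sample
by k^(1/S), while factors anchored to an untouched reference change only the
duplicated sample's factor (by exactly k), leaving every density invariant.
The depth-invariance check uses the anchored form for this reason.

For intergenic normalization, background regions are the complement of gene
spans expanded by a buffer, keeping pieces strictly longer than a minimum.
Defaults (100 kb minimum, 10 kb buffer) suit a mammalian genome; "far away
from genes" is not a sharply defined quantity, so the buffer is an explicit,
documented parameter rather than a hidden constant. Marks without a global
level change use `total_read_factors` (total mapped reads, geometric-mean
centered so conditions are treated symmetrically).

## Densities

density = (reads in region / region length in bp) / (size factor × 1e-8).

Reads are extended to 200 bp in the read direction; a read is "in" a region
when its extended interval overlaps it by ≥ 1 bp (`counting_mode="overlap"`;
a coverage mode summing per-bp overlap is available and is what profiles
use). Gene-body densities run over the full annotated span with no promoter
trimming. Only expressed genes (strictly more than 10 normalized reads per
kb of transcript) carrying at least one read in at least one sample of a
comparison are tabulated, and the same gene set is kept across samples so
fold summaries are matched. The cohort fold change is the ratio of per-gene
density medians (robust to the long right tail of ChIP densities; a ratio of
means is available via `method="mean"`). Distribution shifts are tested with
the two-sided Wilcoxon rank-sum test: exhaustive enumeration of label
assignments when n·m ≤ 64 (valid under ties), otherwise the normal
approximation with tie correction and 0.5 continuity correction (matching
R's `wilcox.test(correct = TRUE)`).

## Profiles

Metagene bins: 20 × 250 bp upstream flank, 160 equal body bins (integer
edges by rounding i·L/160, which tiles the span exactly), 20 × 250 bp
downstream flank; minus-strand genes are reversed so index 0 is 5'-most.
A bin's value is the per-bp extended-tag coverage averaged over the bin,
divided by the size factor — a *mean*, not a sum, so 250-bp flank bins and
body bins of any width are on the same scale, and the conservation identity
sum(value × width × size factor) = total window coverage holds to
floating-point accuracy. Genes shorter than 160 bp (one bp per body bin) are
skipped and counted in the log. TSS profiles use 10-bp bins over a 2-kb
window centered on the TSS, strand-oriented.

k-means runs on linear (not log) bin values with squared-Euclidean distance
and k-means++ seeding controlled by an explicit seed, keeping the best of 10
restarts by within-cluster sum of squares; labels are renumbered so cluster
1 always has the highest mean signal, making "cluster 1" reproducible across
runs.

## Traveling ratio

TR = (TSS-window density) / (body-window density) with windows
[−100, +300) and [+300, +2000) bp around the TSS, strand-aware; the body
window is deliberately not clipped at the TES (it is defined relative to the
TSS only), and eligible genes are already longer than 1 kb. Window counts
use read 5' ends without extension: the two windows are then disjoint events
(no read is counted in both), and a uniform per-bp signal yields TR = 1
exactly. The per-window size factor cancels from the ratio, so TR is
invariant to library depth. Genes with an empty body window are excluded and
counted rather than assigned an infinite ratio. A count-basis TR
(raw count ratio, no length normalization) is available since the two
windows have unequal lengths and some of the literature reports it that way.

Cohorts are compared by the two-sample KS statistic D = sup|ECDF_x − ECDF_y|.
The p-value uses the exact null distribution when n·m ≤ 10 000 and the
samples share no tied value; otherwise the asymptotic Kolmogorov
distribution with effective size nm/(n+m) (ties invalidate the exact
distribution, and the fallback is logged). D is rank-based and therefore
invariant under any common strictly monotone transform of both cohorts.

## DE bookkeeping

Upstream DE tables are consumed, never refit. Up/down classification uses
padj ≤ 0.05 and log2FC ≥ +1 / ≤ −1 (boundaries inclusive); records without a
padj are skipped and counted. Fold bins are cumulative on the fold magnitude
2^|log2FC| at padj ≤ 0.05 — a 34-fold gene counts in bins 2 through 32 — so
counts are non-increasing by construction. A Benjamini–Hochberg adjuster is
provided solely so synthetic fixtures can carry a padj column without an
external fitter.

## Synthetic data: what it emulates, and what it does not

Fragments are 200 bp, contain their signal point at a uniform position, and
are sequenced 50 bp single-end from a random end; per-fragment coverage
after 200-bp extension is therefore a triangular kernel (±200 bp) centered
on the signal point. Per-gene fragment counts are Poisson. Signal shapes:

* **Pol II** — promoter fragment midpoints at TSS+60 (Gaussian, σ = 25 bp;
  total promoter intensity = planted ratio × body rate × 400 bp, so the
  planted pausing ratio is the promoter:body per-bp intensity ratio) over a
  uniform body rate from +300 bp to the TES.
* **H2Bub1** — linear 5' ramp over the first 150 bp up to a body-wide
  plateau, plus a Gaussian bump (3× plateau, σ = 50 bp) with mode at
  TSS+300; KO samples multiply a gene's whole H2Bub1 intensity by its
  planted fold.
* **Pol II Ser2P** — body signal rising linearly toward the TES plus, for a
  planted gene subset, a TES-centered bump (σ = 300 bp): the two-cluster
  structure.
* **Background** — uniform fragment rate per bp genome-wide (default 0.002
  at depth 1), scaled like everything else by the per-sample depth factor.

Peak positions (+60, +300) mirror the biology being modelled; the widths,
ramp length and bump amplitudes are generator design choices fixed once —
they are asserted only through argmax locations and cohort medians, never
through exact shapes. Per-gene body rates are uniform on [0.05, 0.2]
fragments/bp; expression (base median) is tied to the body rate so the
expression filters operate on consistent values.

The simulated study is a single ~10-Mb chromosome with 300 genes (2–8 kb,
gaps 5–52 kb). At this scale the intergenic selector runs with a 20-kb
minimum length and 5-kb buffer — the full-scale defaults (100 kb / 10 kb)
scaled by roughly the genome-size ratio to a mammalian genome; the
*defaults* of `IntergenicConfig` remain the full-scale values. The cluster-
recovery study holds the body rate uniform across genes so the planted TES
signal is the only between-gene structure (well-separated clusters);
with heterogeneous expression, linear-scale k-means legitimately clusters by
overall level first, which is a property of the method, not a defect.

What the generator does **not** emulate: mappability, GC and chromatin-
accessibility bias, fragment-length dispersion, replicate structure, or any
sequence-level feature. Passing recovery tests therefore demonstrates the
*estimators* are correct under the stated statistical model, not that real
libraries satisfy that model.

Randomness: one user seed feeds named NumPy `default_rng` substreams
(genome, truth, per-sample/mark tags, DE tables), and every emitted file
records the seed in a header comment, so identical seeds give byte-identical
outputs.

## Numerical and degenerate-input choices

* Thresholds quoted as "over 10" / "more than 100" / "> 1 kb" are strict
  inequalities; DE thresholds quoted with ≤ / ≥ are inclusive.
* Neighbor removal is symmetric: both members of a pair closer than the
  window are dropped.
* Median of an even-length ratio list is the mean of the central pair.
* Samples that are constant and identical across groups give Wilcoxon p = 1.
* TSS/body windows clipped at chromosome bounds are flagged in the log; a
  zero-length window is rejected.
* k-means on duplicate rows assigns them identical labels (determinism of
  the seeded best-of-restarts fit).

## Problem sizes

The bundled checks use 300-gene (~10 Mb) simulations for fold and pausing
recovery, 100-gene studies for depth invariance and clustering, 200
replicates for KS null calibration, and exhaustive enumeration up to
n = m = 6 for the statistic oracles. These sizes give estimator noise well
inside the stated recovery tolerances (fold ±10 %, pausing ratio ±15 %,
peak offset ±1 bin) while the whole suite runs in well under a minute.

## Known limitations

* The traveling-ratio windows assume the annotation's TSS is the dominant
  initiation site; alternative promoters blur the planted signal.
* Extended-overlap counting lets a read near a region edge count in two
  adjacent *regions* (densities); profiles and TR avoid this by using
  coverage and 5'-end counting respectively.
* The exact KS path refuses tied samples; heavily tied, discretized inputs
  always take the asymptotic branch.
* bedGraph output is plain text; conversion to bigWig is left to standard
  UCSC tooling.
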