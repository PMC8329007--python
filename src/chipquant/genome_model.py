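"""Genomic primitives and plain-text format I/O.

All internal coordinates are 0-based half-open; conversion to/from 1-based
conventions (GTF) happens only at file boundaries.  Tags are stranded 5'
positions; the 5' end of a minus-strand BED interval [start, end) is end-1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A file did not parse in the declared dialect."""


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span with its median transcript length in kb.

    The transcript length enters the expression filters (normalized reads
    per kb of transcript); when no expression table is available it
    defaults to the span length / 1000.
    """

    gene_id: str
    span: GenomicRegion
    median_tx_len_kb: float

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: genes must be stranded")
        if not self.median_tx_len_kb > 0:
            raise ValueError(f"gene {self.gene_id}: median_tx_len_kb must be > 0")

    @property
    def strand(self) -> str:
        return self.span.strand

    def tss(self) -> int:
        """Transcription start site (bp, 0-based)."""
        return self.span.start if self.strand == "+" else self.span.end - 1

    def tes(self) -> int:
        """Transcription end site (bp, 0-based)."""
        return self.span.end - 1 if self.strand == "+" else self.span.start

    def length(self) -> int:
        return self.span.length()


@dataclass(frozen=True)
class TagAlignment:
    """A single aligned tag, reduced to its stranded 5' position."""

    chrom: str
    pos5: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid tag strand {self.strand!r}")
        if self.pos5 < 0:
            raise ValueError(f"negative tag position {self.pos5}")


class ChromSizes(dict):
    """chromosome name -> length (bp).  Two-column text on disk."""

    def __setitem__(self, key: str, value: int) -> None:
        if not int(value) > 0:
            raise ValueError(f"chromosome {key}: length must be > 0")
        super().__setitem__(key, int(value))

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        out = cls()
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError(f"{path}:{i}: expected 2 columns")
                out[fields[0]] = int(fields[1])
        return out

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.items():
                fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class DERecord:
    """One row of an upstream differential-expression table."""

    gene_id: str
    base_median: float
    log2fc: float
    padj: float | None = None

    def __post_init__(self) -> None:
        if self.base_median < 0:
            raise ValueError(f"{self.gene_id}: negative base_median")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"{self.gene_id}: padj outside [0, 1]")


# ---------------------------------------------------------------------------
# Tag containers


class TagSet:
    """Column-oriented store of tags: per chromosome, arrays of 5' positions
    and a boolean plus-strand mask.  This is the in-memory currency for all
    counting and profiling; :class:`TagAlignment` streams convert losslessly.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self.data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos5, plus) in data.items():
            pos5 = np.asarray(pos5, dtype=np.int64)
            plus = np.asarray(plus, dtype=bool)
            if pos5.shape != plus.shape:
                raise ValueError("pos5/strand arrays must align")
            if pos5.size and pos5.min() < 0:
                raise ValueError("negative tag position")
            self.data[chrom] = (pos5, plus)
        self._sorted_pos: dict[str, np.ndarray] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_tags(cls, tags: Iterable[TagAlignment]) -> "TagSet":
        acc: dict[str, tuple[list, list]] = {}
        for t in tags:
            p, s = acc.setdefault(t.chrom, ([], []))
            p.append(t.pos5)
            s.append(t.strand == "+")
        return cls({c: (np.array(p, dtype=np.int64), np.array(s, dtype=bool))
                    for c, (p, s) in acc.items()})

    @classmethod
    def from_bed(cls, path) -> "TagSet":
        return cls.from_tags(read_tags(path))

    # -- basics ---------------------------------------------------------

    def __len__(self) -> int:
        return sum(p.size for p, _ in self.data.values())

    def chroms(self) -> list[str]:
        return list(self.data)

    def tags(self) -> Iterator[TagAlignment]:
        for chrom, (pos5, plus) in self.data.items():
            for p, s in zip(pos5.tolist(), plus.tolist()):
                yield TagAlignment(chrom, p, "+" if s else "-")

    def repeat(self, k: int) -> "TagSet":
        """Duplicate every tag k-fold (depth-scaling construct)."""
        return TagSet({c: (np.repeat(p, k), np.repeat(s, k))
                       for c, (p, s) in self.data.items()})

    def count_in(self, region: GenomicRegion) -> int:
        """Number of tag 5' ends falling inside the region."""
        pos = self._sorted_pos.get(region.chrom)
        if pos is None:
            pair = self.data.get(region.chrom)
            if pair is None:
                return 0
            pos = np.sort(pair[0])
            self._sorted_pos[region.chrom] = pos
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        return int(hi - lo)

    def to_bed(self, path, read_len: int = 50, header: str | None = None) -> None:
        """Write tags as BED6 reads of ``read_len`` bp.

        Plus-strand intervals start at pos5; minus-strand intervals end at
        pos5 + 1, so a round trip through :func:`read_tags` preserves the
        (chrom, pos5, strand) multiset exactly.
        """
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            i = 0
            for chrom, (pos5, plus) in self.data.items():
                starts = np.where(plus, pos5, np.maximum(pos5 - read_len + 1, 0))
                ends = np.where(plus, pos5 + read_len, pos5 + 1)
                for s, e, is_plus in zip(starts.tolist(), ends.tolist(), plus.tolist()):
                    i += 1
                    strand = "+" if is_plus else "-"
                    fh.write(f"{chrom}\t{s}\t{e}\tr{i}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Readers


def read_tags(path) -> Iterator[TagAlignment]:
    """Stream tags from a 6-column BED file of aligned reads."""
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{i}: expected >= 6 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{i}: invalid interval [{start}, {end})")
            strand = fields[5]
            if strand == "+":
                yield TagAlignment(fields[0], start, "+")
            elif strand == "-":
                yield TagAlignment(fields[0], end - 1, "-")
            else:
                raise ParseError(f"{path}:{i}: unknown strand {strand!r}")


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def _resolve_tx_len(expression_table) -> dict[str, float]:
    if expression_table is None:
        return {}
    if isinstance(expression_table, pd.DataFrame):
        df = expression_table
    else:
        df = pd.read_csv(expression_table, sep="\t")
    if "gene_id" not in df.columns or "median_tx_len_kb" not in df.columns:
        raise ValueError("expression table needs gene_id and median_tx_len_kb columns")
    return dict(zip(df["gene_id"], df["median_tx_len_kb"].astype(float)))


def read_annotation(path, format: str = "bed12", expression_table=None) -> list[GeneModel]:
    """Read a gene annotation in BED12 or GTF dialect into GeneModels.

    GTF is 1-based closed and is converted to 0-based half-open here.  The
    median transcript length (kb) is taken from ``expression_table`` when
    given (columns gene_id, median_tx_len_kb), else span length / 1000.
    """
    fmt = format.lower()
    tx_len = _resolve_tx_len(expression_table)
    genes: list[GeneModel] = []
    seen: set[str] = set()

    def _mk(gene_id, chrom, start, end, strand, lineno):
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: gene {gene_id} lacks a strand")
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid span [{start}, {end})")
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {gene_id}")
        seen.add(gene_id)
        span = GenomicRegion(chrom, start, end, strand)
        kb = tx_len.get(gene_id, span.length() / 1000.0)
        genes.append(GeneModel(gene_id, span, kb))

    if fmt in ("bed12", "bed6", "bed"):
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise ParseError(f"{path}:{i}: expected >= 6 BED columns")
                try:
                    start, end = int(f[1]), int(f[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
                _mk(f[3], f[0], start, end, f[5], i)
    elif fmt == "gtf":
        spans: dict[str, list] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise ParseError(f"{path}:{i}: expected 9 GTF columns")
                m = _GENE_ID_RE.search(f[8])
                if m is None:
                    raise ParseError(f"{path}:{i}: no gene_id attribute")
                gid = m.group(1)
                try:
                    start1, end1 = int(f[3]), int(f[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
                start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
                rec = spans.setdefault(gid, [f[0], start, end, f[6], i, f[2] == "gene"])
                if f[2] == "gene":
                    spans[gid] = [f[0], start, end, f[6], i, True]
                elif not rec[5]:
                    rec[1] = min(rec[1], start)
                    rec[2] = max(rec[2], end)
        for gid, (chrom, start, end, strand, lineno, _) in spans.items():
            _mk(gid, chrom, start, end, strand, lineno)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return genes


def write_bed12(genes: Iterable[GeneModel], path, header: str | None = None) -> None:
    """Write genes as single-block BED12 records."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in genes:
            s, e = g.span.start, g.span.end
            fh.write(
                f"{g.span.chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{s}\t{e}\t0\t1\t{e - s},\t0,\n"
            )


def write_regions_bed(regions: Iterable[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion{i}\t0\t{r.strand}\n")


def read_regions_bed(path) -> list[GenomicRegion]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{i}: expected >= 3 BED columns")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicRegion(f[0], int(f[1]), int(f[2]), strand))
    return out


# ---------------------------------------------------------------------------
# DE tables

_DE_ALIASES = {
    "baseMedian": "base_median",
    "basemedian": "base_median",
    "log2FoldChange": "log2fc",
    "log2fc": "log2fc",
}


def read_de_table(path) -> pd.DataFrame:
    """Read a DE result TSV into columns gene_id, base_median, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=_DE_ALIASES)
    missing = {"gene_id", "base_median", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing DE columns {sorted(missing)}")
    return df


def de_records(df: pd.DataFrame) -> list[DERecord]:
    out = []
    for row in df.itertuples(index=False):
        padj = None if pd.isna(row.padj) else float(row.padj)
        out.append(DERecord(str(row.gene_id), float(row.base_median),
                            float(row.log2fc), padj))
    return out


# ---------------------------------------------------------------------------
# Coverage tracks


def build_coverage(tags: TagSet, chrom_sizes: ChromSizes,
                   fragment_len: int = 100) -> dict[str, np.ndarray]:
    """Per-bp coverage after extending every tag to ``fragment_len`` bp in
    the direction of the read, clipped at chromosome bounds."""
    if fragment_len <= 0:
        raise ValueError("fragment_len must be > 0")
    cov: dict[str, np.ndarray] = {}
    for chrom, (pos5, plus) in tags.data.items():
        L = chrom_sizes[chrom]
        start = np.where(plus, pos5, pos5 - fragment_len + 1)
        end = np.where(plus, pos5 + fragment_len, pos5 + 1)
        start = np.clip(start, 0, L)
        end = np.clip(end, 0, L)
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, start, 1)
        np.add.at(diff, end, -1)
        cov[chrom] = np.cumsum(diff[:-1])
    return cov


def write_bedgraph(coverage: Mapping[str, np.ndarray], chrom_sizes: ChromSizes,
                   total_reads: int, path, target_total: float = 1e7) -> None:
    """Write a depth-normalized bedGraph: values are raw coverage scaled by
    target_total / total_reads.  Zero-coverage runs are omitted; emitted
    intervals are sorted and non-overlapping."""
    if total_reads == 0:
        raise ValueError("total_reads must be > 0")
    scale = target_total / total_reads
    with open(path, "w") as fh:
        for chrom in coverage:
            vals = np.asarray(coverage[chrom])
            if vals.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts.tolist(), ends.tolist()):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v * scale:.6g}\n")


def read_bedgraph(path) -> dict[str, list[tuple[int, int, float]]]:
    out: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            out.setdefault(chrom, []).append((int(s), int(e), float(v)))
    return out
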