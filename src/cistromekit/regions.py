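"""Genomic coordinate types, BED/TSV I/O and peak-to-gene geometry.

All coordinates are 0-based, half-open ``[start, end)`` — the native BED
convention — both internally and on disk.  Region-to-gene distances are
measured from the region midpoint to the gene's transcription start site
(TSS), signed so that negative means upstream of the gene.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "BindingRegion",
    "TagLibrary",
    "NearestGene",
    "BedParseError",
    "parse_bed",
    "write_bed",
    "read_genes_tsv",
    "write_genes_tsv",
    "nearest_tss_distance",
    "classify_location",
    "intersect",
]


class BedParseError(ValueError):
    """Raised for malformed BED input; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene with TSS/TES anchors.  On the minus strand ``tss > tes``."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be '+' or '-'")
        if self.tss == self.tes:
            raise ValueError("tss must differ from tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError("plus-strand gene requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError("minus-strand gene requires tss > tes")


@dataclass(frozen=True)
class BindingRegion:
    """A called binding region: interval plus summit, height and enrichment.

    ``height_rpm`` is the weighted tag count in reads-per-million and
    ``fold_enrichment`` the ratio of ChIP signal to library-size-scaled
    input signal.
    """

    interval: GenomicInterval
    summit: int
    height_rpm: float
    fold_enrichment: float
    region_id: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the region interval")
        if self.height_rpm < 0 or self.fold_enrichment < 0:
            raise ValueError("height_rpm and fold_enrichment must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


TAG_COLUMNS = ["chrom", "pos", "strand", "multiplicity"]


@dataclass
class TagLibrary:
    """Aligned sequence tags: strand-annotated 5' positions with multiplicity.

    Multireads (tags aligning to several genomic positions) carry a
    multiplicity m and are down-weighted 1/m in every pileup computation.
    """

    tags: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TAG_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in TAG_COLUMNS if c not in self.tags.columns]
        if missing:
            raise ValueError(f"tag table missing columns: {missing}")
        if len(self.tags) and (self.tags["multiplicity"] < 1).any():
            raise ValueError("every multiplicity must be >= 1")

    @property
    def total_tags(self) -> int:
        return len(self.tags)

    @property
    def weights(self) -> pd.Series:
        return 1.0 / self.tags["multiplicity"]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "TagLibrary":
        df = pd.DataFrame(list(records), columns=TAG_COLUMNS)
        return cls(df)

    @classmethod
    def read_tsv(cls, path) -> "TagLibrary":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df[TAG_COLUMNS].copy())

    def write_tsv(self, path) -> None:
        self.tags.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED and gene-table I/O


def parse_bed(text: str) -> list[GenomicInterval]:
    """Parse BED lines (>=3 columns) into intervals, order preserved.

    Lines that are empty or start with ``track``/``browser``/``#`` are
    skipped.  Malformed lines raise :class:`BedParseError` naming the
    1-based line number.
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("track", "browser", "#")):
            continue
        fields = stripped.split("\t")
        if len(fields) < 3:
            raise BedParseError(f"line {lineno}: expected >=3 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
        strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
        try:
            intervals.append(GenomicInterval(chrom, start, end, strand))
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: {exc}") from exc
    return intervals


def write_bed(regions: Sequence[BindingRegion]) -> str:
    """Render regions as BED6; score column is ``height_rpm`` rounded."""
    out = io.StringIO()
    for i, region in enumerate(regions, start=1):
        name = region.region_id or f"region_{i}"
        out.write(
            f"{region.chrom}\t{region.interval.start}\t{region.interval.end}"
            f"\t{name}\t{round(region.height_rpm)}\t.\n"
        )
    return out.getvalue()


GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes"]


def read_genes_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss), int(r.tes))
        for r in df.itertuples()
    ]


def write_genes_tsv(genes: Sequence[GeneModel], path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.tes) for g in genes],
        columns=GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Peak-to-gene geometry


@dataclass(frozen=True)
class NearestGene:
    """Nearest-gene lookup result; ``gene_id is None`` means no gene found."""

    gene_id: Optional[str]
    distance: Optional[int]

    @property
    def found(self) -> bool:
        return self.gene_id is not None


def signed_tss_distance(midpoint: int, gene: GeneModel) -> int:
    """Signed distance from a point to a gene's TSS; negative = upstream."""
    if gene.strand == "+":
        return midpoint - gene.tss
    return gene.tss - midpoint


def nearest_tss_distance(
    region: BindingRegion | GenomicInterval, genes: Sequence[GeneModel]
) -> NearestGene:
    """Gene minimizing |midpoint - TSS| on the region's chromosome.

    Ties break on lexicographically smallest ``gene_id``.  Returns a
    sentinel (``found == False``) when no gene shares the chromosome.
    """
    interval = region.interval if isinstance(region, BindingRegion) else region
    mid = interval.midpoint
    best: Optional[tuple[int, str, int]] = None
    for gene in genes:
        if gene.chrom != interval.chrom:
            continue
        dist = signed_tss_distance(mid, gene)
        key = (abs(dist), gene.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(dist), gene.gene_id, dist)
    if best is None:
        return NearestGene(None, None)
    return NearestGene(best[1], best[2])


LOCATION_CATEGORIES = ("upstream_5utr", "intragenic", "downstream", "intergenic")


def classify_location(
    region: BindingRegion | GenomicInterval,
    genes: Sequence[GeneModel],
    flank: int = 10_000,
) -> str:
    """Classify a region's midpoint relative to its nearest gene.

    Categories: within ``flank`` bp upstream of the TSS (strand-adjusted)
    -> ``upstream_5utr``; inside the gene body -> ``intragenic``; within
    ``flank`` bp past the TES -> ``downstream``; otherwise ``intergenic``.
    """
    interval = region.interval if isinstance(region, BindingRegion) else region
    nearest = nearest_tss_distance(interval, genes)
    if not nearest.found:
        return "intergenic"
    gene = next(g for g in genes if g.gene_id == nearest.gene_id)
    mid = interval.midpoint
    if gene.strand == "+":
        if gene.tss - flank <= mid < gene.tss:
            return "upstream_5utr"
        if gene.tss <= mid <= gene.tes:
            return "intragenic"
        if gene.tes < mid <= gene.tes + flank:
            return "downstream"
    else:
        if gene.tss < mid <= gene.tss + flank:
            return "upstream_5utr"
        if gene.tes <= mid <= gene.tss:
            return "intragenic"
        if gene.tes - flank <= mid < gene.tes:
            return "downstream"
    return "intergenic"


def _as_interval(x) -> GenomicInterval:
    return x.interval if isinstance(x, BindingRegion) else x


def intersect(set_a: Sequence, set_b: Sequence) -> dict[str, list]:
    """Partition two interval sets by >=1 bp overlap (half-open semantics).

    Accepts :class:`GenomicInterval` or :class:`BindingRegion` items and
    returns ``{"common_a", "unique_a", "common_b", "unique_b"}`` preserving
    input order; ``|common_a| + |unique_a| == |A|`` always holds.
    """
    trees_b: dict[str, IntervalTree] = {}
    for item in set_b:
        iv = _as_interval(item)
        trees_b.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    trees_a: dict[str, IntervalTree] = {}
    for item in set_a:
        iv = _as_interval(item)
        trees_a.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    result: dict[str, list] = {"common_a": [], "unique_a": [], "common_b": [], "unique_b": []}
    for item in set_a:
        iv = _as_interval(item)
        tree = trees_b.get(iv.chrom)
        hit = bool(tree and tree.overlap(iv.start, iv.end))
        result["common_a" if hit else "unique_a"].append(item)
    for item in set_b:
        iv = _as_interval(item)
        tree = trees_a.get(iv.chrom)
        hit = bool(tree and tree.overlap(iv.start, iv.end))
        result["common_b" if hit else "unique_b"].append(item)
    return result
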