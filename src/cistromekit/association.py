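"""Peak-to-gene association accounting, distance tests and regression.

Builds the binding-characteristics summary: how many regions lie within
1/10/50/100 kb of a TSS, how many regulated genes have nearby binding,
region-per-gene densities split by regulation direction, and the share
of regulation-associated regions that carry a response element.  Also
the distance-distribution comparison (up- vs down-regulated genes),
peak-height t-tests and the per-chromosome binding-vs-gene-count
regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np

from .regions import BindingRegion, GeneModel, signed_tss_distance
from .stats import TestResult, ks_two_sample, ols, welch_t

__all__ = [
    "AssociationRecord",
    "SummaryReport",
    "associate",
    "summarize",
    "render_table",
    "compare_distance_distributions",
    "peak_height_comparison",
    "chromosome_binding_regression",
]

DEFAULT_WINDOWS_KB = (1, 10, 50, 100)


@dataclass(frozen=True)
class AssociationRecord:
    """One region-to-gene link with its signed TSS distance.

    ``role`` is "nearest_gene" (nearest gene of any kind) or
    "nearest_regulated" (nearest regulated gene within the outermost
    window).  ``window_class`` is the tightest window (kb) containing the
    absolute distance, or ``None`` beyond the outermost.
    """

    region_id: str
    gene_id: str
    signed_distance: int
    window_class: Optional[int]
    gene_regulation: str        # "up" | "down" | "unregulated"
    role: str

    def __post_init__(self) -> None:
        if self.window_class is not None and \
                abs(self.signed_distance) > self.window_class * 1000:
            raise ValueError("window_class inconsistent with distance")


def _window_class(distance: int, windows_kb: Sequence[int]) -> Optional[int]:
    for wkb in sorted(windows_kb):
        if abs(distance) <= wkb * 1000:
            return wkb
    return None


def associate(
    regions: Sequence[BindingRegion],
    genes: Sequence[GeneModel],
    regulated: Mapping[str, str],
    windows_kb: Sequence[int] = DEFAULT_WINDOWS_KB,
) -> list[AssociationRecord]:
    """Link each region to its nearest gene and nearest regulated gene.

    ``regulated`` maps gene_id -> "up"/"down".  A region contributes at
    most one record per role; the regulated-gene record exists only when
    a regulated gene's TSS lies within the outermost window.
    """
    outer = max(windows_kb) * 1000
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    records: list[AssociationRecord] = []
    for region in regions:
        mid = region.midpoint
        candidates = by_chrom.get(region.chrom, [])
        best = best_reg = None
        for gene in candidates:
            dist = signed_tss_distance(mid, gene)
            key = (abs(dist), gene.gene_id)
            if best is None or key < best[0]:
                best = (key, gene, dist)
            if gene.gene_id in regulated and abs(dist) <= outer:
                if best_reg is None or key < best_reg[0]:
                    best_reg = (key, gene, dist)
        if best is not None:
            _, gene, dist = best
            records.append(AssociationRecord(
                region.region_id, gene.gene_id, dist,
                _window_class(dist, windows_kb),
                regulated.get(gene.gene_id, "unregulated"),
                role="nearest_gene",
            ))
        if best_reg is not None:
            _, gene, dist = best_reg
            records.append(AssociationRecord(
                region.region_id, gene.gene_id, dist,
                _window_class(dist, windows_kb),
                regulated[gene.gene_id],
                role="nearest_regulated",
            ))
    return records


def _pct(numerator: int, denominator: int) -> Optional[float]:
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 1)


def _density(n_regions: int, n_genes: int) -> Optional[float]:
    if n_genes == 0:
        return None
    q = Decimal(n_regions) / Decimal(n_genes)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryReport:
    """The binding-characteristics statistic bundle.

    Every ``*_pct`` field is 100 x numerator / denominator of the printed
    pair, to one decimal; densities are true quotients rounded half-up to
    two decimals.  ``None`` marks an undefined ratio (zero denominator).
    """

    regions_total: int = 0
    regions_within_kb: dict = field(default_factory=dict)        # kb -> count
    regions_near_regulated: int = 0
    regulated_genes_total: int = 0
    regulated_genes_with_region_100kb: int = 0
    regulated_genes_within_kb: dict = field(default_factory=dict)  # kb -> count
    genes_with_region_100kb: int = 0
    density_overall: Optional[float] = None
    density_regulated: Optional[float] = None
    density_up: Optional[float] = None
    density_down: Optional[float] = None
    up_genes_associated: int = 0
    up_genes_total: int = 0
    down_genes_associated: int = 0
    down_genes_total: int = 0
    regions_near_regulated_with_pre: Optional[int] = None  # None: not scanned

    @property
    def regions_within_pct(self) -> dict:
        return {kb: _pct(n, self.regions_total)
                for kb, n in self.regions_within_kb.items()}

    @property
    def regulated_linked_pct(self) -> Optional[float]:
        return _pct(self.regulated_genes_with_region_100kb,
                    self.regulated_genes_total)

    @property
    def regulated_linked_fraction(self) -> Optional[float]:
        if self.regulated_genes_total == 0:
            return None
        return self.regulated_genes_with_region_100kb / self.regulated_genes_total


def summarize(
    records: Sequence[AssociationRecord],
    regions: Sequence[BindingRegion],
    genes: Sequence[GeneModel],
    regulated: Mapping[str, str],
    pre_region_ids: Optional[set] = None,
    windows_kb: Sequence[int] = DEFAULT_WINDOWS_KB,
) -> SummaryReport:
    """Aggregate association records into the summary statistic bundle.

    Region-side counts come from the nearest-gene records (a region
    counts once, against its nearest gene of the relevant class); the
    gene-side counts apply the direct criterion — a gene is associated
    iff at least one region midpoint lies within the window of its TSS —
    so a region shared between two nearby regulated genes still marks
    both genes associated.
    """
    rep = SummaryReport()
    rep.regions_total = len(regions)

    nearest = [r for r in records if r.role == "nearest_gene"]
    nearest_reg = [r for r in records if r.role == "nearest_regulated"]

    rep.regions_within_kb = {
        kb: sum(1 for r in nearest
                if r.window_class is not None and r.window_class <= kb)
        for kb in sorted(windows_kb)
    }
    rep.regions_near_regulated = len(nearest_reg)

    # gene-side: min |TSS - region midpoint| per gene, via sorted midpoints
    mids_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for region in regions:
        tmp.setdefault(region.chrom, []).append(region.midpoint)
    for c, mids in tmp.items():
        mids_by_chrom[c] = np.sort(np.asarray(mids))

    def min_dist(gene: GeneModel) -> Optional[int]:
        mids = mids_by_chrom.get(gene.chrom)
        if mids is None:
            return None
        return int(np.min(np.abs(mids - gene.tss)))

    gene_map = {g.gene_id: g for g in genes}
    gene_best: dict[str, int] = {}          # regulated gene -> tightest window
    for gid in regulated:
        gene = gene_map.get(gid)
        if gene is None:
            continue
        d = min_dist(gene)
        if d is None:
            continue
        wc = _window_class(d, windows_kb)
        if wc is not None:
            gene_best[gid] = wc

    rep.regulated_genes_total = len(regulated)
    rep.regulated_genes_with_region_100kb = len(gene_best)
    rep.regulated_genes_within_kb = {
        kb: sum(1 for w in gene_best.values() if w <= kb)
        for kb in sorted(windows_kb)
    }

    # overall density: regions within the outer window of any TSS, per gene
    # (of any kind) with >= 1 region within that window
    overall_regions = [r for r in nearest if r.window_class is not None]
    outer = max(windows_kb) * 1000
    rep.genes_with_region_100kb = sum(
        1 for g in genes
        if (d := min_dist(g)) is not None and d <= outer
    )
    rep.density_overall = _density(len(overall_regions), rep.genes_with_region_100kb)
    rep.density_regulated = _density(len(nearest_reg),
                                     rep.regulated_genes_with_region_100kb)

    up_records = [r for r in nearest_reg if r.gene_regulation == "up"]
    down_records = [r for r in nearest_reg if r.gene_regulation == "down"]
    up_assoc = sum(1 for gid in gene_best if regulated[gid] == "up")
    down_assoc = sum(1 for gid in gene_best if regulated[gid] == "down")
    rep.density_up = _density(len(up_records), up_assoc)
    rep.density_down = _density(len(down_records), down_assoc)
    rep.up_genes_associated = up_assoc
    rep.down_genes_associated = down_assoc
    rep.up_genes_total = sum(1 for d in regulated.values() if d == "up")
    rep.down_genes_total = sum(1 for d in regulated.values() if d == "down")

    if pre_region_ids is not None:
        reg_region_ids = {r.region_id for r in nearest_reg}
        rep.regions_near_regulated_with_pre = len(reg_region_ids & set(pre_region_ids))
    return rep


def render_table(rep: SummaryReport) -> str:
    """Human-readable summary table, n and % columns, percentages to 1 dp."""
    def fmt(x) -> str:
        return "NA" if x is None else (f"{x:.1f}" if isinstance(x, float) else str(x))

    rows: list[tuple[str, str, str]] = [("Regions total", str(rep.regions_total), "100")]
    for kb, n in sorted(rep.regions_within_kb.items(), reverse=True):
        rows.append((f"Regions within {kb} kb of a TSS", str(n),
                     fmt(rep.regions_within_pct[kb])))
    rows.append(("Regions near to regulated genes total",
                 str(rep.regions_near_regulated),
                 fmt(_pct(rep.regions_near_regulated, rep.regions_total))))
    rows.append(("Regulated genes with regions within 100 kb",
                 f"{rep.regulated_genes_with_region_100kb}/{rep.regulated_genes_total}",
                 fmt(rep.regulated_linked_pct)))
    for kb in sorted(rep.regulated_genes_within_kb, reverse=True):
        if kb == 100:
            continue
        n = rep.regulated_genes_within_kb[kb]
        rows.append((f"Regulated genes with region within {kb} kb of TSS",
                     f"{n}/{rep.regulated_genes_with_region_100kb}",
                     fmt(_pct(n, rep.regulated_genes_with_region_100kb))))
    def fmt2(x) -> str:
        return "NA" if x is None else f"{x:.2f}"

    rows.append(("Region to gene density overall", fmt2(rep.density_overall), ""))
    rows.append(("Region to regulated gene density", fmt2(rep.density_regulated), ""))
    rows.append(("Region to up-regulated gene density", fmt2(rep.density_up), ""))
    rows.append(("Region to down-regulated gene density", fmt2(rep.density_down), ""))
    n_pre = rep.regions_near_regulated_with_pre
    rows.append(("Regions near regulated genes that contain PREs",
                 "NA" if n_pre is None else str(n_pre),
                 "NA" if n_pre is None
                 else fmt(_pct(n_pre, rep.regions_near_regulated))))
    rows.append(("Up-regulated genes associated with binding",
                 f"{rep.up_genes_associated}/{rep.up_genes_total}",
                 fmt(_pct(rep.up_genes_associated, rep.up_genes_total))))
    rows.append(("Down-regulated genes associated with binding",
                 f"{rep.down_genes_associated}/{rep.down_genes_total}",
                 fmt(_pct(rep.down_genes_associated, rep.down_genes_total))))
    width = max(len(r[0]) for r in rows)
    lines = [f"{'':{width}}  {'n':>12}  {'%':>6}"]
    for name, n, pct in rows:
        lines.append(f"{name:{width}}  {n:>12}  {pct:>6}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Distance and height statistics


def compare_distance_distributions(
    dists_up: Sequence[float], dists_down: Sequence[float]
) -> tuple[float, float, float, float]:
    """Two-sample KS on |distance| between up- and down-regulated genes.

    Returns (D, p, median_up, median_down).
    """
    if len(dists_up) < 5 or len(dists_down) < 5:
        raise ValueError("need >= 5 distances per group")
    a = np.abs(np.asarray(dists_up, float))
    b = np.abs(np.asarray(dists_down, float))
    res = ks_two_sample(a, b)
    return res.statistic, res.pvalue, float(np.median(a)), float(np.median(b))


def peak_height_comparison(
    heights_assoc: Sequence[float], heights_nonassoc: Sequence[float]
) -> TestResult:
    """Welch t-test of peak heights: regulation-associated vs not."""
    return welch_t(heights_assoc, heights_nonassoc)


def chromosome_binding_regression(
    region_counts: Mapping[str, int], gene_counts: Mapping[str, int]
) -> tuple[float, float, float]:
    """OLS of per-chromosome region count on gene count: (slope, intercept, R²)."""
    chroms = sorted(set(region_counts) | set(gene_counts))
    if len(chroms) < 3:
        raise ValueError("need >= 3 chromosomes")
    x = [gene_counts.get(c, 0) for c in chroms]
    y = [region_counts.get(c, 0) for c in chroms]
    return ols(x, y)
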