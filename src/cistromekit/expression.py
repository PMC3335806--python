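"""Differential-expression calling, SOM clustering and regulation deltas.

A transcript is progestin-regulated when it passes both thresholds
(differential p < 0.01 and linear fold change >= 1.5) at one or more of
the 2/6/24-h time points.  Regulation time-course profiles are grouped
with a self-organizing map; comparing the regulated sets with and
without a cofactor yields lost / gained / conserved partitions whose
binding-distance structure is then tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .regions import BindingRegion, GeneModel, signed_tss_distance
from .stats import TestResult, kruskal_wallis, welch_t

__all__ = [
    "DECall",
    "RegulationDelta",
    "call_regulated",
    "regulated_directions",
    "som_cluster",
    "SOMResult",
    "cluster_distance_test",
    "regulation_delta",
    "delta_distance_analysis",
    "transcriptome_overlap",
    "nearest_region_distances",
]


@dataclass(frozen=True)
class DECall:
    transcript_id: str
    timepoint: int
    log2_fc: float
    diff_p: float
    direction: str           # "up" | "down" | "none"


def call_regulated(
    expression: pd.DataFrame,
    p_threshold: float = 0.01,
    fc_threshold: float = 1.5,
) -> list[DECall]:
    """Per-transcript/timepoint differential calls.

    The fold-change threshold is on the linear scale: a transcript passes
    when ``|log2_fc| >= log2(fc_threshold)`` and ``diff_p < p_threshold``.
    Rows with missing values are skipped.
    """
    log2_thresh = math.log2(fc_threshold)
    calls: list[DECall] = []
    n_skipped = 0
    for row in expression.itertuples():
        lfc, p = row.log2_fc, row.diff_p
        if pd.isna(lfc) or pd.isna(p):
            n_skipped += 1
            continue
        if p < p_threshold and abs(lfc) >= log2_thresh:
            direction = "up" if lfc > 0 else "down"
        else:
            direction = "none"
        calls.append(DECall(row.transcript_id, int(row.timepoint),
                            float(lfc), float(p), direction))
    if n_skipped:
        import logging
        logging.getLogger(__name__).warning(
            "call_regulated: skipped %d rows with missing values", n_skipped)
    return calls


def regulated_directions(calls: Sequence[DECall]) -> dict[str, str]:
    """transcript -> direction, for transcripts regulated at >=1 timepoint.

    Direction comes from the fold-change sign at the most significant
    passing time point.
    """
    best: dict[str, tuple[float, str]] = {}
    for c in calls:
        if c.direction == "none":
            continue
        cur = best.get(c.transcript_id)
        if cur is None or c.diff_p < cur[0]:
            best[c.transcript_id] = (c.diff_p, c.direction)
    return {t: d for t, (_, d) in best.items()}


# ---------------------------------------------------------------------------
# Self-organizing map


@dataclass
class SOMResult:
    labels: dict[str, int]               # transcript -> node index (row-major)
    node_means: np.ndarray               # (n_nodes, n_timepoints)
    quantization_errors: list[float]     # per logged step, non-increasing trend


def som_cluster(
    profiles: Mapping[str, Sequence[float]],
    grid: tuple[int, int] = (3, 3),
    seed: int = 0,
    n_iterations: int = 2000,
) -> SOMResult:
    """Kohonen self-organizing map over regulation time-course profiles.

    Nodes live on a ``rows x cols`` grid; weights initialize from random
    data points; learning rate and Gaussian neighbourhood radius decay
    exponentially over a fixed iteration budget.  Deterministic given the
    seed.
    """
    rows, cols = grid
    n_nodes = rows * cols
    ids = list(profiles)
    X = np.array([profiles[i] for i in ids], float)
    if X.ndim != 2:
        raise ValueError("profiles must be equal-length vectors")
    if len(ids) < n_nodes:
        raise ValueError(f"grid of {n_nodes} nodes exceeds {len(ids)} profiles")

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(len(ids), size=n_nodes, replace=False)
    weights = X[init_idx].copy()
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], float)

    lr0, lr1 = 0.5, 0.01
    sigma0, sigma1 = max(rows, cols) / 2.0, 0.5
    qe_log: list[float] = []
    log_every = max(1, n_iterations // 20)
    for it in range(n_iterations):
        frac = it / max(n_iterations - 1, 1)
        lr = lr0 * (lr1 / lr0) ** frac
        sigma = sigma0 * (sigma1 / sigma0) ** frac
        x = X[int(rng.integers(0, len(ids)))]
        bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
        grid_d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
        h = np.exp(-grid_d2 / (2.0 * sigma * sigma))
        weights += lr * h[:, None] * (x - weights)
        if it % log_every == 0 or it == n_iterations - 1:
            d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
            qe_log.append(float(np.sqrt(d2.min(axis=1)).mean()))

    d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
    assignment = d2.argmin(axis=1)
    node_means = np.zeros_like(weights)
    for node in range(n_nodes):
        members = X[assignment == node]
        node_means[node] = members.mean(axis=0) if len(members) else weights[node]
    return SOMResult(
        labels={i: int(a) for i, a in zip(ids, assignment)},
        node_means=node_means,
        quantization_errors=qe_log,
    )


def cluster_distance_test(
    labels: Mapping[str, int], distances: Mapping[str, float]
) -> TestResult:
    """Kruskal-Wallis test of binding distance across regulation clusters."""
    groups: dict[int, list[float]] = {}
    for t, lab in labels.items():
        if t in distances:
            groups.setdefault(lab, []).append(float(distances[t]))
    usable = [g for g in groups.values() if len(g) >= 2]
    if len(usable) < 2:
        raise ValueError("need >= 2 clusters with >= 2 members each")
    return kruskal_wallis(usable)


# ---------------------------------------------------------------------------
# Regulation deltas (cofactor present vs absent)


@dataclass(frozen=True)
class RegulationDelta:
    lost: frozenset
    gained: frozenset
    conserved: frozenset


def regulation_delta(baseline_regulated: set, condition_regulated: set) -> RegulationDelta:
    """Partition regulated sets: lost = baseline only, gained = condition
    only, conserved = both."""
    base, cond = set(baseline_regulated), set(condition_regulated)
    return RegulationDelta(
        lost=frozenset(base - cond),
        gained=frozenset(cond - base),
        conserved=frozenset(base & cond),
    )


def nearest_region_distances(
    gene_ids: Sequence[str],
    regions: Sequence[BindingRegion],
    genes: Sequence[GeneModel],
) -> dict[str, float]:
    """|TSS -> nearest region midpoint| per gene; genes with no region on
    their chromosome are omitted."""
    by_chrom: dict[str, list[int]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r.midpoint)
    for mids in by_chrom.values():
        mids.sort()
    gene_map = {g.gene_id: g for g in genes}
    out: dict[str, float] = {}
    for gid in gene_ids:
        gene = gene_map.get(gid)
        if gene is None:
            continue
        mids = by_chrom.get(gene.chrom)
        if not mids:
            continue
        arr = np.asarray(mids)
        out[gid] = float(np.min(np.abs(arr - gene.tss)))
    return out


def region_density_per_gene(
    gene_ids: Sequence[str],
    regions: Sequence[BindingRegion],
    genes: Sequence[GeneModel],
    window: int = 100_000,
) -> dict[str, int]:
    """Count of regions with midpoint within ``window`` of each gene's TSS."""
    by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for r in regions:
        tmp.setdefault(r.chrom, []).append(r.midpoint)
    for c, mids in tmp.items():
        by_chrom[c] = np.sort(np.asarray(mids))
    gene_map = {g.gene_id: g for g in genes}
    out: dict[str, int] = {}
    for gid in gene_ids:
        gene = gene_map.get(gid)
        if gene is None:
            continue
        mids = by_chrom.get(gene.chrom)
        if mids is None:
            out[gid] = 0
            continue
        lo = np.searchsorted(mids, gene.tss - window, "left")
        hi = np.searchsorted(mids, gene.tss + window, "right")
        out[gid] = int(hi - lo)
    return out


def delta_distance_analysis(
    delta: RegulationDelta,
    regions: Sequence[BindingRegion],
    genes: Sequence[GeneModel],
    window: int = 100_000,
) -> dict:
    """Binding-distance structure of lost/gained/conserved gene classes.

    For each class: mean |TSS-to-nearest-region| distance and mean count
    of regions within ``window``; Welch t-tests between every pair of
    non-empty classes on the distances.
    """
    classes = {"lost": sorted(delta.lost), "gained": sorted(delta.gained),
               "conserved": sorted(delta.conserved)}
    per_class: dict[str, dict] = {}
    dists: dict[str, list[float]] = {}
    for name, ids in classes.items():
        d = nearest_region_distances(ids, regions, genes)
        dens = region_density_per_gene(ids, regions, genes, window)
        dists[name] = list(d.values())
        per_class[name] = {
            "n_genes": len(ids),
            "mean_distance": float(np.mean(list(d.values()))) if d else None,
            "mean_region_count": float(np.mean(list(dens.values()))) if dens else None,
        }
    tests: dict[tuple[str, str], Optional[TestResult]] = {}
    names = list(classes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(dists[a]) >= 3 and len(dists[b]) >= 3:
                tests[(a, b)] = welch_t(dists[a], dists[b])
            else:
                tests[(a, b)] = None   # comparison skipped: class too small
    return {"per_class": per_class, "tests": tests}


def transcriptome_overlap(set_a: set, set_b: set) -> dict:
    """Exact overlap accounting between two regulated-transcript sets."""
    a, b = set(set_a), set(set_b)
    common = a & b
    union = a | b
    def pct(num: int, den: int) -> Optional[int]:
        return None if den == 0 else round(100.0 * num / den)
    return {
        "unique_a": len(a - b),
        "unique_b": len(b - a),
        "common": len(common),
        "pct_of_union": pct(len(common), len(union)),
        "pct_of_a": pct(len(common), len(a)),
        "pct_of_b": pct(len(common), len(b)),
    }
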