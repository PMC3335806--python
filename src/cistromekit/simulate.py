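"""Synthetic genomes, planted binding sites, tag libraries and expression.

The generator emulates a two-cell-line progestin ChIP-seq study: two
largely disjoint planted binding-site sets (one per "cell line"), each
site optionally carrying a progesterone response element (PRE) and
cofactor motifs (FOXA1 / NF1 / AP-1) written into the genome sequence;
sonication fragments of 200-400 bp producing strand-shifted tag pileups
with multireads; a uniform input-control library; and a regulated-gene
set linked to nearby sites with exponential distance decay (up-regulated
genes closer than down-regulated) over three treatment time points
(2, 6, 24 h).

Everything is deterministic under ``SimConfig.seed``: each stage draws
from its own sub-stream derived from the master seed, so partial re-runs
reproduce exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regions import GeneModel, GenomicInterval, TagLibrary, TAG_COLUMNS
from .motifs import (
    AP1_CONSENSUS,
    FOXA1_CONSENSUS,
    IUPAC_SETS,
    NF1_CONSENSUS,
    PRE_FULL_CONSENSUS,
    revcomp,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "PlantedSite",
    "RegulatedGene",
    "Genome",
    "SimData",
    "simulate_genome",
    "plant_binding_sites",
    "simulate_tags",
    "simulate_expression",
    "simulate_study",
    "sample_link_distances",
    "instantiate_iupac",
]

CELL_LINES = ("cellA", "cellB")  # cellA emulates the cancer line, cellB the
                                 # immortalized normal line

COFACTOR_CONSENSI = {
    "FOXA1": FOXA1_CONSENSUS,
    "NF1": NF1_CONSENSUS,
    "AP1": AP1_CONSENSUS,
}

_STAGES = {"genome": 1, "sites": 2, "tags_cellA": 3, "tags_cellB": 4,
           "expression_cellA": 5, "expression_cellB": 6}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGES[stage]]))


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-cell-line experiment.

    Defaults are sized for a desk-scale genome (4 x 5 Mb with sequence);
    probabilities mirror the observed motif and linkage fractions of the
    system being emulated: ~60% of planted sites carry a PRE, ~60% of
    regulated genes are linked to a site within 100 kb, up-regulated
    genes link closer (mean 44 kb) than down-regulated (75 kb), and the
    cancer-like line is FOXA1-rich while the normal-like line carries
    NF1/AP-1 sites.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    with_sequence: bool = True
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    n_sites: int = 60                       # per cell line
    site_width: int = 100
    shared_site_fraction: float = 0.25
    pre_plant_prob: float = 0.6
    cofactor_plant_probs: dict = field(default_factory=lambda: {
        "cellA": {"FOXA1": 0.44, "NF1": 0.05, "AP1": 0.10},
        "cellB": {"FOXA1": 0.05, "NF1": 0.23, "AP1": 0.28},
    })
    pre_offset_sd: float = 50.0
    fragment_length_range: tuple[int, int] = (200, 400)
    n_chip_tags: int = 50_000
    n_input_tags: int = 5_000
    multiread_fraction: float = 0.1
    multiread_max: int = 10
    background_rate: float = 0.1            # fraction of ChIP tags that are noise
    frac_regulated_genes: float = 0.3
    frac_regulated_with_site_100kb: float = 0.60
    up_down_ratio: dict = field(default_factory=lambda: {"cellA": 8.0, "cellB": 0.88})
    timepoints: tuple[int, ...] = (2, 6, 24)
    de_fc_effect: float = 2.0               # minimum linear fold change when regulated
    de_p_noise: float = 0.1                 # sd of null log2 fold-change noise
    up_distance_mean: float = 44_000.0
    down_distance_mean: float = 75_000.0
    max_link_distance: int = 100_000
    min_link_distance: int = 1_000
    linked_strength_boost: float = 2.0

    def __post_init__(self) -> None:
        probs = [self.shared_site_fraction, self.pre_plant_prob,
                 self.multiread_fraction, self.background_rate,
                 self.frac_regulated_genes, self.frac_regulated_with_site_100kb]
        for line in self.cofactor_plant_probs.values():
            probs.extend(line.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        lo, hi = self.fragment_length_range
        if not (50 <= lo <= hi <= 1000):
            raise ValueError("fragment_length_range must lie within [50, 1000]")
        for name in ("n_chroms", "chrom_length", "n_chip_tags", "n_input_tags",
                     "n_sites", "site_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass
class Genome:
    """Chromosome lengths plus (optionally) the base sequence."""

    chrom_lengths: dict[str, int]
    sequences: Optional[dict[str, str]] = None

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def write_fasta(self, path) -> None:
        if self.sequences is None:
            raise ValueError("genome has no sequence to write")
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


@dataclass
class PlantedSite:
    cell_line: str
    interval: GenomicInterval
    motifs: list[tuple[str, int, str]]   # (motif name, offset from centre, strand)
    strength: float
    linked_gene: Optional[str] = None
    shared: bool = False

    @property
    def centre(self) -> int:
        return self.interval.midpoint


@dataclass
class RegulatedGene:
    gene_id: str
    cell_line: str
    direction: str                       # "up" | "down"
    timepoints: tuple[int, ...]
    linked_site_index: Optional[int]     # index into SimTruth.sites, or None


@dataclass
class SimTruth:
    """Planted ground truth against which every stage's recovery is scored."""

    sites: list[PlantedSite] = field(default_factory=list)
    regulated: list[RegulatedGene] = field(default_factory=list)

    def sites_for(self, cell_line: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.cell_line == cell_line]

    def regulated_for(self, cell_line: str) -> list[RegulatedGene]:
        return [g for g in self.regulated if g.cell_line == cell_line]

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.sites:
                rec = {"kind": "site", "cell_line": s.cell_line,
                       "chrom": s.interval.chrom, "start": s.interval.start,
                       "end": s.interval.end, "motifs": s.motifs,
                       "strength": s.strength, "linked_gene": s.linked_gene,
                       "shared": s.shared}
                fh.write(json.dumps(rec) + "\n")
            for g in self.regulated:
                rec = {"kind": "regulated_gene", **asdict(g)}
                fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# Genome and genes


def simulate_genome(config: SimConfig) -> tuple[Genome, list[GeneModel]]:
    """Uniform-base chromosomes plus collision-free gene placements."""
    rng = _stage_rng(config.seed, "genome")
    lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    sequences: Optional[dict[str, str]] = None
    if config.with_sequence:
        letters = np.frombuffer(b"ACGT", dtype=np.uint8)
        sequences = {}
        for chrom, L in lengths.items():
            codes = rng.integers(0, 4, size=L)
            sequences[chrom] = letters[codes].tobytes().decode("ascii")

    genes: list[GeneModel] = []
    chroms = list(lengths)
    placed_tss: dict[str, list[int]] = {c: [] for c in chroms}
    min_tss_gap = 2_000
    glo, ghi = config.gene_length_range
    max_tries = 200 * max(config.n_genes, 1)
    tries = 0
    for i in range(config.n_genes):
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("could not place genes without TSS collisions")
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            L = lengths[chrom]
            margin = 1_000
            glen = int(rng.integers(glo, min(ghi, max(glo, (L - 2 * margin) // 2)) + 1))
            if L - margin - glen <= margin:
                continue
            start = int(rng.integers(margin, L - margin - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else start + glen
            if any(abs(tss - t) < min_tss_gap for t in placed_tss[chrom]):
                continue
            placed_tss[chrom].append(tss)
            if strand == "+":
                genes.append(GeneModel(f"gene_{i:04d}", chrom, "+", start, start + glen))
            else:
                genes.append(GeneModel(f"gene_{i:04d}", chrom, "-", start + glen, start))
            break
    return Genome(lengths, sequences), genes


# ---------------------------------------------------------------------------
# Site planting


def instantiate_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Draw one concrete word: each degenerate position sampled uniformly
    from its IUPAC set."""
    out = []
    for ch in pattern.upper():
        allowed = sorted(IUPAC_SETS[ch])
        out.append(allowed[int(rng.integers(0, len(allowed)))])
    return "".join(out)


def sample_link_distances(
    config: SimConfig, direction: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Site-to-TSS distances for linked regulated genes.

    Exponential decay, mean 44 kb for up-regulated and 75 kb for
    down-regulated genes, resampled into
    [min_link_distance, max_link_distance].
    """
    mean = config.up_distance_mean if direction == "up" else config.down_distance_mean
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.exponential(mean, size=max(2 * (n - filled), 16))
        ok = draw[(draw >= config.min_link_distance) & (draw <= config.max_link_distance)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _overlaps_any(pos: int, width: int, chrom: str,
                  occupied: dict[str, list[tuple[int, int]]]) -> bool:
    half = width // 2
    for s, e in occupied.get(chrom, ()):
        if pos - half < e and s < pos + half:
            return True
    return False


def _plant_motifs_at_site(
    site: PlantedSite,
    sequences: Optional[dict[str, bytearray]],
    pre_prob: float,
    cofactor_probs: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Write PRE/cofactor words into the sequence around a site centre and
    record (name, offset, strand) in the site's truth."""
    jobs: list[tuple[str, str, int]] = []   # (name, word, offset)
    if rng.random() < pre_prob:
        word = instantiate_iupac(PRE_FULL_CONSENSUS, rng)
        offset = int(round(rng.normal(0.0, config.pre_offset_sd)))
        jobs.append(("PRE", word, offset))
    for name in sorted(cofactor_probs):
        if rng.random() < cofactor_probs[name]:
            word = instantiate_iupac(COFACTOR_CONSENSI[name], rng)
            offset = int(rng.integers(-150, 151))
            jobs.append((name, word, offset))

    centre = site.centre
    chrom = site.interval.chrom
    taken: list[tuple[int, int]] = []
    for name, word, offset in jobs:
        w = len(word)
        start = centre + offset - w // 2
        placed = False
        for _ in range(20):
            if all(start + w <= s or start >= e for s, e in taken):
                placed = True
                break
            offset = int(rng.integers(-150, 151))
            start = centre + offset - w // 2
        if not placed:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = word if strand == "+" else revcomp(word)
        if sequences is not None:
            seq = sequences[chrom]
            if start < 0 or start + w > len(seq):
                continue
            seq[start:start + w] = oriented.encode("ascii")
        taken.append((start, start + w))
        site.motifs.append((name, offset, strand))


def plant_binding_sites(
    genome: Genome, genes: Sequence[GeneModel], config: SimConfig
) -> SimTruth:
    """Plant the two cell lines' binding-site sets and the regulated truth.

    Per line, a binomial fraction of regulated genes is "linked": each
    linked gene gets a dedicated site at an exponential-decay distance
    from its TSS (<= 100 kb).  Shared sites (identical coordinates in
    both lines) and the remaining line-unique sites are placed uniformly.
    Unlinked regulated genes are then drawn from genes with no same-line
    site within 100 kb, so the configured linkage fraction is what the
    association stage actually measures.
    """
    rng = _stage_rng(config.seed, "sites")
    truth = SimTruth()
    seqs: Optional[dict[str, bytearray]] = None
    if genome.sequences is not None:
        seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}

    chroms = genome.chroms
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], float)
    chrom_probs = lengths / lengths.sum()
    w = config.site_width
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    n_shared = int(round(config.shared_site_fraction * config.n_sites))
    n_unique = config.n_sites - n_shared
    genes_by_id = {g.gene_id: g for g in genes}

    def place_uniform() -> GenomicInterval:
        for _ in range(1000):
            c = chroms[int(rng.choice(len(chroms), p=chrom_probs))]
            pos = int(rng.integers(w, genome.chrom_lengths[c] - w))
            if not _overlaps_any(pos, 2 * w, c, occupied):
                occupied[c].append((pos - w // 2, pos + w // 2))
                return GenomicInterval(c, pos - w // 2, pos + w // 2)
        raise RuntimeError("could not place a site without overlap")

    def site_strength(linked: bool) -> float:
        s = float(rng.lognormal(mean=0.0, sigma=0.5))
        return s * (config.linked_strength_boost if linked else 1.0)

    # --- regulated genes and their linked (gene-anchored) sites, per line
    n_reg = int(round(config.frac_regulated_genes * config.n_genes))
    anchored: dict[str, list[PlantedSite]] = {ln: [] for ln in CELL_LINES}
    linked_gene_ids: dict[str, list[tuple[str, str]]] = {ln: [] for ln in CELL_LINES}
    for line in CELL_LINES:
        if n_reg == 0:
            continue
        # count fixed at expectation; which genes are linked stays random
        n_linked = int(round(n_reg * config.frac_regulated_with_site_100kb))
        if n_linked > n_unique:
            raise ValueError(
                f"not enough line-unique sites to link {n_linked} regulated genes "
                f"({n_unique} available); increase n_sites or lower linkage"
            )
        ratio = config.up_down_ratio[line]
        p_up = ratio / (1.0 + ratio)
        chosen = rng.choice(len(genes), size=min(n_linked, len(genes)), replace=False)
        for gi in chosen:
            gene = genes[int(gi)]
            direction = "up" if rng.random() < p_up else "down"
            placed = None
            for _ in range(1000):
                d = float(sample_link_distances(config, direction, 1, rng)[0])
                side = 1 if rng.random() < 0.5 else -1
                pos = gene.tss + side * int(round(d))
                L = genome.chrom_lengths[gene.chrom]
                if pos - w // 2 < 0 or pos + w // 2 > L:
                    continue
                if _overlaps_any(pos, 2 * w, gene.chrom, occupied):
                    continue
                occupied[gene.chrom].append((pos - w // 2, pos + w // 2))
                placed = GenomicInterval(gene.chrom, pos - w // 2, pos + w // 2)
                break
            if placed is None:
                raise RuntimeError("could not place a gene-anchored site")
            site = PlantedSite(line, placed, [], site_strength(True),
                               linked_gene=gene.gene_id)
            anchored[line].append(site)
            linked_gene_ids[line].append((gene.gene_id, direction))

    # --- shared sites (same coordinates in both lines, one sequence)
    shared_pairs: list[tuple[PlantedSite, PlantedSite]] = []
    avg_cof = {
        name: float(np.mean([config.cofactor_plant_probs[ln][name]
                             for ln in CELL_LINES]))
        for name in COFACTOR_CONSENSI
    }
    for _ in range(n_shared):
        iv = place_uniform()
        strength = site_strength(False)
        a = PlantedSite(CELL_LINES[0], iv, [], strength, shared=True)
        b = PlantedSite(CELL_LINES[1], iv, list(a.motifs), strength, shared=True)
        _plant_motifs_at_site(a, seqs, config.pre_plant_prob, avg_cof, config, rng)
        b.motifs = list(a.motifs)
        shared_pairs.append((a, b))

    # --- line-unique background sites + motif planting for anchored sites
    unique_bg: dict[str, list[PlantedSite]] = {ln: [] for ln in CELL_LINES}
    for line in CELL_LINES:
        cof = config.cofactor_plant_probs[line]
        for site in anchored[line]:
            _plant_motifs_at_site(site, seqs, config.pre_plant_prob, cof, config, rng)
        for _ in range(n_unique - len(anchored[line])):
            site = PlantedSite(line, place_uniform(), [], site_strength(False))
            _plant_motifs_at_site(site, seqs, config.pre_plant_prob, cof, config, rng)
            unique_bg[line].append(site)

    for line in CELL_LINES:
        truth.sites.extend(anchored[line])
        truth.sites.extend(unique_bg[line])
    for a, b in shared_pairs:
        truth.sites.extend([a, b])

    site_index = {id(s): i for i, s in enumerate(truth.sites)}

    # --- unlinked regulated genes: drawn from genes with no same-line site
    # within 100 kb, so measured linkage equals the planted fraction
    for line in CELL_LINES:
        if n_reg == 0:
            continue
        line_sites = truth.sites_for(line)
        linked_ids = {gid for gid, _ in linked_gene_ids[line]}
        clean: list[str] = []
        for gene in genes:
            if gene.gene_id in linked_ids:
                continue
            near = any(
                s.interval.chrom == gene.chrom
                and abs(s.centre - gene.tss) <= config.max_link_distance
                for s in line_sites
            )
            if not near:
                clean.append(gene.gene_id)
        n_unlinked = n_reg - len(linked_gene_ids[line])
        if len(clean) < n_unlinked:
            raise ValueError(
                f"cannot select {n_unlinked} unlinked regulated genes for {line}: "
                f"only {len(clean)} genes lack a site within 100 kb"
            )
        ratio = config.up_down_ratio[line]
        p_up = ratio / (1.0 + ratio)
        unlinked = rng.choice(len(clean), size=n_unlinked, replace=False)

        tp = list(config.timepoints)
        def draw_timepoints() -> tuple[int, ...]:
            k = int(rng.integers(1, len(tp) + 1))
            idx = sorted(rng.choice(len(tp), size=k, replace=False))
            return tuple(tp[i] for i in idx)

        anchored_by_gene = {s.linked_gene: site_index[id(s)]
                           for s in anchored[line]}
        for gid, direction in linked_gene_ids[line]:
            truth.regulated.append(RegulatedGene(
                gid, line, direction, draw_timepoints(), anchored_by_gene[gid]))
        for ci in unlinked:
            gid = clean[int(ci)]
            direction = "up" if rng.random() < p_up else "down"
            truth.regulated.append(RegulatedGene(
                gid, line, direction, draw_timepoints(), None))

    if seqs is not None and genome.sequences is not None:
        genome.sequences = {c: bytes(b).decode("ascii") for c, b in seqs.items()}
    return truth


# ---------------------------------------------------------------------------
# Tag simulation


def simulate_tags(
    genome: Genome, truth: SimTruth, config: SimConfig, cell_line: str = "cellA"
) -> tuple[TagLibrary, TagLibrary]:
    """ChIP and input tag libraries for one cell line.

    ChIP tags come from sonication fragments of U[200, 400] bp centred
    (with jitter) on planted sites, allocated in proportion to site
    strength; each fragment is sequenced from a uniformly chosen end, so
    plus-strand tags sit at fragment left ends and minus-strand tags at
    right ends — the two strand pileups flank the site by about half the
    mean fragment length.  A ``background_rate`` fraction of ChIP tags,
    and all input tags, are uniform.  A ``multiread_fraction`` of tags in
    each library gets multiplicity 2..multiread_max.
    """
    rng = _stage_rng(config.seed, f"tags_{cell_line}")
    chroms = genome.chroms
    lengths = np.array([genome.chrom_lengths[c] for c in chroms])
    chrom_probs = lengths / lengths.sum()
    flo, fhi = config.fragment_length_range

    def uniform_tags(n: int) -> pd.DataFrame:
        ci = rng.choice(len(chroms), size=n, p=chrom_probs)
        pos = (rng.random(n) * lengths[ci]).astype(np.int64)
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        return pd.DataFrame({"chrom": np.array(chroms, dtype=object)[ci],
                             "pos": pos, "strand": strand})

    sites = truth.sites_for(cell_line)
    n_site_tags = int(round(config.n_chip_tags * (1.0 - config.background_rate)))
    parts: list[pd.DataFrame] = []
    if sites and n_site_tags > 0:
        strengths = np.array([s.strength for s in sites])
        alloc = rng.multinomial(n_site_tags, strengths / strengths.sum())
        half_w = config.site_width // 2
        for site, k in zip(sites, alloc):
            if k == 0:
                continue
            jitter = rng.integers(-half_w, half_w + 1, size=k)
            frag_len = rng.integers(flo, fhi + 1, size=k)
            frag_centre = site.centre + jitter
            left = frag_centre - frag_len // 2
            right = left + frag_len - 1
            from_left = rng.random(k) < 0.5
            pos = np.where(from_left, left, right)
            strand = np.where(from_left, "+", "-")
            L = genome.chrom_lengths[site.interval.chrom]
            pos = np.clip(pos, 0, L - 1)
            parts.append(pd.DataFrame({"chrom": site.interval.chrom,
                                       "pos": pos.astype(np.int64),
                                       "strand": strand}))
    n_bg = config.n_chip_tags - (n_site_tags if sites else 0)
    if n_bg > 0:
        parts.append(uniform_tags(n_bg))
    chip_df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["chrom", "pos", "strand"])

    def add_multiplicity(df: pd.DataFrame) -> pd.DataFrame:
        n = len(df)
        mult = np.ones(n, dtype=np.int64)
        is_multi = rng.random(n) < config.multiread_fraction
        mult[is_multi] = rng.integers(2, config.multiread_max + 1,
                                      size=int(is_multi.sum()))
        df = df.copy()
        df["multiplicity"] = mult
        return df[TAG_COLUMNS]

    chip = TagLibrary(add_multiplicity(chip_df))
    input_lib = TagLibrary(add_multiplicity(uniform_tags(config.n_input_tags)))
    return chip, input_lib


# ---------------------------------------------------------------------------
# Expression simulation


def simulate_expression(
    truth: SimTruth,
    genes: Sequence[GeneModel],
    config: SimConfig,
    cell_line: str = "cellA",
) -> pd.DataFrame:
    """Per-transcript, per-timepoint log2 fold change and differential p.

    Regulated genes exceed ``de_fc_effect`` (linear) at their regulated
    time points with a low p; everything else is null noise (log2 FC
    ~ N(0, de_p_noise), p ~ U(0, 1)).
    """
    rng = _stage_rng(config.seed, f"expression_{cell_line}")
    regulated = {g.gene_id: g for g in truth.regulated_for(cell_line)}
    rows = []
    log2_effect = np.log2(config.de_fc_effect)
    for gene in genes:
        reg = regulated.get(gene.gene_id)
        for t in config.timepoints:
            if reg is not None and t in reg.timepoints:
                sign = 1.0 if reg.direction == "up" else -1.0
                lfc = sign * (log2_effect + rng.exponential(0.4))
                p = 10.0 ** (-rng.uniform(3.0, 8.0))
            else:
                lfc = rng.normal(0.0, config.de_p_noise)
                p = rng.uniform(0.0, 1.0)
            rows.append((gene.gene_id, t, lfc, p))
    return pd.DataFrame(rows, columns=["transcript_id", "timepoint",
                                       "log2_fc", "diff_p"])


# ---------------------------------------------------------------------------
# One-call study bundle


@dataclass
class SimData:
    config: SimConfig
    genome: Genome
    genes: list[GeneModel]
    truth: SimTruth
    chip: dict[str, TagLibrary]
    input_control: dict[str, TagLibrary]
    expression: dict[str, pd.DataFrame]


def simulate_study(config: SimConfig) -> SimData:
    """Run every generator stage for both cell lines."""
    genome, genes = simulate_genome(config)
    truth = plant_binding_sites(genome, genes, config)
    chip: dict[str, TagLibrary] = {}
    ctrl: dict[str, TagLibrary] = {}
    expr: dict[str, pd.DataFrame] = {}
    for line in CELL_LINES:
        chip[line], ctrl[line] = simulate_tags(genome, truth, config, line)
        expr[line] = simulate_expression(truth, genes, config, line)
    return SimData(config, genome, genes, truth, chip, ctrl, expr)


def write_study(data: SimData, outdir) -> None:
    """Write FASTA genome, gene/tag TSVs, truth JSON-lines and expression."""
    from .regions import write_genes_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if data.genome.sequences is not None:
        data.genome.write_fasta(out / "genome.fa")
    write_genes_tsv(data.genes, out / "genes.tsv")
    data.truth.write_jsonl(out / "truth.jsonl")
    for line in CELL_LINES:
        data.chip[line].write_tsv(out / f"chip_{line}.tsv")
        data.input_control[line].write_tsv(out / f"input_{line}.tsv")
        data.expression[line].to_csv(out / f"expression_{line}.tsv",
                                     sep="\t", index=False)
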