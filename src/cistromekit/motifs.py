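"""PWM scanning with exact p-values, PRE classification and motif enrichment.

The hormone response element bound by the progesterone receptor (PRE) is a
15-bp palindrome, consensus ``RGNACAnnnTGTNCY``.  Occurrences are scored
with a position-specific probability matrix; each score gets an exact
p-value P(S >= s) under the background model, computed by dynamic
programming over the quantized score distribution (the FIMO convention:
log-odds are quantized once to a fine integer grid, and both the null
distribution and every observed window score live on that grid, so the
lookup is self-consistent).

Match strength bins follow the reporting convention: strong p < 1e-5,
moderate 1e-5 <= p <= 1e-3, weak/absent p > 1e-3.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .regions import GenomicInterval
from .stats import hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "MotifHit",
    "PositionalDistribution",
    "PRE_FULL_CONSENSUS",
    "PRE_CORE_CONSENSUS",
    "FOXA1_CONSENSUS",
    "NF1_CONSENSUS",
    "AP1_CONSENSUS",
    "IUPAC_SETS",
    "revcomp",
    "gc_content",
    "pwm_from_iupac",
    "pwm_score",
    "pwm_pvalue",
    "scan_regions",
    "classify_strength",
    "match_iupac",
    "build_matched_background",
    "enrichment_test",
    "cooccurrence_table",
    "positional_distribution",
    "read_meme",
    "write_meme",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Full-length PRE palindrome and the conserved core; cofactor consensi are
# the canonical forkhead, NF1 half-palindrome and TPA-response elements.
PRE_FULL_CONSENSUS = "RGNACANNNTGTNCY"
PRE_CORE_CONSENSUS = "CWNNNTGTNC"
FOXA1_CONSENSUS = "TRTTKRYTY"
NF1_CONSENSUS = "TTGGCNNNNNGCCAA"
AP1_CONSENSUS = "TGASTCA"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    gc = sum(1 for b in seq if b in "GCgc")
    return gc / len(seq)


# ---------------------------------------------------------------------------
# PWM


@dataclass
class PWM:
    """Position-specific probability matrix with a 0-order background.

    ``probs`` is (width, 4) over A, C, G, T.  A pseudocount is mixed in and
    renormalized before any log-odds computation, so zero entries stay
    finite.  ``qdelta`` is the quantization grid (bits) for the exact
    p-value dynamic programming; per-position log-odds are floored onto
    that grid, a conservative rounding.
    """

    name: str
    probs: np.ndarray
    pseudocount: float = 0.001
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    qdelta: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, float)
        self.background = np.asarray(self.background, float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if self.width < 2:
            raise ValueError("motif width must be >= 2")
        adj = self.adjusted_probs
        if not np.allclose(adj.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probabilities must sum to 1 per position")
        self._dist_cache: Optional[tuple[int, np.ndarray]] = None

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def adjusted_probs(self) -> np.ndarray:
        return (self.probs + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        """Exact per-position log2(p/background); -inf for zero probability."""
        with np.errstate(divide="ignore"):
            return np.log2(self.adjusted_probs / self.background[None, :])

    @property
    def qscores(self) -> np.ndarray:
        """Integer log-odds on the ``qdelta`` grid (floor rounding).

        Per-position log-odds are clamped at -100 bits so zero
        probabilities (pseudocount 0) stay on a finite grid.
        """
        clamped = np.maximum(self.log_odds, -100.0)
        return np.floor(clamped / self.qdelta + 1e-9).astype(np.int64)

    # -- scoring ----------------------------------------------------------

    def _encode(self, window: str) -> Optional[np.ndarray]:
        try:
            return np.fromiter((BASE_INDEX[b] for b in window.upper()),
                               dtype=np.int64, count=self.width)
        except KeyError:
            return None

    def score(self, window: str) -> float:
        """Exact log-odds score; NaN for windows with ambiguous bases."""
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != width {self.width}")
        idx = self._encode(window)
        if idx is None:
            return float("nan")
        return float(self.log_odds[np.arange(self.width), idx].sum())

    def qscore(self, window: str) -> Optional[int]:
        idx = self._encode(window)
        if idx is None:
            return None
        return int(self.qscores[np.arange(self.width), idx].sum())

    # -- exact null distribution ------------------------------------------

    def _distribution(self) -> tuple[int, np.ndarray]:
        """(min_qscore, probability array) of the quantized score under
        the background, by positionwise convolution."""
        if self._dist_cache is not None:
            return self._dist_cache
        q = self.qscores
        bg = self.background
        lo = hi = 0
        dist = np.ones(1)
        for i in range(self.width):
            qmin, qmax = int(q[i].min()), int(q[i].max())
            new_lo, new_hi = lo + qmin, hi + qmax
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                shift = int(q[i, b]) - qmin
                new[shift:shift + len(dist)] += dist * bg[b]
            lo, hi, dist = new_lo, new_hi, new
        self._dist_cache = (lo, dist)
        return self._dist_cache

    def qscore_pvalue(self, qscore: int) -> float:
        """P(Q >= qscore) under the background; clamped into (0, 1]."""
        lo, dist = self._distribution()
        hi = lo + len(dist) - 1
        if qscore <= lo:
            return 1.0
        if qscore > hi:
            qscore = hi  # scores above the attainable max get the min tail
        tail = float(dist[qscore - lo:].sum())
        return min(max(tail, np.nextafter(0, 1)), 1.0)

    def score_pvalue(self, score: float) -> float:
        """p-value for an exact float score, via the quantized grid."""
        if math.isnan(score):
            raise ValueError("score must not be NaN")
        if score == -math.inf:
            return 1.0
        score = max(score, -100.0 * self.width)
        return self.qscore_pvalue(int(math.floor(score / self.qdelta + 1e-9)))


def pwm_score(pwm: PWM, window: str) -> float:
    return pwm.score(window)


def pwm_pvalue(pwm: PWM, score: float) -> float:
    return pwm.score_pvalue(score)


def pwm_from_iupac(pattern: str, name: str = "motif") -> PWM:
    """Build a PWM from an IUPAC consensus: allowed bases split evenly."""
    rows = []
    for ch in pattern.upper():
        allowed = IUPAC_SETS.get(ch)
        if allowed is None:
            raise ValueError(f"invalid IUPAC character {ch!r}")
        row = np.zeros(4)
        for b in allowed:
            row[BASE_INDEX[b]] = 1.0 / len(allowed)
        rows.append(row)
    return PWM(name=name, probs=np.array(rows))


# ---------------------------------------------------------------------------
# Scanning and classification

STRENGTH_STRONG = "strong"
STRENGTH_MODERATE = "moderate"
STRENGTH_WEAK = "weak_absent"


def classify_strength(pvalue: float) -> str:
    """Bin a match p-value: strong < 1e-5 <= moderate <= 1e-3 < weak."""
    if not (0.0 < pvalue <= 1.0):
        raise ValueError(f"p-value must be in (0, 1], got {pvalue}")
    if pvalue < 1e-5:
        return STRENGTH_STRONG
    if pvalue <= 1e-3:
        return STRENGTH_MODERATE
    return STRENGTH_WEAK


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: int              # motif midpoint relative to region centre, bp
    strand: str
    score: float             # exact log2 odds
    pvalue: float
    strength_class: str
    is_best: bool = False


def scan_regions(
    pwm: PWM,
    region_sequences: Mapping[str, str],
    report_p: float = 0.01,
) -> list[MotifHit]:
    """Scan both strands of each region sequence, reporting hits p < report_p.

    Offsets are measured from the sequence centre to the motif midpoint.
    At a given position, opposite-strand hits are collapsed to the lower
    p-value (tie -> plus strand).  Per region, the single best hit is
    flagged ``is_best``.  Sequences shorter than the motif are skipped.
    """
    w = pwm.width
    q = pwm.qscores
    # scoring the reverse complement of a window equals scoring the window
    # with positions reversed and bases complemented
    q_rc = q[::-1, ::-1]
    lo, dist = pwm._distribution()
    sf = np.minimum(np.cumsum(dist[::-1])[::-1], 1.0)
    tiny = float(np.nextafter(0, 1))

    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i

    hits: list[MotifHit] = []
    n_skipped = 0
    for region_id, seq in region_sequences.items():
        if len(seq) < w:
            n_skipped += 1
            continue
        centre = len(seq) // 2
        codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        valid = (windows >= 0).all(axis=1)
        safe = np.where(windows >= 0, windows, 0)
        cols = np.arange(w)
        q_fwd = q[cols, safe].sum(axis=1)
        q_rev = q_rc[cols, safe].sum(axis=1)
        # collapse opposite-strand hits at one position: better score wins,
        # ties go to the plus strand
        use_rev = q_rev > q_fwd
        q_best = np.where(use_rev, q_rev, q_fwd)
        idx = np.clip(q_best - lo, 0, len(sf) - 1)
        pvals = np.where(q_best <= lo, 1.0, np.maximum(sf[idx], tiny))
        keep = valid & (pvals < report_p)

        region_hits: list[MotifHit] = []
        for i in np.flatnonzero(keep):
            strand = "-" if use_rev[i] else "+"
            window = seq[i:i + w].upper()
            oriented = window if strand == "+" else revcomp(window)
            p = float(pvals[i])
            region_hits.append(MotifHit(
                region_id=region_id,
                offset=int(i) + w // 2 - centre,
                strand=strand,
                score=pwm.score(oriented),
                pvalue=p,
                strength_class=classify_strength(p),
            ))
        if region_hits:
            best_idx = min(
                range(len(region_hits)),
                key=lambda j: (region_hits[j].pvalue,
                               abs(region_hits[j].offset),
                               region_hits[j].strand != "+"),
            )
            for j, h in enumerate(region_hits):
                hits.append(MotifHit(h.region_id, h.offset, h.strand, h.score,
                                     h.pvalue, h.strength_class,
                                     is_best=(j == best_idx)))
    if n_skipped:
        logger.warning("scan_regions: skipped %d region(s) shorter than motif width",
                       n_skipped)
    return hits


def match_iupac(pattern: str, sequence: str) -> list[tuple[int, str]]:
    """All (offset, strand) where the IUPAC pattern matches exactly.

    A minus-strand match at offset i means the reverse complement of
    ``sequence[i:i+len]`` matches the pattern.
    """
    pattern = pattern.upper()
    for ch in pattern:
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC character {ch!r}")
    seq = sequence.upper()
    out: list[tuple[int, str]] = []
    for strand, pat in (("+", pattern), ("-", revcomp(pattern))):
        sets = [IUPAC_SETS[ch] for ch in pat]
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + j] in sets[j] for j in range(len(pat))):
                out.append((i, strand))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Matched background and enrichment


def build_matched_background(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    n_per_region: int = 2,
    gc_tolerance: float = 0.05,
    max_tries: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> list[GenomicInterval]:
    """Sample GC-matched background intervals avoiding the foreground.

    For each foreground region, ``n_per_region`` intervals of the same
    length are drawn uniformly from the genome, rejected if they overlap
    any foreground region or their GC differs from the foreground's by
    more than ``gc_tolerance``; after ``max_tries`` draws the nearest-GC
    non-overlapping candidate is kept.
    """
    rng = rng or np.random.default_rng()
    fg_trees: dict[str, IntervalTree] = {}
    for iv in regions:
        fg_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], float)
    if lengths.sum() <= max(iv.length for iv in regions):
        raise ValueError("genome too small to sample background intervals")
    probs = lengths / lengths.sum()

    background: list[GenomicInterval] = []
    for iv in regions:
        fg_gc = gc_content(genome[iv.chrom][iv.start:iv.end])
        for _ in range(n_per_region):
            best: Optional[tuple[float, GenomicInterval]] = None
            chosen: Optional[GenomicInterval] = None
            for _try in range(max_tries):
                c = chroms[rng.choice(len(chroms), p=probs)]
                if len(genome[c]) <= iv.length:
                    continue
                start = int(rng.integers(0, len(genome[c]) - iv.length))
                tree = fg_trees.get(c)
                if tree and tree.overlap(start, start + iv.length):
                    continue
                cand = GenomicInterval(c, start, start + iv.length)
                dgc = abs(gc_content(genome[c][start:start + iv.length]) - fg_gc)
                if dgc <= gc_tolerance:
                    chosen = cand
                    break
                if best is None or dgc < best[0]:
                    best = (dgc, cand)
            if chosen is None:
                if best is None:
                    raise ValueError("could not place a background interval")
                chosen = best[1]  # nearest-GC fallback
            background.append(chosen)
    return background


def enrichment_test(fg_hit_count: int, fg_total: int,
                    bg_hit_count: int, bg_total: int) -> float:
    """One-sided motif enrichment p: cumulative hypergeometric tail.

    Foreground regions are the draw, foreground+background the population,
    and all hit regions the successes — P(X >= observed foreground hits).
    """
    if min(fg_hit_count, fg_total, bg_hit_count, bg_total) < 0:
        raise ValueError("counts must be non-negative")
    if fg_hit_count > fg_total or bg_hit_count > bg_total:
        raise ValueError("hits cannot exceed totals")
    return hypergeom_tail(
        k=fg_hit_count,
        K=fg_hit_count + bg_hit_count,
        n=fg_total,
        N=fg_total + bg_total,
    )


def cooccurrence_table(
    hits_by_motif: Mapping[str, set],
    universe: Optional[set] = None,
    subsets: Optional[Iterable[tuple[str, ...]]] = None,
) -> dict[tuple[str, ...], int]:
    """Count regions carrying every motif of each queried combination.

    Default subsets are all singletons plus all pairs.  When a universe is
    given, only regions in it are counted.
    """
    motifs = sorted(hits_by_motif)
    if subsets is None:
        subsets = [(m,) for m in motifs] + [
            (a, b) for i, a in enumerate(motifs) for b in motifs[i + 1:]
        ]
    out: dict[tuple[str, ...], int] = {}
    for subset in subsets:
        common: Optional[set] = None
        for m in subset:
            s = set(hits_by_motif[m])
            common = s if common is None else common & s
        common = common or set()
        if universe is not None:
            common &= set(universe)
        out[tuple(subset)] = len(common)
    return out


# ---------------------------------------------------------------------------
# Positional statistics


@dataclass(frozen=True)
class PositionalDistribution:
    offsets: np.ndarray
    normality_p: float
    mean: float
    sd: float


def positional_distribution(hits: Sequence[MotifHit]) -> PositionalDistribution:
    """Best-hit offsets about the region centre plus a normality screen.

    A directly bound motif should pile up symmetrically under the summit;
    the one-sample KS p against Normal(mean, sd) quantifies that.
    """
    from .stats import ks_one_sample_normal

    best = [h for h in hits if h.is_best] or list(hits)
    if len(best) < 8:
        raise ValueError("positional_distribution requires >= 8 hits")
    offsets = np.array([h.offset for h in best], float)
    if np.std(offsets, ddof=1) == 0:
        raise ValueError("degenerate offsets: zero standard deviation")
    res = ks_one_sample_normal(offsets)
    return PositionalDistribution(offsets, res.pvalue,
                                  float(offsets.mean()),
                                  float(offsets.std(ddof=1)))


# ---------------------------------------------------------------------------
# MEME minimal motif format


def load_bundled_motifs() -> list[PWM]:
    """The bundled motif set: full/core PRE plus FOXA1, NF1 and AP-1,
    each built from its consensus with degenerate positions split evenly
    (synthetic stand-ins for matrices learned de novo from ChIP data)."""
    from importlib.resources import files

    text = files("cistromekit.data").joinpath("motifs.meme").read_text()
    return read_meme(text)


def read_meme(text: str) -> list[PWM]:
    """Parse motifs from MEME minimal format text."""
    background = np.full(4, 0.25)
    bg_match = re.search(
        r"Background letter frequencies.*?\nA\s+([\d.eE+-]+)\s+C\s+([\d.eE+-]+)"
        r"\s+G\s+([\d.eE+-]+)\s+T\s+([\d.eE+-]+)",
        text,
    )
    if bg_match:
        background = np.array([float(g) for g in bg_match.groups()])
        background = background / background.sum()

    pwms: list[PWM] = []
    motif_blocks = re.split(r"(?m)^MOTIF\s+", text)[1:]
    for block in motif_blocks:
        lines = block.strip().splitlines()
        name = lines[0].split()[0]
        rows: list[list[float]] = []
        in_matrix = False
        for line in lines[1:]:
            if line.lower().startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                parts = line.split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                elif rows:
                    break
        if not rows:
            raise ValueError(f"motif {name!r}: no probability matrix found")
        pwms.append(PWM(name=name, probs=np.array(rows),
                        background=background.copy()))
    return pwms


def write_meme(pwms: Sequence[PWM]) -> str:
    if not pwms:
        return "MEME version 4\n"
    bg = pwms[0].background
    out = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}",
        "",
    ]
    for pwm in pwms:
        out.append(f"MOTIF {pwm.name}")
        out.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 20 E= 0"
        )
        for row in pwm.probs:
            out.append(" " + " ".join(f"{x:.6f}" for x in row))
        out.append("")
    return "\n".join(out) + "\n"
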