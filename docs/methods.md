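# Methods

This note documents the models, numerical choices and limitations of the
package; nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Peak calling

The caller implements the documented parameter semantics of
shift-and-threshold tag-cluster methods for transcription-factor ChIP-seq;
it is not a bit-for-bit reproduction of any particular tool's internals.

1. **Strand shift.** Sequenced tags mark fragment ends, so plus- and
   minus-strand pileups flank a binding site by about half the fragment
   length. `learn_shift` finds 1-kb windows holding ≥ 10 weighted tags,
   estimates (modal minus position − modal plus position)/2 per window
   (10-bp binned mode, leftmost tie), and returns the median, floored at
   zero. With U[200, 400] fragments the truth is ~150 bp; the learned value
   is within a few bp at the default library sizes.
2. **Weighted clustering.** Tags shifted ±shift by strand, weighted
   1/multiplicity (multireads above the multiplicity cap of 10 are
   dropped). Maximal runs with inter-tag gaps ≤ `merge_gap` (200 bp ≈ the
   minimum fragment length) form candidates.
3. **Thresholds.** A candidate is kept when its weighted tag sum reaches
   `min_rpm` (default 10) reads-per-million of the ChIP library *and*
   exceeds the control sum — scaled by the library-size ratio and floored
   at one pseudo-tag so sparse control windows never divide by zero — by
   `fold_threshold` (default 4). RPM normalizes by the aligned-tag count,
   not the weighted count.
4. **Summit.** Position maximizing the weighted tag count in a ±30 bp
   window, leftmost on exact ties. The window is deliberately narrow
   relative to the post-shift tag spread (± fragment/3): a window that
   blankets the whole cluster creates a tie plateau whose leftmost point
   biases the summit left by tens of bp.
5. **FDR.** The swap estimate |peaks(control vs ChIP)| / |peaks(ChIP vs
   control)|, with the shift resolved once from the ChIP library and
   reused in both directions. `None` marks the undefined case (no forward
   peaks).

Absolute thresholds only separate signal from noise when tag densities are
in a realistic regime; the package therefore uses two canonical synthetic
configurations (below) rather than shrinking thresholds to toy scales.

## Motif analysis

**Scores.** A match scores Σ log₂(p(base)/background(base)) over positions,
with probabilities pseudocount-adjusted (default 0.001) and renormalized.
Windows containing ambiguous bases score NaN and are skipped.

**Exact p-values.** `P(S ≥ s)` under the 0-order background is computed by
dynamic programming over the score distribution. Following the convention
of exact-scan tools, the per-position log-odds are quantized once onto a
0.01-bit integer grid (floor rounding — conservative; −∞ entries clamp to
−100 bits), and *both* the DP distribution and every observed window score
live on that grid, so the survival lookup is self-consistent. The DP is a
positionwise convolution of an integer-indexed probability array; the test
suite checks it against brute-force enumeration of all 4⁸ windows scored
through an independent summation path (agreement ≤ 10⁻⁶ absolute).
`pwm_score` itself returns the exact float log-odds.

**Strength classes.** strong: p < 10⁻⁵; moderate: 10⁻⁵ ≤ p ≤ 10⁻³ (both
bounds in the moderate bin, matching the strict `<` of the strong class);
weak/absent above. When deciding whether a *region* "contains" a PRE over a
±400 bp scan, the pipeline requires a strong match: at ~1600 windows per
region, a p < 0.01 report threshold hits almost every region by chance,
while the strong class keeps the per-region false rate near 1%.

**Scanning.** Both strands at every offset; at one position the
opposite-strand pair collapses to the better score (tie → plus). Offsets
run from the sequence centre to the motif midpoint; per region the single
lowest-p hit is flagged best.

**Enrichment.** One-sided cumulative hypergeometric tail: foreground
regions are the draw, foreground + background the population, hit regions
the successes. Background intervals are length-matched, sampled uniformly
outside the foreground, GC within ±5 points of their foreground region
(200 tries, then nearest-GC fallback). Background GC autonormalization
beyond this simple matching is not modelled.

**Positional statistics.** Best-hit offsets are screened for normality
with a one-sample KS test against Normal(mean, sd). Because the
parameters are estimated from the sample, the Lilliefors-corrected
p-value (statsmodels) is used: with the uncorrected Kolmogorov p, a
uniform offset sample of n = 500 lands almost exactly on the 5% critical
value (D ≈ 0.058 vs 0.061) and rejection becomes a coin flip, which
defeats the purpose of the screen. D is reported as the ordinary
ECDF-vs-CDF sup gap.

## Statistical kernel

Thin wrappers over scipy.stats / statsmodels, each returning a uniform
`TestResult`:

- `ks_two_sample`: exact p for max(n) ≤ 100, asymptotic beyond. The
  asymptotic form at n ≈ 15 deviates from the permutation null by more
  than Monte-Carlo error, so the exact method is the default at the
  sample sizes where the pipeline's distance comparisons operate.
- `kruskal_wallis`: H with tie correction, chi-square p; all-identical
  input returns H = 0, p = 1 instead of an error.
- `hypergeom_tail` / `fisher_exact_2x2`: log-space survival function; the
  one-sided Fisher p is identical to the tail on the table's margins
  (asserted over random tables).
- `welch_t`: unpaired, Welch–Satterthwaite df (the robust default when
  the variance assumption is unstated); `ols`/`pearson_r2`: textbook.

Tests verify every primitive against explicit pmf summation, hand
arithmetic, or 10⁴-draw permutation oracles written independently of
scipy's code paths.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions; all defaults were fixed from
the emulated system's reported characteristics or from conventional
practice, before any recovery statistics were examined.

**Genome and genes.** Uniform i.i.d. bases (default 4 × 5 Mb with
sequence); genes 5–20 kb, random strands, TSSs ≥ 2 kb apart.

**Sites.** 60 per cell line (default), 100 bp wide, 25% shared between
lines (coordinate-identical). 60% of sites receive a PRE — the consensus
`RGNACAnnnTGTNCY` instantiated by sampling each degenerate position
uniformly — written into the sequence at a N(0, 50 bp) offset from the
site centre, random strand. Cofactor words are planted per line with the
emulated asymmetry (cell line A: FOXA1 0.44 / NF1 0.05 / AP-1 0.10;
cell line B: 0.05 / 0.23 / 0.28); shared sites, which have one sequence,
use the two lines' mean probabilities, so per-line cofactor fractions are
asserted on line-unique sites.

**Regulated genes and linkage.** 30% of genes are regulated per line
(directions drawn from the per-line up:down ratio, 8.0 for the
cancer-like line and 0.88 for the normal-like line); exactly 60% of them
are *linked*: a dedicated site is placed at TSS ± d with d exponential
(mean 44 kb for up-regulated, 75 kb for down-regulated), resampled into
[1, 100] kb. Linked counts are fixed at their expectation; which genes are
linked is random. The remaining (unlinked) regulated genes are drawn from
genes with *no* same-line site within 100 kb — at desk-scale genome sizes,
chance proximity would otherwise contaminate the planted fraction and the
association stage could not be scored against it. Regulated time points
are random non-empty subsets of {2, 6, 24} h.

**Tags.** ChIP fragments are U[200, 400] bp centred (± half site width
jitter) on sites, allocated across sites in proportion to a lognormal
site strength (linked sites boosted 2×, so peak height correlates with
regulation); each fragment is sequenced from a uniformly chosen end —
plus-strand tags at left ends, minus at right. A configurable fraction of
ChIP tags (default 0.1) and the whole input library are uniform; 10% of
tags get multiplicity 2–10.

**Expression.** Regulated transcripts at regulated time points get
log₂FC = ±(log₂ 2.0 + Exp(0.4)) with p = 10^−U(3,8); everything else is
N(0, 0.1) noise with uniform p.

**Two canonical configurations.**
*Desk pipeline* (default): 20 Mb with sequence, 50 k ChIP / 5 k input
tags, background rate 0.1 — sized so motif scanning and association run in
seconds while the absolute caller thresholds still separate signal from
background (expected spurious clusters < 1).
*Sequencing scale* (used for peak-caller recovery): 100 Mb without
sequence, 100 sites, background rate 0.5, 20 k ChIP / 10 k input tags —
the regime where the swap-FDR statistic is meaningful.

**Determinism.** Every stage draws from its own sub-stream derived from
the master seed, so partial re-runs and full runs are byte-identical.

**What passing recovery tests does not show.** Real ChIP-seq background is
non-uniform (chromatin accessibility, mappability, GC), fragment sizes are
not uniform, binding sites are not disjoint from each other or from genes,
input libraries share the chromatin biases of the ChIP, expression noise
is heavier-tailed than the planted model, and the "unlinked genes are
clean" construction removes the chance-association ambiguity that real
data always carries. Recovery here demonstrates correctness of the
implementations under their stated models, not performance on real
libraries.

## Association and reporting conventions

- Distances are region **midpoint** to TSS, signed negative upstream; the
  nearest gene breaks ties by lexicographic id. All windowed accounting is
  TSS-anchored.
- Region-side counts attribute each region once, to its nearest gene of
  the relevant class; gene-side counts apply the direct criterion (≥ 1
  region midpoint within the window of the TSS), so one region between two
  regulated genes marks both genes associated.
- Densities are regions-associated / genes-with-≥1-region, as true
  quotients rounded half-up to two decimals; percentages to one decimal;
  undefined ratios render as NA.
- SOM: Kohonen map, 3×3 default grid (nine time-course clusters), weights
  initialized from random data points, learning rate 0.5 → 0.01 and
  Gaussian neighbourhood max(grid)/2 → 0.5 both decaying exponentially
  over 2000 iterations; quantization error is logged and must not
  increase end-to-end. Deterministic under its seed.
- Metaprofiles: weighted, shift-corrected tags in 25-bp bins over ±2 kb of
  each anchor summit, averaged per region and normalized per bp; the
  central/flank ratio divides the central 10% of bins by the outer 20%.

## Known limitations

- The caller has no broad-domain mode and no paired-end support; candidate
  formation is point-tag clustering, so very low densities with tight
  absolute thresholds (toy scales) leave the fold filter as the only guard.
- PWM p-values assume a 0-order background; higher-order models and
  position-specific priors are out of scope, as is de novo motif
  discovery (matrices come from consensus patterns or MEME minimal files).
- The one-sample normality screen is a screen, not a calibrated test, for
  offsets that are integers with heavy central ties.
- Hierarchical clustering for display and any genome-browser output beyond
  plain BED are not implemented.
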