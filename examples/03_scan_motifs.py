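"""Scan peak sequences for PREs with exact p-values and strength classes.

Scores every window of +/-400 bp around each called summit against the
PRE probability matrix; a match's p-value is the exact probability that
a random background window scores at least as high.  Matches bin into
strong (p < 1e-5), moderate (1e-5..1e-3) and weak/absent classes.
"""

from collections import Counter

from cistromekit.motifs import load_bundled_motifs, positional_distribution, \
    scan_regions
from cistromekit.peaks import call_peaks_with_fdr
from cistromekit.pipeline import region_sequences
from cistromekit.simulate import SimConfig, simulate_study

data = simulate_study(SimConfig(seed=1))
peaks = call_peaks_with_fdr(data.chip["cellA"], data.input_control["cellA"])
seqs = region_sequences(peaks.regions, data.genome, window=400)

pre = next(p for p in load_bundled_motifs() if p.name == "PRE_full")
hits = scan_regions(pre, seqs, report_p=0.01)
best = [h for h in hits if h.is_best]

classes = Counter(h.strength_class for h in best)
print(f"regions scanned: {len(seqs)}; best-hit classes: {dict(classes)}")
strong_regions = {h.region_id for h in hits if h.strength_class == "strong"}
print(f"regions with a strong PRE: {len(strong_regions)} "
      f"(~60% of sites carry a planted PRE; chance strong hits are ~1%)")

strong_best = [h for h in best if h.strength_class == "strong"]
if len(strong_best) >= 8:
    res = positional_distribution(strong_best)
    print(f"strong-PRE offsets about the summit: mean {res.mean:.0f} bp, "
          f"sd {res.sd:.0f} bp, normality p = {res.normality_p:.3f} "
          "(planted offsets are N(0, 50))")
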