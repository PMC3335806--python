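# cistromekit

Cistrome–transcriptome integration for transcription-factor ChIP-seq,
exercised end to end on synthetic genomes with planted ground truth.

The package re-implements the analysis chain of a two-cell-line nuclear
receptor study — progesterone receptor (PR) binding mapped by ChIP-seq in a
breast cancer line and an immortalized normal line, integrated with
progestin-regulated expression at 2, 6 and 24 h:

- **Peak calling** with input control: tags re-centred by a learned strand
  shift, multireads weighted 1/multiplicity, candidates kept at ≥ 4-fold
  enrichment over the library-size-scaled input and ≥ 10 RPM, FDR estimated
  by swapping the ChIP and control roles.
- **Motif analysis**: scanning with position-specific probability matrices
  and *exact* match p-values `P(S ≥ s)` computed by dynamic programming over
  the quantized score distribution; hormone response element (PRE,
  consensus `RGNACAnnnTGTNCY`) strength classes (strong p < 10⁻⁵, moderate
  10⁻⁵–10⁻³, weak/absent above); IUPAC matching; hypergeometric enrichment
  against a GC-matched genomic background; cofactor (FOXA1/NF1/AP-1)
  co-occurrence; positional normality of motifs about summits.
- **Peak-to-gene association**: signed midpoint-to-TSS distances, windowed
  counts (1/10/50/100 kb), regulated-gene linkage, region-per-gene
  densities, up- vs down-regulated distance distributions (two-sample KS),
  peak-height comparisons (Welch t), per-chromosome binding-vs-gene-count
  regression.
- **Expression integration**: differential calls (p < 0.01 and fold change
  ≥ 1.5 at ≥ 1 time point), self-organizing-map clustering of time-course
  profiles, lost/gained/conserved regulation deltas with binding-distance
  analysis, transcriptome overlaps.
- **Tag-density metaprofiles** of one factor's tags around another factor's
  peak set.
- **A synthetic-data generator** that plants all of the above: two
  largely disjoint site sets with embedded motifs, sonication fragments of
  200–400 bp producing strand-shifted pileups, multireads, and regulated
  genes linked to sites with exponential distance decay (up-regulated genes
  closer than down-regulated).

Every stage can be scored against the generator's `SimTruth`.

## Worked example

```python
from cistromekit.simulate import SimConfig, simulate_study
from cistromekit.peaks import call_peaks_with_fdr
from cistromekit.regions import intersect

data = simulate_study(SimConfig(seed=1))
result = call_peaks_with_fdr(data.chip["cellA"], data.input_control["cellA"])
planted = [s.interval for s in data.truth.sites_for("cellA")]
parts = intersect(planted, [r.interval for r in result.regions])
print(result.shift, result.n_chip_peaks, result.fdr,
      len(parts["common_a"]), len(parts["unique_b"]))
```

prints

```
150 59 0.0 60 0
```

— the caller learned a 150 bp strand shift (fragments are U[200, 400], so
half the mean fragment length is the truth), called 59 peaks with a swap
FDR of 0, recovered all 60 planted sites (two sites merged into one
region), and called nothing that matches no planted site.  The scripts in
`examples/` walk through each capability the same way — simulation, peak
calling, motif scanning, gene association, expression integration and tag
profiles — each printing the numbers it computes and what they mean.

A thin CLI mirrors the stages for shell use:

```bash
cistromekit simulate --seed 1 --outdir study/
cistromekit callpeaks --chip study/chip_cellA.tsv --control study/input_cellA.tsv -o peaks.bed
cistromekit associate --peaks peaks.bed --genes study/genes.tsv \
    --regulated study/expression_cellA.tsv -o report.txt
```

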