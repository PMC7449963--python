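# fpk — ATAC-seq digital genomic footprinting

`fpk` is a library and command-line toolkit for inferring transcription
factor (TF) binding from ATAC-seq data by digital genomic footprinting:
a DNA-bound protein shields its site from the Tn5 transposase, leaving a
localized depletion ("footprint") in the per-base cut-site signal inside
accessible chromatin. The package covers the full analysis chain —

1. **Tn5 bias correction** — estimate the transposase's sequence
   preference as a dinucleotide weight matrix (DWM) and subtract the
   sequence-predictable part of the signal;
2. **footprint scoring** — a continuous per-base score combining the
   depth of the local depletion with the accessibility of the locus;
3. **binding-site detection** — motif scanning (log-odds PWM, p-value
   threshold), per-site scoring across conditions, quantile
   normalization, two-component bound/unbound classification, and
   per-TF differential binding with volcano-style statistics;
4. **aggregate diagnostics** — mean footprint profiles, the footprint
   depth (FPD) metric, and a randomized-null test for measurable
   footprints;
5. **motif clustering** by genomic binding-site overlap and **TF→TF
   network inference** from promoter binding;
6. a **simulator** generating genomes, peaks, bias, and footprints with
   known ground truth, used by the entire test suite.

It is aimed at computational biologists analyzing bulk ATAC-seq who
want per-TF, per-site and per-condition binding estimates without
ChIP-seq.

## The model in brief

**Bias model.** Around each insertion point a window of *k* = 20 bases
holds *k* − 1 overlapping ordered dinucleotides. The DWM stores, per
offset *r*, the probability of each dinucleotide at cut events
(*p*<sub>r</sub>) and at background positions (*q*<sub>r</sub>). The
per-position bias weight is the Markov likelihood ratio

  w(x) = [ ∏<sub>r</sub> p<sub>r</sub>(x)/q<sub>r</sub>(x) /
  ∏<sub>interior i</sub> m<sub>i</sub>(x)/u<sub>i</sub>(x) ]<sup>γ</sup>

with mononucleotide ratios m/u at interior window positions and a
scale exponent γ fitted by multinomial maximum likelihood. The
**expected** track redistributes each region's observed cut total
proportionally to w; the **corrected** track is observed − expected
(mean-zero per region).

**Footprint score.** For a candidate footprint window of width *w*
centered at *p* with flank means *L*, *R* and center mean *C* (signal
floored at 0, accessibility baseline restored):

  score(p) = max<sub>w</sub> [ max(0, (L+R)/2 − C) + max(0, (L+R)/2) ]

i.e. depletion + accessibility. The classical footprint occupancy
score FOS(p) = min<sub>w</sub> (C+1)/(L+1) + (C+1)/(R+1) is provided
as a baseline (emitted negated so higher = more bound).

**Bound/unbound.** Per motif and condition, a two-component Gaussian
mixture on log(1 + score) separates bound from unbound sites; the
threshold is the smallest score whose posterior for the high component
reaches 0.5.

**Differential binding.** Per motif, the difference of mean normalized
scores between conditions is standardized against subsampled background
site sets; z and a two-sided normal p-value are the volcano coordinates.
Per-site change is log2((s₂+1)/(s₁+1)).

**Clustering & networks.** Motif similarity = overlap coefficient of
binding-site sets (tree distance 1 − overlap, so 80% overlap = depth
0.2); complete-linkage trees are cut at 0.5. The network module draws
A→B edges when a site of motif A with log2FC > 0 (and bound in the
target condition) lies in the promoter window (−10 kb/+1 kb around the
TSS, strand-aware) of a gene encoding motif B; node levels are BFS
distances from a chosen source TF.

## Worked example

```bash
python examples/01_simulate_and_correct.py
```

prints

```
simulated 86308 cut events over 200 peaks
bias-model recovery: Pearson r = 0.988 over 304 DWM cells
fitted weight-scale exponent: 0.997
first peak: observed total 484, expected total 484.00, corrected sum -2.49e-14
```

The simulator implanted a known Tn5 dinucleotide preference; estimating
it back from the simulated cut events alone recovers the 304 DWM cells
at r = 0.988. The expected track redistributes exactly the observed cut
total (484 = 484) and the corrected track sums to zero — the correction
removes precisely the sequence-predictable signal. Continuing with

```bash
python examples/02_footprint_scoring.py
```

```
combined  AUROC = 0.911  (n = 300 sites)
FOS       AUROC = 0.834  (n = 300 sites)
```

the combined depletion+accessibility score separates truly bound from
unbound sites markedly better than the pure-depletion FOS baseline on
the same corrected signal. The remaining examples demonstrate
differential binding (`03`), aggregate footprints and the
measurable-footprint test (`04`), and clustering plus network inference
(`05`).

The same stages are available as a CLI:

```bash
fpk simulate --seed 1 --outdir sim/
fpk correct --fragments sim/fragments_cond1.bed --genome sim/genome.fa \
    --peaks sim/peaks.bed --outdir corr/
fpk run --config run_config.json   # full pipeline with manifest
```

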