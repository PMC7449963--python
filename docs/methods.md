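# Methods

This note documents the models, estimators and numerical choices behind
`fpk`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem left genuine freedom.

## Signal model and coordinates

All coordinates are 0-based half-open. A *cut event* is the single base
at which Tn5 inserted, derived from a fragment end with the standard
+4/−5 shifts that center both ends of the 9-bp target-site duplication
(configurable). Fragment ends are strand-typed: the start cut is a
plus-strand event, the end cut a minus-strand event. Pileup of events
over merged, disjoint peak regions gives the observed per-base track.

## Tn5 bias model (DWM)

Tn5 prefers certain sequences around its insertion point. We model a
window of `window` = 20 bases centered on the insertion point through
its 19 overlapping ordered dinucleotides. Estimation is by counting:
`dinuc_probs[r][d]` is the pseudocounted, row-normalized frequency of
dinucleotide `d` at offset `r` over all event-centered windows
(minus-strand events are reverse-complemented first), and
`background_probs` is built identically from every position of the
supplied regions (optionally a seeded subsample). Windows containing N
or extending past a chromosome end are skipped for counting and receive
weight 1 (background) when scoring. Mononucleotide frequencies per
window position are counted alongside.

**Weight formula.** The per-position weight is the first-order Markov
likelihood ratio,

    log w = Σ_r log(p_r/q_r)  −  Σ_{i interior} log(m_i/u_i),

raised to an exponent γ. Two facts motivate this over the plain product
of dinucleotide ratios. First, overlapping dinucleotides share bases, so
the product of per-offset marginal ratios is not the likelihood ratio of
the window; for a sequence preference composed of nearest-neighbour
terms the window distribution *is* first-order Markov, and the
dinucleotide/mononucleotide factorization above is its exact likelihood.
Second, residual dependence between offsets still inflates the dynamic
range of the raw product; the exponent γ is fitted once per dataset by
maximizing the multinomial likelihood of the observed within-region
counts (counts given region totals are multinomial with p ∝ w^γ; the
negative log-likelihood is convex in γ, solved by bounded scalar
minimization on [0, 3]). In practice γ lands near 1 (±0.03 on
simulations). With uniform mononucleotide matrices the formula reduces
to the plain product of dinucleotide ratios.

**Expected and corrected tracks.** Within each region, expected =
w/Σw × Σobserved (conserving the region total exactly), corrected =
observed − expected, optionally after a sliding-mean smooth
(`smooth_w`, default 1 = none; boundary mode "nearest"). Corrected
tracks are therefore mean-zero per region.

**Scoring input.** Footprint scoring needs the accessibility *level* as
well as the bias-free structure, so the scoring input is the corrected
track plus the region's mean observed coverage
(`BiasTrackBundle.scoring_track()`). This restores the positive
baseline that a mean-zero track lacks while keeping the local shape
bias-corrected.

## Footprint scores

For every position p and candidate footprint width w ∈ {8, 10, …, 20}
(flanks 30 bp), with center mean C and flank means L, R on the floored
(≥ 0) signal:

* combined score = max over w of max(0, (L+R)/2 − C) + max(0, (L+R)/2)
  — depletion plus accessibility, ≥ 0, 0 at out-of-bounds positions;
* FOS = min over w of (C+1)/(L+1) + (C+1)/(R+1), emitted negated so all
  scores share "higher = more bound". Strictly negative flank means
  (possible only when the floor is disabled) and out-of-bounds
  positions receive the worst finite value rather than −∞ so that
  downstream rank statistics stay defined.

Whether depletion and accessibility are combined additively is a
committed design choice of this package (the combiner is a single
function and easy to swap); the additive form satisfies every property
we require of it: accessibility-aware, monotone in depletion depth,
translation-equivariant, and strictly better than FOS on sparse
simulated data. Both scorers are implemented with cumulative sums and
verified against a direct O(n·w) reimplementation.

## Binding sites, normalization, classification, differential binding

Motifs are count PFMs; log-odds = log2 of pseudocounted column
probabilities over background base frequencies. The match threshold
corresponds to a motif-score p-value of 1e-4 under the background,
computed by exact DP convolution of the per-column score distributions
on a 1e-3 grid; the returned threshold is backed off by the worst-case
rounding (half a bin per column) so no qualifying site is lost, and for
short motifs whose minimal achievable p-value exceeds 1e-4 the maximum
score is used (only exact consensus matches). Both strands are scanned;
overlapping same-motif matches on a strand keep the higher score (ties:
leftmost).

Per-site score = maximum footprint-score value within the site extended
by ±L/2 (L = motif length). Across ≥ 2 conditions, full quantile
normalization maps each condition's sorted scores onto the mean of the
sorted scores (ties share interpolated reference values) — "activity"
comparisons are relative, not absolute. Bound/unbound is a 2-component
Gaussian mixture on log(1 + normalized score) per motif and condition
(≥ 50 sites required, else all-unbound; fits with component means
within 1e-3 or a weight < 0.01 are declared degenerate → all unbound).
The threshold is the smallest observed score with posterior ≥ 0.5 for
the higher-mean component.

Differential binding per motif: raw statistic = difference of mean
normalized scores (c2 − c1) over the motif's sites; its null scale is
estimated from 100 seeded random subsamples (size = the motif's site
count) of the pooled per-site differences across all motifs; z = (raw −
bg mean)/bg sd and p = two-sided normal tail. A zero background spread
yields z = 0, p = 1 with a warning. This subsampled-background z-test
is a reconstruction choice; it is approximately calibrated (≲ 5% of
motifs at p < 0.05 under exchangeable labels in our checks) and has the
property that motifs over-represented in the pool are conservatively
diluted. Per-site log2FC = log2((s₂+pc)/(s₁+pc)), pc = 1.

## Aggregate profiles and FPD

Aggregate profile = per-offset mean signal over a motif's sites,
centered with 60-bp flanks, minus-strand sites flipped; sites whose
window leaves the containing region are skipped. FPD = (mean of the
20-bp flank windows immediately outside the motif − mean of the motif
window) / flank mean — a relative depth, comparable across TFs with
different accessibility. Mean-zero corrected profiles have no flank
level of their own, so `footprint_depths()` normalizes the observed,
expected and corrected FPDs of one site set by the *observed* flank
level; `fpd()` accepts an explicit denominator for the same purpose.
The measurable-footprint test compares the observed FPD against FPDs of
aggregates built from equally many uniformly sampled in-peak positions
(seeded; measurable ⇔ above the null's 95th percentile). Null positions
are restricted to peaks to preserve accessibility composition.

## Motif clustering and TF networks

Motif similarity is the overlap coefficient: the fraction of the
*smaller* site set overlapping the other set by ≥ 1 bp (denominator =
min size, so a motif nested in a larger motif's repertoire clusters
tightly). Distance = 1 − overlap; agglomerative clustering with
complete linkage (scipy backend, ids pre-sorted lexicographically for
deterministic ties), flat cut at 0.5. The linkage method and
denominator are configurable; both are reconstruction choices.

Promoter windows span −10000/+1000 around the TSS, strand-aware; a site
may be assigned to several genes, sites hitting none are "intergenic".
Network edges A→B require a site of motif A with log2FC > 0 — and, by
default, bound in the target condition — in the promoter of a gene
encoding motif B; the bound requirement is a flag
(`require_bound=False` relaxes it). Levels are BFS distances from the
source motif (networkx backend, independent BFS oracle in tests);
self-edges are recorded but do not affect levels; nodes beyond
`max_level` (default 2 → three layers) are pruned.

## The synthetic-data generator

The generator emulates: (i) i.i.d. uniform background genome; (ii)
non-overlapping peaks (default 200 peaks of 500 bp on 2×100 kb) with
per-peak accessibility drawn log-normal(0, 0.8) — real peak intensities
span about an order of magnitude; (iii) a true Tn5 DWM, drawn with
per-cell log-weights N(0, 0.35·bias_strength) plus a fixed CG/GC
penalty of 0.6·bias_strength, made reverse-complement symmetric (Tn5
acts as a homodimer) and double-centered per offset so the preference is
a pure dinucleotide coupling — a mononucleotide component of overlapping
dinucleotides would leak into neighbouring offsets of any per-offset
counting estimator and make the model unidentifiable by the estimator
the package uses; (iv) motif instances implanted at known positions
with 5% per-base mutation and random strand; (v) exact bound fractions
per motif and condition, the bound subset chosen by accessibility-
weighted sampling without replacement (weights ∝ accessibility²,
Gumbel-max keys) — occupancy concentrates in open chromatin; (vi) cut
intensity ∝ accessibility × bias weight, with bound sites depleted by
`footprint_depth` (default 0.5) over the motif and boosted 1.5× in
±50 bp flanks — bound TFs open the chromatin around their site, which
is what gives the accessibility term of the footprint score its
condition contrast; (vii) Poisson counts per base, emitted as minimal
fragments whose two shifted ends land on the sampled base (observed
counts are exactly twice the Poisson draw; fragment-length realism is
out of scope). Everything is reproducible bit-for-bit from the seed.

Not emulated: nucleosome phasing, fragment-length mixtures, replicate
variability, non-uniform genomic background composition, and TF
cooperativity. Consequently, passing tests demonstrate internal
consistency of the estimators under the stated generative assumptions,
not performance on real chromatin.

## Benchmark problem sizes

`fpk.benchmarks` freezes the study conditions for the headline checks:
bias recovery uses the default 200-peak genome at a coverage yielding
≥ 200k cut events; the false-footprint experiment uses 80 unique
10-bp motifs with graded CG/GC content, 40 sites each, on a 1.6 Mb /
1600-peak genome at reads_per_peak 800 — implants are kept to ~4% of
accessible sequence because dense repeated motif islands violate the
Markov window assumption and re-introduce motif-correlated correction
residuals, and the across-motif correlation bound (|r| < 0.3) has a
null standard deviation of 1/√(n−1), which n = 80 motifs keeps at ~2.7
standard deviations. Score-superiority and conservation checks run on
generator defaults; differential power/calibration run on synthetic
normalized-score cohorts (50 motifs × 100 sites).

## Numerical and degenerate-input conventions

Bias weights are computed in log space; expected tracks conserve totals
to < 1e-6 relative; corrected sums are < 1e-6 per bp. Zero-count
regions produce all-zero expected tracks. Regions shorter than
2·flank + max(width) score zero with a warning. The mixture classifier
refuses non-finite scores and returns all-unbound below 50 sites.
Quantile normalization of a single condition is the identity. The DP
threshold grid is 1e-3; exhaustive enumeration over all 4^L k-mers
(L ≤ 10) serves as the test oracle. All stochastic components
(background subsampling, mixture initialization, differential
background, simulator) take explicit seeds and are covered by
determinism tests.
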