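# Methods

## Data model and coordinate conventions

All interval tracks (BED, bedGraph, ibed interaction tables) are 0-based
half-open. Array-manifest CpG positions are 1-based single-bp, the
convention of EPIC-style manifests. The two conventions meet in exactly one
function (`io_formats.pos1_in_interval`): a 1-based position *p* lies in
[start, end) iff start ≤ p − 1 < end. Every downstream containment test (TF
sites, PCHi-C other-ends, CTCF motifs) routes through this rule, so boundary
semantics cannot drift between stages. Strand is parsed but ignored by
overlaps: CpG methylation is read out symmetrically on both strands.

Beta values are methylation fractions in [0, 1]. Statistics for the
differential filter are computed on the beta scale because the magnitude
threshold (|Δβ| ≥ 0.66) is defined there; an M-value transform
(log2(β/(1−β))) is available for the significance test only, never for the
Δβ filter.

## Differential CpG calling

A probe passes when both hold: *p* < 0.05 (strict) and |Δβ| ≥ 0.66
(inclusive; an epsilon of 1e−12 absorbs binary rounding of thresholds like
0.66 so an exact-boundary change passes). Δβ is the difference of replicate
means between 168 h and 0 h. The default test is Welch's *t* between the
two endpoint replicate groups, matching the endpoint semantics of Δβ; a
one-way *F* across all seven timepoints (`method="anova_f"`) detects
trajectories that move and return. *p* is unadjusted by default; BH
adjustment is available (`adjust="bh"`), in which case the significance
filter applies to the q-value.

Degenerate probes (zero variance in both groups) get *p* = 1 when the means
are equal, and the smallest positive float when they differ, keeping *p* in
(0, 1].

**Small-sample conservatism.** With 3 replicates per group, Welch's *t* is
conservative under the null: the Welch–Satterthwaite degrees of freedom are
estimated and fall below the pooled value whenever the two sample variances
differ, inflating critical values. Measured over null simulations the
rejection rate at α = 0.05 is ≈ 0.035. The one-way *F* across timepoints is
exactly F-distributed under this normal equal-variance null and rejects at
≈ 0.05. Calibration checks therefore assert the two-sided 5% band for the
*F* configuration and the one-sided bound (never anti-conservative) for
Welch.

Control concordance: a passing CpG is "macrophage-like" when its 168 h mean
beta is within `tol` = 0.2 of the positive-control mean **and** closer to
the positive than to the negative control. The tolerance is half the
smallest planted plateau gap, so genuinely converged probes pass while a
probe stuck at its starting level cannot.

## Local methylation–expression linkage

Per (passing gene-annotated CpG, annotated gene) pair, Pearson correlation
of the seven per-timepoint means of beta and expression. With *n* = 7 the
*t*-approximation for the correlation null is poor, so significance is an
exact two-sided permutation test: the fraction of all *n*! pairings
(identity included) with |r| ≥ |r_observed| (to 1e−12, so the observed
pairing always counts and ties are kept). Enumeration is exact for *n* ≤ 8
(5040 pairings at *n* = 7, vectorized); longer series fall back to 10,000
seeded Monte-Carlo permutations with the add-one estimator
(1 + hits)/(1 + m), which stays in (0, 1] and converges to the enumerated
value. Spearman (ranks, then the same machinery) is a config option.

Link classes encode methylation's default repressive reading: for a
hypomethylated CpG, r < 0 (expression up as beta falls) is *activation* and
r > 0 is *repression*; signs invert for hypermethylated CpGs. Expression is
used on the log2 scale as provided; genes missing from the expression matrix
are reported as uncovered rather than erroring. Each (probe, gene) link is
tested independently; BH across links is available but off by default.

## TF overlap and category enrichment

A CpG maps to TF *t* iff its converted position lies in ≥ 1 interval named
*t* (interval-tree lookup; an all-pairs scan is the test oracle). The
enrichment universe defaults to all TFs present in the supplied track —
the natural hermetic choice when the binding-site resource itself defines
which TFs were observable — and is configurable. P(X ≥ k) uses the
hypergeometric survival function; k = 0 returns exactly 1. BH adjustment
runs over all categories hit at least once; TFs with no category count in
the universe N but in no K. The category map is a plain TSV input, keeping
the stage free of live ontology queries.

## PCHi-C integration

Probes are mapped into interaction *other-end* fragments only, by default
(the bait side is a flag), because the question is whether a distal element
loops to a promoter; gene-annotated CpGs remain eligible, since a CpG inside
one gene's body can still contact another gene's promoter. An interaction
with *k* bait genes yields *k* candidate links — genes are counted, not
interactions. No interaction-score threshold is applied by default:
CHiCAGO-style calls arrive pre-filtered.

Classification reuses the permutation correlation: enhancer when a
hypomethylated CpG anti-correlates with target expression, silencer when it
correlates positively (inverted for hypermethylated CpGs). Multiplicity
(unique = 1 distinct correlated target gene, dual = 2, complex ≥ 3) is
computed over classified links only. For the enhancer/silencer *gene*
split, a gene carrying links of both signs (possible across probes) is
assigned the class of its most significant link (lowest p_perm, ties by
|r| then probe id) so the two counts always partition the distinct gene
set.

CTCF overlap accepts either a motif-site track or a raw sequence scanned
for an IUPAC consensus (default `CCGCGNGGNGGCAG`) on both strands.

## UMI-4C contact comparison

Fragments are kept when the fragment-midpoint distance to the bait is
within [500 bp, 1 Mb], inclusive at both ends — the assay's reliable
quantification band; this also drops the self-ligation-dominated bait
fragment. Counts are normalized by each profile's total filtered UMIs (the
minimal normalization making two sequencing depths comparable), smoothed by
a centered moving average with truncated edge windows, and the domainogram
stores, per odd window scale *s* and fragment *i*, the difference of
*s*-window means (condition B − A); at scale 1 this is exactly the
normalized-count difference.

The formal test is a Pearson chi-square (df = 1, no continuity correction —
UMI totals here are in the thousands; Yates by flag) on [[A_in, A_out],
[B_in, B_out]] for a fragment window. Any zero margin raises a degenerate-
table error. When several windows are tested in one call, BH adjustment
across windows gives the adjusted p; a single window reports adjusted = raw.

For *locating* a differential contact before testing, the raw normalized
difference is misleading: near-bait fragments carry large counts, hence
large absolute Poisson noise. `per_fragment_z` is the variance-stabilized
two-proportion z score per fragment, and the pipeline targets its argmax.

## Synthetic-data generator

The generator emulates the statistical structure of the study, not its
genome: one synthetic chromosome tiled into equal restriction fragments
(4 kb default), gene promoters at every other fragment, probes at random
positions, baits at gene promoters.

- **Planted differential probes** follow a logistic trajectory between a
  high plateau drawn in [0.7, 0.95] and a low plateau in [0.05, 0.25];
  midpoint uniform in [12, 72] h, steepness set so both endpoints sit within
  ~1% of their plateaus (gradual, sigmoidal transitions rather than a step).
  Plateau pairs are drawn conditioned on a gap ≥ 0.72, so the planted
  endpoint effect clears the 0.66 filter under the default noise
  (sd 0.03, SE of Δβ ≈ 0.025 at 3 replicates); without the conditioning
  nearly half the planted probes would sit below their own detection
  threshold and "planted truth" would be ill-defined as a recovery target.
- **Null probes** hold a constant expected beta drawn U[0.15, 0.85], ≥ 5 sd
  from the [0, 1] bounds at the default noise so truncation effects are
  negligible and the null Δβ distribution is clean (sd · √(2/r) for r
  replicates).
- **Noise** is truncated-Gaussian by default (values stay in [0, 1] without
  a clipping point-mass); a Beta-distributed alternative with matched mean
  and variance is available (`noise_model="beta"`).
- **Controls**: negative-control samples are drawn around the 0 h
  expectation, positive-control samples around the 168 h expectation, with
  the same noise — emulating an untransdifferentiated line and terminal
  macrophages.
- **Expression** is affine in (1 − β) of the linked probe (slope U[2, 4] on
  a log2-like scale, baseline U[2, 8], Gaussian noise sd 0.1) with positive
  slope for activation/enhancer links and negative for repression/silencer;
  unlinked genes are flat plus noise.
- **Planted regulatory structure** (defaults): 100 hypo + 1 hyper probes
  (mirroring the heavily hypomethylation-skewed direction split of such
  conversions, at 1/20 scale); 20 activation + 5 repression local links
  (≈ 80/20); 12 enhancer + 8 silencer distal genes (≈ 60/40) over 17 distal
  probes of which 3 are dual (two target genes each); 4 distal probes inside
  CTCF motif sites. One probe per planted link, planted genes never reused
  as filler annotation, and one other-end fragment per planted probe — the
  truth stays unambiguous.
- **UMI-4C**: per-fragment counts are Poisson with mean depth ·
  d^(−decay) (depth 2000, decay 1.0, fragment-index distance d), and the
  planted loop fragment's mean is multiplied by the gain factor (5.0) in the
  boosted condition only. The assayed loop is planted at 12–480 kb from its
  bait — the distance range where a promoter–enhancer UMI-4C bait is
  actually informative (at ~1 Mb the expected signal is ~8 UMIs/fragment and
  no single-locus assay would be designed there); other distal elements
  span the full 12–960 kb band.
- **Replicates** default to 3 per timepoint (a study-design choice; the
  counts are configurable).

Everything derives from one `numpy` Generator seeded by `SimConfig.seed`;
two runs with the same config are bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: array probe chemistry (type I/II) and
normalization artifacts, SNP/cross-reactive probes, batch effects, realistic
genome structure (CpG islands, gene density, chromatin domains), biological
replicate correlation structure, and PCHi-C call noise. Recovery rates here
are upper bounds on what identical settings achieve on deposited data.

## Problem sizes in validation

The test-suite and acceptance experiments run at the generator defaults:
2000 probes × 27 samples per study; 20 seeded studies for recovery F1; one
2000-probe null study per calibration; 1000 simulated profile pairs for
contact-test calibration; 50 seeded studies for loop detection. These sizes
put Monte-Carlo error well inside the asserted bands (binomial SE ≈ 0.005
at n = 2000, ≈ 0.007 at 1000 simulations).

## Known limitations

- The exact permutation test is only exact for the per-timepoint *means*;
  replicate-level variation within timepoints is averaged away before
  correlation.
- Welch's endpoint test ignores the intermediate timepoints; the F-test
  option uses them but assumes equal within-group variance.
- The enhancer/silencer call is correlational; no causal claim is made, and
  a confounded gene (e.g. driven by a second locus) will be classified by
  whatever correlation it shows.
- The chi-square contact test conditions on total UMIs and ignores
  overdispersion beyond Poisson; with strongly overdispersed real UMI-4C
  data its p-values are anti-conservative.
- `write_bedgraph` emits 6-significant-digit values; round-trips of
  smoothed profiles are lossy at that precision (raw counts round-trip
  exactly).
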