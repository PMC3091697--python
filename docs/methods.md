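# Methods

`gillzinc` re-implements, as a tested pipeline, the computational analysis of
a two-channel microarray time course of the zebrafish gill under zinc
depletion: normalization and filtering of sample-vs-common-reference arrays,
per-time-point differential-expression calling, temporal regulation
summaries, annotation-term enrichment, promoter binding-site frequency
testing against a non-regulated control cohort, direct-interaction-network
assembly, and the closed-form physiology (tracer influx, standard-curve
qPCR).  Because the real arrays and the proprietary databases behind the
original annotation/motif/interaction steps are not redistributable, every
stage is driven and verified through a synthetic-data generator whose planted
ground truth makes recovery checkable by enumeration.

## Preprocessing

Each hybridisation compares one gill sample (Cy5) against a common reference
(Cy3).  Spot intensities enter as the MA transform M = log2(R/G),
A = (log2 R + log2 G)/2; non-positive or missing intensities become missing
values rather than errors.  Dye-incorporation bias appears as a smooth trend
of M on A and is removed per array by subtracting a lowess fit of M on A
(span 0.3, 3 robustness iterations; `statsmodels` lowess).  The span and
iteration count are package defaults — typical values for MA-trend removal —
exposed as parameters.  Normalization is global per array, not
print-tip-group-wise, and never changes the missingness pattern (a spot with
missing A cannot be corrected and stays missing).  An optional
`--per-gene-median-center` style re-centering is deliberately *not* applied
by default.

Two filters follow: spots failing the scanner's per-spot confidence call are
set missing, and a reporter enters the depleted-vs-control comparison at a
time point only when both groups retain at least 3 non-missing replicates
there.  Filtering is per comparison — a reporter missing in one group at one
day is dropped only for that day — and idempotent.

## Differential expression

At each of the five sampling times (0.3, 1, 4, 7, 14 days) each retained
reporter is tested with a two-sample t-test of depleted vs time-matched
control.  Welch's unequal-variance form with Welch–Satterthwaite degrees of
freedom is the default (the equal-variance Student form is available via
`pooled=True`) because the variance homogeneity of the original software's
test is unknowable and Welch is the robust modern default.  Degenerate
inputs follow a stated convention: both groups constant with equal means
gives p = 1, with unequal means p = 0 — which makes the noise-free limit of
the simulator exactly recoverable.

P-values are Benjamini–Hochberg adjusted *within each time point* across the
reporters tested there, since calling is defined between two groups at each
time point.  Fold change uses the signed two-colour convention: with
r = 2^(mean depleted − mean control), FC = +r for r ≥ 1 and −1/r otherwise,
so ±1.8 is a symmetric threshold.  A reporter is called regulated when
|FC| > 1.8 AND q < 0.1, both strict inequalities.  The temporal summary
counts up/down calls per day, the percentage of all called (reporter, day)
events in each direction, and the direction-persistent genes (same nonzero
direction, called at every sampled day).  Reporters are the test unit;
`collapse_to_genes` keeps the most significant reporter per gene for
reporting.

## Term enrichment

Enrichment of a called list against a background population uses the
one-sided hypergeometric upper tail per term, with the conservative EASE
variant (overlap decremented by one before the tail; an overlap of one is
never significant) as the default mode and plain Fisher as the alternative,
plus BH adjustment across the terms tested.  Terms with zero overlap are
excluded from both the output and the multiple-testing family.  The term
database is a user-supplied GMT-like table and the background is an explicit
input — by convention the reporters passing the replicate filter.  Numerical
reproduction of enrichment probabilities from any particular annotation
database snapshot is out of scope; only the statistic is implemented.

## Promoter TFBS analysis

Promoters are the 2000 bp upstream of the *translation* start: a plus-strand
gene with start s maps to genomic bases [s−2000, s−1]; a minus-strand gene to
the reverse complement of [s+1, s+2000]; windows truncate at contig edges
with a flag, and per-gene coordinate problems are recorded, not raised.
Motifs are IUPAC consensus strings scanned for exact compatibility with
overlapping matches counted on both strands by default; an N in the subject
matches nothing, including pattern N.  Minus-strand positions are reported
1-based on the reverse-complemented promoter.  The tested quantity is
presence (≥ 1 site per gene), not site counts, because the comparison is the
percentage of genes carrying the site.  Presence in the regulated list is
compared with presence in a seeded uniform sample of 198 never-regulated
genes using the pooled two-proportion z-test, two-sided, without continuity
correction; a degenerate pooled proportion (0 or 1) yields z = 0, p = 1.
z² equals the Pearson chi-square of the 2×2 table by construction, which the
tests assert to 1e-10.  Curated motif collections are proprietary, so the
package ships only clearly-labelled synthetic fixture motifs; production
use requires a user motif file.

## Interaction network

The direct-interaction network is the induced subgraph of a user-supplied
curated edge table on the regulated genes plus declared seed nodes (the zinc
ion and Mtf1 by default): an edge survives iff both endpoints are members.
Duplicate (source, target, type) rows collapse with a count; malformed rows
are skipped with a count; members touching no edge stay as flagged isolated
nodes.  Hubs are ranked by degree counted as *unique neighbours*, collapsing
edge types and directions, with ties broken by node id.  Reproducing any
particular proprietary database's node/edge content is out of scope.

## Physiology

Unidirectional zinc influx is J_in = cpm/(SA·bw·t) in pmol g⁻¹ h⁻¹, with
SA = [tracer]/[total Zn] in cpm pmol⁻¹, bw in g and t in h.  qPCR copies come
from inverting a per-gene standard curve Ct = slope·log10(copies) + intercept
(plain least squares; amplification efficiency E = 10^(−1/slope) − 1 is
reported) and are normalised by division with the 18s rRNA reference copies.
Group comparisons use the two-tailed unpaired Student t at α = 0.05.

## The synthetic-data generator

The generator's default configuration is the study design itself: 16,000
reporters; depleted vs control at 0.3/1/4/7/14 days; five replicates per
cell with one Day-4 control replicate dropped; 3% of reporters carrying a
nonzero effect at one or more time points.  Each spot's measurement is

    M = beta_g + effect(g, t)·[depleted] + b(A) + eps,  eps ~ N(0, 0.4)

with reporter baseline beta_g ~ N(0, 0.3), spot intensity A ~ N(10, 1.7)
clipped to [6, 16] (≈ three decades of intensity), and dye bias b a cubic in
(A−11)/5 with coefficients (0.1, −0.4, 0.15, 0.3), giving a visible but
removable |b| ≤ ~0.35 trend.  Planted effects have constant magnitude 1.5
log2 units (so the noise-free limit recovers the planted set exactly at any
FC threshold below 2^1.5) with random sign: 50/50 up/down before Day 4 and
75% down from Day 4 on, matching the reported dominance of down-regulation
at later times.  Activation probabilities per time point
(0.12, 0.18, 0.32, 0.42, 0.07) reproduce the rise-to-Day-7-then-subside
shape of the regulated-gene counts.  One designated reporter is persistently
down-regulated at 3.0 log2 units (8-fold) — the strong metallothionein-like
response.  2% of spots are flagged low-confidence.  All randomness flows
from a single seed through named child streams, so identical configurations
are byte-identical.

Companion generators plant motif sites at recorded positions into random
promoters of given GC content, annotation terms with exactly reproduced
list/term overlaps, and random typed edge tables.  What the generator does
*not* emulate: probe-sequence effects, print-tip or batch covariates,
spatially correlated spot artifacts, heavy-tailed noise, and correlated
biological pathway dynamics.  Passing recovery tests therefore demonstrates
the correctness of the statistics chain on its stated model, not performance
on real arrays.

## Verification design and problem sizes

- Exact statistics are tested against independent oracles: BH against a
  hand-coded step-up on all permutations of five p-values; hypergeometric
  tails against exhaustive enumeration of every table with N ≤ 25 (both
  modes); the IUPAC scanner against a naive expand-and-slide oracle on 1,000
  random (sequence ≤ 200 bp, motif ≤ 10 bp) pairs, both strands; z² against
  the Pearson chi-square.
- FDR control is checked on 200 seeded null replicates of a 2,000-reporter
  5v5 comparison: the mean false-discovery proportion must stay within
  three Monte-Carlo standard errors of 0.1.
- Power is checked on a dedicated recovery benchmark — 2,000 reporters, 5%
  planted in a single 5v5 comparison at |log2 FC| = 1.5, noise SD 0.4 —
  sized by power analysis so that BH leaves per-event sensitivity ≈ 0.9;
  planted directions must be recovered perfectly among true positives.  At
  the *study's* sparsity (≈ 1% signals per time point among 16,000
  reporters) the same effect size yields per-event sensitivity of only
  ~0.35, and the persistent 8-fold reporter can still miss a day when the
  Day-4 dropout leaves three control replicates and an outlier draw — an
  instructive echo of why single-direction persistence was so rare in the
  original data.  The acceptance script reports these measured values
  honestly rather than asserting them.
- Motif-comparison calibration uses 200 seeded promoter-set replicates per
  condition (80 vs 198 genes, 2000 bp): planted presence 0.5 vs 0.05 must be
  flagged in ≥ 95% of replicates, equal presence in ≤ 7.5%.
- Trend removal is checked on a 5,000-spot array with the default cubic bias
  and small (SD 0.1) noise so the decile-median estimator's own noise does
  not mask the property: all per-A-decile medians of normalized M must be
  below 0.02 in absolute value.

## Known limitations

The lowess span is fixed per run, not selected by cross-validation; the
t-test assumes within-group normality (no empirical-Bayes moderation);
enrichment ignores ontology structure; the scanner does exact IUPAC matching
only (no position-weight-matrix scoring); network assembly trusts the curated
edge table's identifiers; and cross-species ortholog mapping, which the
original analysis used to widen annotation coverage, is entirely out of
scope.
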