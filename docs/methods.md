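# Methods

This note documents the models, numerical choices and limitations of the
`cnge` pipeline in the order the stages run.

## Copy-number estimation

Copy numbers are ratios: marker intensity divided by the per-marker median
of a non-cancer reference panel (90 samples by default), times two. The
scale is linear and centered at 2 ("equal to the reference median"); no
log transform is applied anywhere downstream unless the log mode is
explicitly enabled. Markers with a non-positive reference median cannot be
centered and are excluded with a logged count. The estimator is
scale-equivariant per marker: rescaling one marker's tumor intensities by
c rescales its CN by c.

## Circular binary segmentation

Within a segment of n ordered marker values, every circular arc (i, j] is
scored with the squared mean-shift statistic
V = (D_j − D_i)² / (l(n−l)), where D is the prefix sum of mean-centered
values and l the arc length — a monotone transform of the two-sample
t statistic under a global variance estimate, which a permutation test
renders scale-free. The best arc is accepted when its permutation p-value
falls below `alpha` (default 0.01); accepted splits recurse until nothing
is significant. Arcs and their complements must both contain at least
`min_width` markers (default 2). No split-undo/pruning pass runs after
segmentation; this is a deliberate simplification relative to full CBS
implementations and can occasionally leave an extra boundary on drifting
signals.

Permutation testing is made affordable at genome scale by two devices:

* **Sequential stopping.** The split decision is taken at a budget of
  M = min(`n_perm`, `n_perm_cap`) permutations (defaults 10,000 and 199):
  the split is accepted iff the Monte-Carlo p-value (1+k)/(1+M) would be
  below alpha, and permutation stops as soon as the exceedance count k
  makes that impossible. The decision is identical to running all M
  permutations; only the reported p-value is coarser (resolution
  1/(M+1) = 0.005 at the defaults, which must stay below alpha).
* **A dyadic prefix-sum bound.** For each permutation an O(n log n) bound
  on the maximum arc statistic is computed from block maxima/minima of the
  prefix sums at dyadic scales; when the bound cannot reach the observed
  maximum the O(n²) arc scan is skipped. For strong splits (focal
  amplicons) most permutations are certified this way.

Segmentation is per chromosome (no arm boundaries) and per sample, with
one independent child RNG stream per sample derived from the root seed.

## Calls and tracks

Segment means are discretized with fixed thresholds on the 2-centered
scale: homozygous deletion < 0.75 ≤ loss < 1.7 ≤ normal ≤ 2.3 < gain ≤
4.0 < high gain. Boundary values resolve to the lower-severity category.
A hierarchical mixture calling model would adapt these cuts to each
cohort; fixed thresholds keep the stage deterministic and are sufficient
because calls feed only frequency tracks and plot coloring. Frequency
tracks report per-marker category fractions (summing to 1) plus combined
gain and combined loss. Quantile tracks (e.g. the 95% track that reveals
aberrations carried by small patient fractions) use the
linear-interpolation quantile definition, so five samples [2,2,2,2,6]
give 5.2 at q = 0.95.

## Probe-set integration

A probe set's position is floor((min_start + max_stop)/2) from its
annotation; probe sets with missing, ambiguous (multi-chromosome) or
Y-chromosome localization are removed with per-reason counts. Coordinates
are 1-based closed intervals. Each retained probe set is matched per
sample to the segment covering its position; a boundary tie resolves to
the segment with the smaller start, and a position in a gap between
segments takes the nearest segment (ties to the downstream one), with
distance logged and an optional cap. Expression values pass through
untouched — only rows are subset. Moving expression tracks (median, 5%
and 95% quantiles; window of 301 probe sets) are computed per chromosome
with symmetric truncation at the ends; windows never span chromosome
boundaries because adjacency across a centromere or chromosome break is
not biologically meaningful.

## ECCC and significance

The externally centered correlation coefficient uses Δx = CN − 2 (the CN
scale's own center — the reference median is 2 by construction, so
recomputing it would be redundant) and Δy = GE − cohort median per probe
set. Both are linear-scale; a log2 mode exists for sensitivity analysis
only. An undefined ECCC (zero deviation sum of squares) is flagged NaN,
not an error.

The equally-directed test scores each sample
d_i = sign(Δx_i Δy_i) · min(|Δx_i|, |Δy_i|) and applies a one-sided
Wilcoxon signed-rank test for positive location on the nonzero scores:
exact null distribution up to 25 nonzero scores, normal approximation with
continuity correction above. Zero scores are dropped (standard
convention). CN deviations within `cn_zero_tolerance` of the center
(default 0.05) count as zero: a segment mean that close to 2 reflects
averaging noise, not an aberration, and letting hundreds of such
near-zero, random-sign scores enter the rank sum would dilute the signal
carried by the few genuine carriers. The tolerance sits far below the
loss/gain call thresholds (1.7 / 2.3) and is configurable, including to 0.

Multiple testing is Benjamini–Hochberg across all probe sets in one
family per analysis. Flags: high correlation = ECCC > 0.7 and FDR < 0.05;
moderate = ECCC > 0.5. Loss candidates (median CN < 1.9 and 25% quantile
< 1.5) are excluded from gain-side analyses and reported separately. The
permutation null shuffles the pairing of samples between the expression
and CN matrices and recomputes all ECCCs; the cohort-median GE centers are
invariant under that shuffle.

Quantile-class analyses stratify probe sets into seven equal-frequency
classes on median GE or median CN (ties broken by stable probe-set order)
and compare adjacent classes by two-sided rank-sum tests with BH-FDR over
the six comparisons. Gene-set comparisons report an unadjusted rank-sum p
and a covariate-adjusted linear model ECCC ~ in_set + CN 95th percentile +
GE 95th percentile; the adjusted reading treats "stratified for CN and GE
as continuous variables" as covariate adjustment, the natural regression
interpretation.

## Hotspots

Candidate windows of a fixed width are anchored at the positions of highly
correlating genes (a gene is highly correlating if any of its probe sets
is; its position is the median of its probe-set positions). Counts change
only at gene positions, so anchored windows find every region a continuous
moving window would: sliding a qualifying window right until its left edge
touches its leftmost member keeps all members. Windows with at least
`min_genes` (default 10) distinct flagged genes qualify; overlapping or
adjacent qualifying windows of one width merge into maximal regions whose
boundaries are clipped to the outermost member genes, making them
data-determined rather than width-determined. Gene counts are the unit by
default; flagged probe-set counts are reported alongside. No significance
model is attached to the counts — the threshold is the definition.

## Survival and meta-analysis

Overall survival is months from diagnosis to death; the two-year
dichotomization labels deaths within 24 months "short", anyone observed
beyond 24 months "long", and excludes patients censored before 24 months
(class unknown; count logged). AUC uses the rank-sum identity with ties
counted half, short survival as the positive class.

Cox models use lifelines (Efron tie handling, Wald p). Expression is
z-scored within each cohort before fitting so log hazard ratios are per
standard deviation and poolable across cohorts of different dynamic range
(configurable off). Multivariate models adjust for age, stage and
histology by default — histology stands in for performance status, which
the synthetic generator does not carry — with dummy coding, row-wise
deletion of incomplete covariates, and stepwise removal of collinear
covariates on convergence failure.

Kaplan–Meier dichotomization supports a prespecified percentile cutoff
(default 75%) and an optimized cutoff that scans all cutpoints leaving at
least 10% of samples per arm and reports the minimum log-rank p. The
optimized p is exploratory and labeled unadjusted; by construction it is
never larger than any single-cutoff p on the same data.

Duplicate patients across (or within) cohorts are pairs with expression
correlation ≥ 0.999; removal keeps the copy in the earlier cohort of the
configured order. Meta-analysis pools per-study log hazard ratios with
DerSimonian–Laird: fixed-effect weights 1/se², heterogeneity Q, τ²
truncated at 0, random-effects weights 1/(se² + τ²), normal-theory p and
95% CI, BH-FDR across probe sets, per-study rows exported as forest-plot
data. The enrichment test is a one-sided Fisher exact (upper
hypergeometric tail) on the 2×2 of prognostic × highly-correlating flags.

## Synthetic cohorts

The generator emulates the structure that makes the integration problem
interesting, at desk scale: 190 tumors in three histology groups
(defaults 0.55/0.33/0.12), 4 chromosomes × 50 Mbp with 5,000 evenly
spaced markers and 2,000 probe sets (roughly every fourth gene carries
two probe sets); per-marker baseline intensities lognormal around 1,000;
multiplicative lognormal marker noise (sd 0.1), which keeps intensities
positive. Four focal 5-Mbp amplicons (target CN 6) are carried by 5, 8,
12 and 15% of samples, plus one broad loss region (CN 1.3 in 60% of
samples) emulating the common chromosome-arm losses; the carrier counts
are round(fraction × n). Dosage genes — genes inside amplicon loci, up to
10% of probe sets — get expression GE = α + β(CN − 2) + ε with α ~
U(3, 10), β ~ U(0.8, 1.5) and ε ~ N(0, 0.4²), floored at 0.05; all other
genes have β = 0. The linear coupling on linear scales mirrors the
decision to correlate non-log values; a multiplicative variant sits
behind the `coupling` flag. The generative relation is a stand-in for
testing recovery, not a claim about transcriptional biology.

Survival is proportional hazards on standardized expression of a
prognostic subset (1% of probe sets, |log HR| = 0.2 per SD, random
signs), exponential event times with baseline median 30 months, and
independent uniform censoring whose upper limit is calibrated by
bisection to achieve the configured censoring fraction (default 0.5).
Meta-analysis cohorts (10 by default, 80–250 samples) share annotation
and generative coefficients but draw fresh carriers, noise and survival;
near-duplicates are planted by copying one sample's expression into the
next cohort with relative noise of order 1e-5 (correlation ≥ 0.999).
All stages draw from named substreams of a single root seed, so any stage
can be regenerated independently and full runs are bit-identical.

What the generator does not emulate: probe-level hybridization chemistry,
normalization artifacts, tumor purity and subclonality, LD structure
among markers, correlated expression programs, and non-genetic expression
regulation. Passing tests therefore demonstrate that the statistics
recover the planted signal under clean conditions, not that the pipeline
is robust to every artifact of real arrays.

## Problem sizes and numerical choices

Defaults were chosen so a full synthetic run (generation, segmentation of
190 × 4 chromosomes, ECCC for 2,000 probe sets, hotspots, duplicate
detection over ~1,600 meta-cohort samples, meta-analysis of the flagged
probe sets) completes in roughly two minutes on one CPU, and the recovery
simulations (200 segmentation replicates, 20 cohort seeds, 200
meta-analysis replicates) in minutes. The permutation-resolution cap
(199) and the CBS early-stopping rule are the only places where speed
trades against p-value granularity, never against the accept/reject
decision at alpha = 0.01. Ties: call boundaries go to lower severity;
segment-match boundary ties to the smaller start; gap ties downstream;
quantile-class ties to stable probe-set order. Degenerate inputs produce
flags (NaN ECCC, non-estimable Cox/meta results, p = 1 enrichment on
degenerate margins) rather than exceptions wherever an analysis can
continue.

## Known limitations

* The CBS variant has no undo/pruning and its mean-shift statistic uses a
  global variance; heteroscedastic noise along the genome can shift
  boundaries.
* Fixed call thresholds do not adapt to cohort-specific noise; downstream
  call-dependent results are relative to the documented cuts.
* The equally-directed score's zero tolerance is a measurement-precision
  judgment; cohorts with pervasive low-amplitude aberrations should lower
  it.
* The optimized-cutoff log-rank p is a minimum over cutpoints and must
  not be read as a calibrated significance level.
* DerSimonian–Laird τ² is noisy for few studies; with two or three
  cohorts the pooled CI can be optimistic.
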