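# Methods

## Coordinates and transforms

All calling happens per probe set on strand-summarized allele
intensities (arithmetic mean over retained strands, linear scale).
A sample is the point (c, m) with contrast c = (A − B)/(A + B) and
average m = log2((A + B)/2).  The CCS variant of the contrast,
asinh(k·c)/asinh(k) with default k = 4, is used for calling: it fixes
−1, 0 and +1, is strictly increasing in c, and — because its slope
exceeds 1 near 0 and falls below 1 near ±1 — spreads the heterozygous
cluster while tightening the homozygous ones, which balances the
three-component mixture fit.  k is a free constant; 4 puts the
homozygous clusters of the default geometry near ±0.8 without
saturating them.

## Genotype calling

**Mixture stage.**  One-, two- and three-component 1D Gaussian
mixtures are fitted to the contrasts by EM (tolerance 1e−6 on the
log-likelihood, at most 200 iterations, variance floor 1e−6; the
log-likelihood trace is recorded and asserted non-decreasing).
Initialization is deterministic: component centers at the observed
minimum / AB-center prior (global default 0) / maximum for k = 3, at
the extremes for k = 2, at the mean for k = 1.  The component count is
the k ∈ {2, 3} maximizing the silhouette of the hard posterior
assignment; if that best silhouette is below 0.6 (an invented
threshold — silhouette is undefined at k = 1) a single component is
used.  Components map to genotypes by contrast order (high = AA,
low = BB, middle = AB); for k ≤ 2 a center inside the ±0.25 "het band"
is read as AB, ties resolving the upper component to AA.

**Initial assignment.**  Per component, the confident samples are
those whose largest other-component posterior is below 0.5; the
component's threshold is the median of the confident samples'
posteriors, and samples at or above their best component's threshold
are assigned.  The comparison is ≥ rather than >: in well-separated
clusters posteriors saturate to exactly 1.0 and the whole cluster sits
at its own median.

**Friends of friends.**  Unassigned samples join, one accretion at a
time, the group of the nearest assigned sample in (contrast, average)
space, each dimension standardized by its across-sample SD.  Ties
break to the lowest sample index.  The procedure is the single-linkage
complement of the mixture: it respects gaps the variance-driven
posteriors cannot see.

**Confidence.**  Each group's 2D center and scatter are one-step Tukey
biweight estimates around the per-dimension median with MAD scaling
(tuning constant c = 5, floor eps = 1e−4); the scale uses the
midvariance/midcovariance normalization, which is consistent for
Gaussian data.  Confidence is exp(−d²/2), the χ²₂ upper tail of the
squared Mahalanobis distance; calls below 0.005 become N (d ≈ 3.26).
Two numerical safeguards, both needed on realistic panels:

* after the first confidence pass flags gross outliers as N, the group
  statistics are refitted without them and the refined statistics give
  the final confidence and the VINO scores — a one-step biweight only
  *downweights* contamination near its rejection boundary, and a
  20% cluster of low-intensity carriers otherwise inflates the
  average-intensity scale about 1.6-fold;
* each group's per-dimension variance is floored at a quarter of the
  size-weighted pooled within-group variance, because the biweight
  scale of a small group (5–10 members) occasionally collapses and
  would declare ordinary members extreme.

Groups with fewer than 3 members use their plain mean with a diagonal
scatter from the across-sample variance.

## VINO calling

The VINO score is (1 − confidence) × Φ((μ_avg − m)/σ_avg), evaluated
against the sample's pre-no-call genotype group: the second factor is
one-sided in the low-intensity direction, since only an intensity
*deficit* is evidence of an off-target variant.  A sample above its
group's mean intensity can never score above 0.5.  Scores above 0.9999
seed a V group; if any seed fires at a probe, every sample with
average intensity below the across-sample mean is unassigned and the
friends-of-friends accretion re-run with V as an assignable group
(seed coordinates serve as the V anchors).  Samples accreting to V are
called V; all other re-evaluated samples keep their original call and
confidence, so vinotypes differ from genotypes only by V
substitutions.  Score monotonicity in the intensity deficit holds for
samples at or below their group mean (below it, the two factors move
in opposite directions by vanishing amounts); the property tests are
stated on that domain.

A closed-form consequence of the stringent threshold: since the score
is capped by Φ(z), no event with deficit below Φ⁻¹(0.9999) ≈ 3.7
within-cluster SDs is detectable from a single sample.  Detection of
weaker events relies entirely on the cluster-expansion pass.  This is
the intended conservatism — edge OTVs and 1–1.5 kb fragment events
are left as ordinary calls.

## Normalization

Within-array correction fits cubic B-splines (basis dimension 5 beyond
the intercept, internal knots at covariate quantiles) of log2
intensity against probe C+G content, then sequentially against the
NspI and StyI fragment lengths on the residuals; the centered fitted
effects are subtracted so each array's mean log2 intensity is
preserved exactly, and values return to the linear scale.  Quantile
normalization maps each array independently onto a reference
distribution (element-wise mean of sorted per-array vectors); tied
inputs receive the mean of the reference values at their shared ranks.
Both steps are optional — quantile normalization assumes a shared
intensity distribution and should be skipped for taxonomically diverse
panels — and the default order is covariate correction first.

## Probe and strand QC

Probes are flagged when more than 50% of non-N calls on an inbred
reference panel are heterozygous (strict >), when only one call class
appears, or when no calls exist; flags are advisory.  For strand
filtering, each strand gets a preliminary mixture fit on its own
contrasts; the strand with the better self-clustering silhouette
provides reference labels, and the other strand's contrasts are
silhouette-scored against those labels.  A strand is dropped iff its
silhouette is below 0.7 *and* the other strand's exceeds it by more
than 0.2.  Scoring the weaker strand against reference labels (rather
than its own) matters: any fitted interval partition of 1D data has a
silhouette floor around 0.6, so a pure-noise strand evaluated on its
own labels would rarely fall below the 0.7 cutoff.

## Event classification

Coordinates are 0-based half-open.  A variant at offset o of an
L-mer probe is an edge OTV iff o < 3 or o ≥ L − 3, else central (for
21–25-mers this is exactly the central 15–19 bp).  Fragment classes
use the minimum available NspI/StyI fragment: ≤ 1 kb optimal, (1 kb,
1.5 kb] and > 1.5 kb form the two RFLP bins (upper boundary of the
first bin closed at 1500 bp); both fragments absent is "inaccessible".
A recognition site overlapping the probe interval is "cut in probe".
Distinct co-occurring classes collapse to "multiple"; an event present
on every retained strand sets the both-strands flag.  The intensity
summary bins probes by OTV distance-to-edge (0–12, plus "none") and,
for no-OTV probes, by 250-bp minimum-fragment bins, reporting the mean
best-hybridizing-allele intensity and V/N rate per bin.

## Concordance

All statistics are exact rational functions of cross-tab counts:
pairwise agreement is the diagonal fraction of the {AA, AB, BB}²
submatrix; the V-row breakdown divides each cell by the V margin; the
parent→F1 prediction maps two homozygous parents to their obligate F1
genotype and everything else to a compound category label; the F1
summary reports shared-homozygous concordance, its discordant split
(N-or-V / wrong het / wrong homozygote) and predicted-het concordance;
the calls-vs-sequence summary reports het call rate, homozygous
concordance, and the V total/rate/homozygous-truth fraction.
Percentages print at two decimals, round-half-even.  The bundled
worked-example tables under `src/vinotyper/data/` carry the published
cross-tabulations these statistics are verified against.

## The simulator

The generator works in the caller's own coordinates.  Each genotype
has a configured (MA contrast, log2 average) center — defaults
AA (0.65, 11.0), AB (0.0, 11.2), BB (−0.65, 11.0), within-cluster SDs
(0.05, 0.25), chosen to visually match real contrast plots, not
asserted as measured truth — and a per-strand draw is inverted
analytically to linear intensities A = (1+c)·2^m, B = (1−c)·2^m.
Each allele signal is split into specific hybridization plus a
non-specific background floor (default 20% of the per-allele mean);
OTV and fragment events multiply only the specific part, so strong
events also compress the contrast toward 0 as the background takes
over — the mechanism that creates the low-intensity, low-contrast
VINO cluster.  The knockdown factor is solved so a homozygous
carrier's average-intensity deficit is exactly e within-cluster SDs,
saturating at the background floor (−log2(0.2) ≈ 2.3 log2 units).

Event-class effects e (in within-cluster SDs of the average) are
implementer-chosen, as no quantitative noise model exists for them:
central OTV and cut-in-probe 5 (= 1.25 log2 units, ~2.4-fold signal
loss — the weak end of reported central-mismatch effects, and
comfortably above the 3.7-SD single-sample detectability bound), RFLP
> 1.5 kb 3, RFLP 1–1.5 kb 1.2, edge OTV 0.5 (the latter two
intentionally below detectability).  A heterozygous carrier of a
within-probe OTV has the variant ride the B haplotype: with an AB
genotype the B allele's only specific template is disrupted, so the B
signal is knocked down hard (factor 2^(−4·e·σ_m)) and the sample
flips to the AA side of the contrast — the cryptic-VINO geometry.
Heterozygous carriers with homozygous target genotypes, and fragment
events in heterozygosity, apply half-strength knockdown to both
alleles.  Smooth C+G and log-fragment-length polynomial biases and a
per-array log-normal scale factor (SD 0.1 log2 units) multiply
everything; probe lengths are uniform 21–25 nt, and 90% of probe sets
have their minimum fragment inside the 50 bp–1 kb optimal window.

What the simulator does *not* emulate: batch and plate structure,
probe-sequence-specific variance heterogeneity, saturation at the high
end, linked multi-variant haplotype patterns that produce four or more
clusters, or pedigrees beyond hand-built parent/F1 truth sets.
Passing tests therefore show the algorithm recovers the assumed
cluster geometry, not that real-array error rates are matched.

## Test and verification sizes

Recovery checks run at 200 probes × 96 samples (a panel size at which
every genotype group is usually populated); fuzz comparisons against
brute-force oracles use 100+ randomized instances of ≤ 25 points.
Genotype accuracy is reported as concordance of non-N calls with the
no-call rate alongside — the convention of every published comparison
table — and the observed no-call rate at the default 0.005 confidence
threshold is ~1.2%, matching the N margins of those tables.  VINO
sensitivity is measured on an inbred panel with central-OTV events
(the configuration in which hom carriers exist by definition); under
the default mixed-event panel with 25% heterozygous-capable samples it
drops to ~93–95%, because a heterozygous group whose membership is
half absorbed carriers defeats a one-step robust estimator — a known
limitation shared with the underlying approach.

## Known limitations

* Four-or-more-cluster probes (multiple linked variants) are forced
  into at most three genotype components plus one V cluster.
* Cryptic VINOs are by construction invisible to the per-probe score;
  they surface only through parent/F1 discordance reports.
* The second friends-of-friends pass is single-linkage and can chain a
  borderline carrier back into its genotype group across a small gap.
* Quantile normalization with heavy ties redistributes mass; tied
  inputs share averaged reference values, which can change the
  multiset of outputs relative to the reference.
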