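# Methods

This note records the models, conventions and numerical choices behind the
package, in the order the pipeline runs them.

## Coordinate and merge conventions

All intervals are 0-based half-open (BED). The consensus map is the
interval union of all per-sample peak calls; book-ended (touching)
intervals merge, matching the default behaviour of the standard BED merge
utilities (verified against pyranges with `slack=0` in the tests). Every
input peak therefore lies in exactly one consensus region, and region IDs
are `chrom_start_end`.

Saturation curves add samples in random order and count unique merged
regions after each addition; the band is the 2.5/97.5 percentile across
iterations (the method behind a "95% confidence interval" on such curves
is not standardized; the percentile band is recorded in the output).
Support-class boundaries — constitutive > 0.95, rare < 0.05, shared in
between — are conventions and are emitted alongside the numbers.

Nearest-TSS distance uses the region midpoint (0 if a TSS falls inside
the region), with ties broken to the lexicographically smallest gene ID.
Midpoint-versus-edge is a genuine free choice; midpoint is symmetric and
is recorded in the annotation output.

## Accessibility matrix

Raw entries count fragments overlapping a region by ≥ 1 bp; a fragment
spanning several regions counts once in each (recorded in QC metadata).
Quantile normalization follows the classic microarray algorithm: each
column's sorted values are replaced by the row-wise mean of all
column-sorted values, and tied input values receive the mean of the
reference values at their rank positions. With ties this deliberately
perturbs the per-column multiset (exactly as R's `normalize.quantiles`
does); on tie-free data all columns share one multiset and the transform
is idempotent.

Variability metrics use the n−1 standard deviation. Gene-level summaries
take the closest region within 1,000 bp of the TSS as the promoter value
and the mean of regions farther than 2,500 bp as the distal value;
regions between 1,000 and 2,500 bp belong to neither summary — the gap
between the two rules is acknowledged rather than silently bridged.

Coverage is normalized to reads per total filtered reads × 10⁷. Corridor
percentiles (5/25/75/95) use linear interpolation between order
statistics; positions where some samples have zero coverage contribute
those zeros. Corridors are computed per base over requested loci rather
than genome-wide by default.

## Subtype analysis

IGHV germline homology strictly above 98% labels a sample unmutated;
at or below, mutated; missing, unknown (excluded). Differential
variability is a two-sided variance-ratio F test per region
(p = 2·min(P(F≥f), P(F≤f)), capped at 1), Bonferroni-corrected over the
regions actually tested (zero-variance-in-both-groups regions are skipped
and flagged); a region is significant if the adjusted p < 0.05 **and** its
overall mean exceeds 1, and is attributed to the group with the larger
variance.

Known limitation: the F test assumes normality, and on overdispersed
count data its extreme-tail p-values are anticonservative — on
negative-binomial null cohorts drawn from this package's own generator,
roughly half the cohorts show a Bonferroni false positive. The test suite
therefore calibrates the implementation on the test's own null model
(normal data at matched moments), where the family-wise error control
holds; variance calls on strongly non-normal data should be read with
this caveat.

Classification uses a random forest (default 500 trees, unlimited depth,
√p features per split — standard ensemble practice; the configuration is
user-settable and recorded in output metadata) under leave-one-out
cross-validation in which every sample sharing the test sample's patient
is also removed from training, eliminating repeated-patient leakage.

The out-of-fold score for each sample is the positive-class probability
centered on the training fold's positive-class prior and mapped affinely
back into [0, 1]. This matters at small cohort sizes: leaving a sample
(and its patient's other samples) out makes the training class balance
anti-correlated with the held-out label, and the raw forest probability
embeds that prior, which depresses shuffled-label null AUCs well below
the chance level 0.5 (measured ≈ 0.42 at 40 samples). Centering removes
exactly that composition component, restoring the null mean to 0.5
without touching within-fold ranks or the strong-signal behaviour. The
ROC is a threshold sweep over the out-of-fold scores; AUC is
the trapezoidal area (identical to the Mann–Whitney concordance
probability with ties counted ½, which the tests verify independently);
the reported operating point minimizes the Euclidean distance to
(FPR 0, TPR 1). The shuffled-label null permutes labels across samples
while keeping the patient structure for fold exclusion and reruns the
full cross-validation per permutation; because the null's mean AUC is
insensitive to ensemble size, the 100-permutation runs use a lighter
50-tree forest (an ~11-fold cost reduction) while observed-label runs
keep the 500-tree default.

Signature regions are those with fold-averaged Gini importance > 10⁻⁴
(observed-label folds only), directed by comparing subtype means on the
normalized layer. Note that at the desk-scale region count (2,000) the
mean importance is 5×10⁻⁴, so this absolute threshold is far less
selective than at a realistic map size (~10⁵ regions, mean ~10⁻⁵); planted
regions are nevertheless ranked far above background. Sample clustering
uses 1 − Pearson correlation over signature regions with average linkage,
cut to k clusters (default 4, configurable; the right k is data-dependent
and not derivable from first principles). PCA is a centered SVD of the
samples-by-regions normalized layer.

## Regulatory network inference

Footprint sites qualify with purity strictly > 0.7 and ≥ 1 bp overlap
with accessible chromatin; TFs are retained with ≥ 500 qualifying sites.
Sites in a gene body or within 2,500 bp upstream of the TSS
(strand-aware) are assigned to every such gene with full weight (no
splitting — flagged in metadata); intergenic sites go to the single gene
with the nearest TSS by site-midpoint distance, ties to the smallest gene
ID. Distance is midpoint-to-TSS for all classes, including body hits.

The interaction score is the sum over assigned sites of
`w(P, d) = 2(P − 0.5) · 10^(−d / 10⁶)`: the purity term vanishes at the
chance level 0.5 and reaches 1 for a perfectly confident site; the decay
constant of one decade per megabase keeps promoter-proximal sites near
full weight while suppressing megabase-distant assignments. This
functional form is this package's own choice of a purity-monotone,
distance-decaying, site-additive weight; both the purity offset and the
decay constant are configurable, and the form is recorded in all outputs.
Edges require score strictly > 1; nodes without edges are dropped.
Differential connectivity divides each node's (in+out) degree by its
network's total edge count and reports the log2 ratio for nodes present
in both networks (others are flagged by side); the measure is
antisymmetric and invariant to uniformly scaling a network's edge count.
A "more than 200 connections" display filter exists for reporting only
and never enters the statistics.

## Synthetic cohort generator

The generator is the package's study-condition bed: 40 samples from 25
patients (extras spread over random patients, so some patients contribute
several samples — the structure that makes patient-aware fold exclusion
matter), a 50-Mb two-chromosome genome, and 2,000 fixed-width (500 bp)
regions: 240 core (present in every sample, ≈ 12%), 1,160 shared-variable
(per-region presence fraction uniform on 0.1–0.9, ≈ 58%) and 15
sample-specific regions per sample (≈ 30%) — proportions chosen to echo
the constitutive/shared/rare architecture reported for real accessibility
cohorts.

Counts are negative binomial in the mean/dispersion parameterization
(var = μ + αμ², default α = 0.25) with per-region baseline means
lognormal around 30 (typical peak read counts at desk-scale depth; σ =
0.4). Fragments (100 bp) are placed uniformly inside their region, so the
quantification stage recovers the drawn counts exactly and column sums
equal fragment totals — a deliberate conservation property used by the
tests. Regions absent from a sample's peak set still emit background
counts (mean 1).

Planted structure, all recorded in ground truth:

- **Signature regions** (50, subset of the core): subtype means split
  ±e/2 in log2 around the baseline (default effect e = 1.5), directions
  alternating so both subtypes gain regions. Intermediate samples (an
  optional patient fraction) receive the arithmetic midpoint of the two
  subtype means and IGHV homology values straddling 98%.
- **Differential-variability regions** (50, core): the dispersion of one
  group is rescaled so the NB variance ratio equals the requested value
  (default 4) at exactly equal means — variance differences are not
  confounded with mean shifts.
- **Footprints**: 8 TFs with Beta(4, 1.5)-distributed purities mapped to
  (0.5, 1]. Four planted TFs place 550–700 sites inside their target
  gene's promoter-proximal anchor region (distance ≲ 500 bp, so each
  qualifying site contributes nearly its full purity weight and the pair
  scores far above the edge threshold); four decoy TFs scatter the same
  number of sites into accessible regions many megabases from the nearest
  TSS, where the distance decay drives their scores to ≈ 0. Planted edges
  are thus recoverable and decoys rejectable by construction.

One integer seed drives every stream; regeneration with the same spec is
byte-identical. What the generator does **not** emulate: fragment-length
and Tn5 insertion-site biases, GC effects, peak-boundary jitter between
samples (peaks coincide with the planted intervals), mitochondrial or
blacklist contamination, and realistic linkage between neighbouring
regions. Passing tests therefore demonstrate the statistical machinery —
normalization, calibration, fold construction, recovery of planted
effects — not robustness to those real-data artifacts.

## Problem sizes and known limitations

The default scales (2,000 regions, 40 samples, 100-iteration saturation,
100-permutation nulls) are the package's desk-scale defaults; every one
is a parameter. The F-test power caveat above is the main statistical
limitation: with 30 samples per group and Bonferroni control over ~2,000
regions, a true variance ratio of 4 is detected only ~23% of the time
(the two-sided critical value at df (29, 29) is ≈ 5.3); ratios near 8, or
substantially larger groups, are needed for reliable detection. The
classifier, by contrast, detects the default planted mean effect
essentially perfectly, and the shuffled-label null sits at 0.5 as it
must.
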