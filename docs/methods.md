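# Methods

## The norming model

Raw scores on a 40-item forced-choice odor identification test are
integers 0–40. Norms are empirical: within each of ten cells (2 sexes × 5
age bands: 60–64, 65–69, 70–74, 75–79, ≥80; half-open bins, so age 65.0
belongs to 65–69), a cell's score sample defines a raw-score → percentile
lookup table. No smoothing or regression-based (continuous) norming is
used — the published tables are empirical bins, and this package
reproduces exactly that construction.

### Quantile definition

All quantiles use the empirical-distribution-function rule with averaging:
for sorted scores x₍₁₎…x₍ₙ₎ and np = n·p, an integer np = j < n yields
(x₍ⱼ₎+x₍ⱼ₊₁₎)/2, np = n yields x₍ₙ₎, and a fractional np yields x₍⌈np⌉₎.
Equivalently, a score's percentile rank counts half of its ties (the
mid-rank percentile 100·(L + E/2)/n, which the engine exposes as an
independent oracle). Integer n·p is detected with a relative tolerance of
1e-8, far wider than the ~1e-11 floating error of n·(k/100) at realistic n
and far narrower than the spacing of true non-integers.

### Table construction

The grid is the integer percents p = 1…100. Because grid quantiles of an
integer sample are averages of two integer order statistics, each is an
integer or a half-integer; only integer quantiles are assigned to a score
(a half-integer falls between two scores). Then, per raw score s:

1. if one or more grid percents map to s, its value is the **median** of
   those percents — medians of even-sized percent runs end in .5, which is
   why published tables contain non-integer entries;
2. if none do and s lies strictly between two assigned scores, its value
   is the mean of the two bordering values **rounded up** to an integer;
3. below every assigned score the value is floored to 1;
4. above every assigned score the value is 100, rendered ">99.5";
5. any value above 99.5 is likewise rendered ">99.5" (99.5 itself prints
   as 99.5).

Choosing the 1…100 grid (including p = 100) reproduces the published
half-integer entries and the ">99.5" cap through the median rule alone,
with no extra rounding step; whether the original analysis included
p = 100 is not stated, so this convention is documented rather than
claimed as the authors' certain intent.

**Accuracy relative to the mid-rank oracle.** A score whose sample mass
spans at least two grid percents is assigned directly, and its entry lies
within 100/n + 1 of its mid-rank percentile. A rarer score (< ~1% mass)
catches no grid percent and takes the between-percentiles interpolation,
whose error is instead bounded by the spread of the neighbouring scores'
percentiles — it can exceed 100/n + 1 when a rare score sits between two
heavy neighbours. The tests assert the tight bound in the regime where it
is a theorem and the sandwich bound for realistic clustered samples.

## Threshold classification

The legacy categorical scheme is provided for context: normosmia at raw
≥ 34 (males) / ≥ 35 (females), total anosmia at raw ≤ 18 (both sexes),
hyposmia in between. Percentiles, not these thresholds, are the
recommended metric.

## Bridging analysis

Participants who took both test versions contribute a paired difference
(revised − original). Summaries report mean, sample SD (n−1), and
median/quartiles under the same averaging quantile rule; the IQR is
reported as the (q1–q3) pair. Records missing either score are excluded
pairwise with a logged count; no imputation.

**Wilcoxon signed-rank.** Zero differences are discarded before ranking
(the classical treatment; the count is reported — the original analysis's
zero policy is not stated). Absolute differences receive mid-ranks; W⁺ is
the rank sum of the positives. The exact two-sided p (2·min(CDF, SF),
both tails including the observed point mass, capped at 1) is computed by
dynamic programming over the doubled mid-ranks — identical to enumerating
all 2^m sign assignments at polynomial cost — for up to 300 nonzero
differences, which covers every cohort size in this package. Beyond that,
a normal approximation with tie-corrected variance and a 0.5 continuity
correction is used. Exactness in the far tail matters: for claims of the
form "p < 0.0001" the continuity-corrected normal approximation is
conservative by roughly a factor of two at n ≈ 90. With heavy ties at
very small m (≤ 12), the exact null has large lattice point masses that no
continuous approximation tracks within 0.05; agreement between the two
branches is therefore a property of untied samples.

**Wilcoxon rank-sum** (group and block-order comparisons of the
differences): exact by enumeration when the pooled size is ≤ 12 with no
ties, else the tie- and continuity-corrected normal approximation. Both
tests are two-sided throughout.

**Bland–Altman.** Per-pair (mean, difference) points; limits of agreement
are the mean difference ± 1.96 sample SD. The default scale is the raw
score (as in the published agreement figure); percentile-scale summaries
are produced when norm sets for *both* versions are supplied. Norms for
the original 1984 test are not packaged (published elsewhere); any
user-supplied norm set in the JSON schema works, and the analysis scripts
use a clearly-labelled synthetic stand-in.

## Synthetic cohorts

The generators exist so that every stage runs and is testable without any
data access; they emulate the published study conditions, not the full
data-generating process.

**Bridging cohort** (defaults = the published bridging study): per group,
original ~ round(clamp(Normal(μ, σ), 0, 40)); a latent difference ~
round(clamp(Normal(δ, τ), −40, 40)); revised = clamp(original +
difference, 0, 40). Healthy controls: n=89, μ/σ = 32.7/5.4, δ/τ =
1.7/2.6; Parkinson's group: n=48, 18.6/7.3, 2.5/4.5. Ages are normal
(67.2 ± 5.0 and 67.9 ± 8.1) clamped to [60, 89] so percentile lookups
against the 60+ norms are always defined; sex mix and block-order split
follow the published demographics (controls 60% female and 94%
original-first; patients 46% and 50%).

**Calibration.** The published group moments are *observed* moments of
ceiling-limited data. Clamping a Normal(32.7, 5.4) at 40 attenuates the
realized mean difference from 1.7 to ≈1.33, so the generators calibrate
their latent normal means — deterministically, from the exact discrete
probability mass function of a rounded clamped normal (and, for the
difference, the exact expectation of clamp(o+d, 0, 40) − o over the two
independent PMFs), inverted with a bracketed root-find — so the observed
means equal the targets. The targets thus mean what a study reports.

**Normative cohort** (defaults = the published per-cell summary rows,
e.g. females 60–64: n=4266, mean 35.2, SD 5.0): per subject, with
probability 1−π a rounded clamped normal draw (latent mean calibrated as
above, mixture-aware), with probability π a uniform integer from a low
tail. Defaults π = 0.05 over scores [2, 25], covering the
anosmic-to-moderate-hyposmic range an impaired subpopulation occupies.
Ages are uniform within the cell's band (≥80 mapped to [80, 95), one
decimal).

**What passing tests do and do not show.** The generator matches cell
sizes and means (and approximately the published left skew, via ceiling
plus low tail) but not the full published score distributions — their SDs,
minima and tie structure differ, and no covariate structure (smoking, REM
sleep behavior disorder, family history) is modelled. Tests passing on
synthetic cohorts validate the *algorithms* (construction, lookup, tests,
agreement) under realistic conditions; they do not re-derive the published
table values, which enter the package as packaged data, transcribed and
validated (monotone columns, cell Ns summing to 11,754 women + 5,218 men =
16,972).

## Numerical and design choices

- Score domain fixed to integers 0–40; all score inputs validated.
- Quantile-grid inversion uses an absolute tolerance of 1e-6 to classify a
  grid quantile as integer vs half-integer (the two cases are 0.5 apart).
- Median of an even-sized percent set: arithmetic mean of the two central
  values (standard median).
- Percentile cutoff score at level P: the largest raw score whose
  tabulated percentile is ≤ P, or none when no entry qualifies; the same
  rule on both sides of a norm-set comparison so differences are
  comparable.
- Degenerate inputs error loudly: empty samples, all-zero difference
  vectors, cohorts with no complete pairs, ages below 60 in norming
  contexts (with offending record ids).
- Seeds are required parameters of the generators; one seeded stream per
  generator call; identical seed gives byte-identical CSV output.
- Problem sizes in the test suite and analysis drivers (full-size
  normative cells of up to 4,266; 500-seed simulation sweeps at n=89; 100
  random samples up to n=2000 for oracle equivalence) were chosen so each
  stage completes in seconds while keeping sampling error far below the
  tolerances being asserted.

## Known limitations

- Norms cover ages 60+ only; no interpolation between age bands and no
  extrapolation below 60.
- The published left-skewed score distributions are approximated, not
  matched, by the truncated-discretized-normal-plus-tail generator.
- The rank-sum exact branch requires an untied pooled sample; tied small
  samples fall to the approximation.
- Percentile-scale bridging output depends on the norm sets supplied for
  each version; with the synthetic stand-in used in the analysis scripts
  those percentile numbers characterise the generator, not the real tests.
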