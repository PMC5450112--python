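# Methods

This note records the models implemented in `lincdiscover`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic generators do and do not emulate.

## Array model and simulation

A two-channel genotyping array reports per-marker intensities (X, Y) for
the two alleles.  The generator (`synthetic.simulate_cohort`) emulates a
paired-cohort experiment: one germline gDNA hybridization per subject and
one ds-cDNA hybridization per sample (normal and tumor of each pair),
plus technical replicates for designated samples.  Its components:

- **Genotypes.** Each marker's minor-allele frequency is drawn uniformly
  from `maf_range` (default 0.10–0.50) and subject genotypes follow
  Hardy–Weinberg sampling, Binomial(2, MAF) copies of the B allele.
- **gDNA clusters.** AA markers put the full `intensity_scale` (default
  1000 arbitrary fluorescence units) on X with a 2% background on Y; BB
  is the mirror image; AB splits the scale evenly.  These are idealized,
  well-separated clusters: the caller's accuracy on them is an upper
  bound for real arrays, where clusters overlap and compress near the
  poles.
- **cDNA intensities.** Total intensity per marker equals the expression
  level of the containing locus (right-skewed across loci: log-normal
  with σ = 0.5 around the intensity scale), split across channels by the
  genotype's allele balance (0.5/0.5 for AB; allelic imbalance is
  deliberately not modelled).  Tumor samples of planted "up" loci are
  multiplied by 2^`planted_log2fc` (default 2.0), "down" loci by the
  reciprocal.
- **Noise.** Multiplicative log-normal per channel with unit mean and a
  coefficient of variation `noise_cv` (default 0.15).  Array data are
  positive and right-skewed, which a multiplicative model captures with
  one parameter; the magnitude of real BeadChip noise is not publicly
  characterized, so the default is a plausible placeholder surfaced in
  the config rather than a calibrated value.  At `noise_cv = 0` the
  generator is exactly deterministic in the intensities: cDNA X+Y equals
  the configured expression level for every marker, which the tests use
  as a conservation law.
- **QC failures.** `n_degraded_pairs` pairs (default 2 of 7) have a
  random `1 − degraded_call_rate` fraction (default 20%) of their gDNA
  markers zeroed out, so they fail a 0.95 call-rate threshold and are
  excluded — reproducing the designed cohort narrative of seven pairs
  with five analyzable.

Not emulated: batch/plate effects, copy-number alterations, probe-level
GC or cross-hybridization artifacts, allele-specific expression, and the
proprietary normalization a scanner vendor applies.  Passing tests on
these simulations therefore demonstrate the correctness and calibration
of the statistical machinery under the stated model, not robustness to
every failure mode of real arrays.

## Genotype calling and quantification

Fixed thresholds on θ = X/(X+Y) (AA ≥ 0.75, BB ≤ 0.25, AB in
[0.35, 0.65], otherwise NoCall; NoCall also when X+Y falls below a floor
of 5% of the grand median intensity) replace the vendor's proprietary
clustering algorithm, which is unpublished.  All thresholds are exposed
as parameters.  θ is scale-free, so calls are invariant to a uniform
rescaling of both channels (the floor must be rescaled alongside).

Technical replicates are averaged channel-wise on the raw intensity
scale before quantification: replicates share the same biology, so
averaging reduces noise without inflating the effective sample size.

Expression is quantified genotype-aware (AB → X+Y, AA → X, BB → Y,
NoCall → missing), then median scaled per array to the grand median and
transformed log2(e+1).  A pass-through mode (`scale=False`) skips the
median scaling for inputs that arrive pre-normalized.  Markers called AB
whose cDNA has one near-zero channel are retained as-is; detecting
allelic silencing is out of scope.

## Empirical-Bayes moderated paired t

With d_i the per-pair log2 differences, the marker summary is
(d̄, s², n), computed per marker over its complete pairs only — a marker
missing one pair's value loses that pair, not the whole marker, which
matters at five pairs.  The hierarchical model places a scaled
inverse-chi-square prior on the residual variance; its hyperparameters
(d₀, s₀²) are fitted by matching the mean and variance of log s² to the
scaled-F marginal via digamma/trigamma identities, inverting the
trigamma equation by Newton iteration.  When the dispersion of log s²
does not exceed what sampling alone explains, d₀ = ∞ and the moderated
test becomes a z-test against the pooled variance.  The two limits are
exact: d₀ = 0 reproduces the classical paired t (verified to 1e-10
against an independent implementation), and the posterior variance is a
convex combination, so shrinkage always moves s² toward s₀².

The candidate filter (P < 0.005, FDR < 0.15, |log2FC| > 1) uses strict
inequalities throughout; boundary values are rejected.  FDR is
Benjamini–Hochberg step-up with enforced monotonicity, capped at 1.
Marker-level FDR is filtered; the locus roll-up is descriptive.
Candidates map to loci by half-open interval containment (marker map
1-based, locus BED 0-based half-open); a marker inside two loci is an
error, and loci whose passing markers disagree in sign are reported as
"discordant" and excluded from the up/down tallies, since a
single-direction call is what a locus-level claim means.

## ISH scoring

The 0/1/2 rubric is: 0 below 0.1 dots/cell; 2 requires both >10
dots/cell and >10% of dots in clusters; everything else is 1.  Two
readings were genuinely open and are resolved conservatively: "few dot
clusters" is quantified as cluster fraction ≤ 0.10, and a specimen above
10 dots/cell without the clustering criterion is scored 1 rather than 2
(score 2 demands both conditions).  Two-observer consensus takes the
agreed score, the lower score on a one-level disagreement, and flags a
two-level disagreement for adjudication (excluded from analysis); the
combination rule for dual observers is a package choice, made
conservative on purpose.  QC excludes specimens whose positive control
(POLR2) scores 0 (degraded RNA) or whose negative control (dapB) scores
2 (background failure).

Rank tests use mid-ranks for ties.  Below a total of 12 observations the
two-sided p-value is exact — full enumeration of group assignments
(rank-sum) or sign flips (signed-rank), with "as extreme" measured by
distance of the statistic from its null mean, which handles the
asymmetric tie distributions correctly.  Above that, a tie-corrected
normal approximation with a 0.5 continuity correction is used; the two
agree within 0.02 at the boundary.  Zero differences are dropped
(classical Wilcoxon); `drop_zeros=False` switches this off for users who
prefer Pratt's treatment of zeros, though ranks are then computed over
all differences.

The ISH generator draws dots/cell from a gamma distribution
(shape 0.3, normal-tissue mean 0.15 dots/cell) whose heavy lower tail
reproduces the observed situation that most normal specimens fall below
the staining threshold while most tumors exceed it; the treatment effect
multiplies the mean by e^effect.  Cluster fraction increases smoothly
with dot density.  Degradation hits specimens independently with the
configured probability and zeroes the positive control.

## Survival analysis

Survival time is days-to-death for deceased subjects and
days-to-last-follow-up (censored) otherwise — implemented exactly as
stated, with records at time 0 or with unavailable stage excluded before
analysis.  Expression is categorized by absolute cutpoints (≤1, >1–5,
>5–10, >10; the historical upper bound of the top category merely
reflects an observed maximum and is treated as open-ended), and the
binary low/high contrast at 1.0 (boundary low) is the analysis
covariate.

- **Kaplan–Meier**: product-limit estimator; at tied times events are
  processed before censorings.
- **Log-rank**: observed-minus-expected event counts with hypergeometric
  variance per event time, chi-square with 1 df.
- **Cox**: Newton–Raphson on the partial likelihood with Breslow tie
  handling by default (Efron available via `ties="efron"`); covariates
  are centered internally for numerical stability; step halving guards
  the ascent; convergence at max |score| < 1e-8, with a stalled
  precision-limited score accepted and anything larger diagnosed as
  non-convergence (monotone likelihood from complete separation raises
  with the diverging coefficients named).  The global score test at
  β = 0 is reported; on tie-free data with a single binary covariate it
  equals the log-rank chi-square, a known identity the tests verify
  numerically.  "Adjusted for age" means a Cox model with the expression
  group and age as covariates; a stratified log-rank would be the other
  reading, and Cox was chosen as the conventional interpretation.
- **Kruskal–Wallis**: tie-corrected H, chi-square reference with k−1 df,
  exact enumeration of group assignments at total n ≤ 10; when every
  value is identical the statistic is defined as 0 with p = 1.
- **Fisher's exact**: full hypergeometric enumeration; the two-sided
  p-value sums all tables with point probability not exceeding the
  observed one (with a 1e-7 relative tolerance against float ties); the
  odds ratio is the sample odds ratio ad/bc.
- **Stage summaries**: sub-labels collapse (IA/IB → I, T1a/b/c → T1,
  etc.); quartiles use the linear-interpolation convention (numpy
  default, type 7) since the convention of the emulated reports is
  unknown.

The survival generator plants proportional hazards: exponential event
times with hazard multiplied by `hr_high` for expression > 1 and by
`hr_age_per_year` per year of age above 60, independent exponential
censoring targeting the requested censoring fraction, log-normal
expression (σ = 1.5) positioned so the >1 fraction is approximately
`frac_high`, ages uniform on 35–80 years (spanning typical
breast-cancer diagnosis ages; the exact bounds are immaterial to
correctness), and stage labels whose multipliers (0.7/1.0/1.25/2.5 for
I–IV) impose the stage-increasing expression shift the stage-association
tests are meant to detect.  Times are rounded to whole days and floored
at 1 to mimic clinical exports.  It does not model non-proportional
hazards, informative censoring, or competing risks.

## Knockdown concordance

Gene-level statistics are consumed, not produced — upstream expression
profiling and its normalization are out of scope, and the generator
plants shared and treatment-specific effects directly on the gene-level
scale (observed log2FC = true effect + N(0, se), p from the matching
z-test, so null genes have uniform p-values).  Filtering is strict
(p < 0.001), overlap percentages are relative to each treatment's own
significant set, and Spearman's ρ is the Pearson correlation of
mid-ranks with a t-approximation p-value (exact permutation at n ≤ 8).
ρ² is reported alongside ρ because squared correlation is the
convention in concordance scatterplots; both are labelled so no reader
needs to guess which was meant.

## Problem sizes and numerical choices

The test suite and acceptance script run the simulations at desk scale,
chosen so each check is decisive but quick: 200–2000 markers per array
cohort, 100-seed Monte-Carlo loops for calibration claims (false-locus
rate, sensitivity, Cox recovery), 50,000 markers for hyperparameter
recovery (where the moment estimator's ±15%/±10% accuracy needs the
ensemble), and n = 700 patients for survival recovery.  Determinism is
file-level: one `numpy` Generator seeded from the config drives each
generator, so identical seeds give byte-identical outputs.

Known limitations: the genotype caller's fixed thresholds have no
cluster adaptation, so atypical intensity distributions need manual
threshold tuning; the moderated test assumes exchangeable variances
across markers (no variance trend on intensity); the exact rank-test
enumerations are exponential and deliberately capped at small n; and
the Cox implementation targets small covariate counts, not
high-dimensional regression.
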