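# Methods

## Study design emulated by the generator

Ten endurance athletes (the default; any n ≥ 1 is supported) each complete
two counterbalanced crossover arms — three consecutive days of 2.5 h
exercise overload, or three days of rest — sampled pre and post on each
day plus the two following recovery mornings: occasions D1pre, D1post,
D2pre, D2post, D3pre, D3post, R1, R2 per arm, 16 study samples per
athlete. All 16 samples of an athlete are measured consecutively as one MS
batch in randomized injection order, bracketed and interleaved by four
injections of a pooled QC sample (slots 1, 8, 14, 20 of a 20-injection
batch). Arm order is counterbalanced (|exercise-first − rest-first| ≤ 1)
and randomized by seed.

## Generative model

Intensities are lognormal: on the natural-log scale, a study sample of
protein *p*, athlete *a*, batch *b* is

log I = μ_p + α_{pa} + γ_{pb} + 1[affected ∧ responder]·log(f) + δ_{pb}·ε

with μ_p ~ N(baseline_log_mean, baseline_log_sd²) the protein baseline,
α_{pa} ~ N(0, athlete_sd²) a per-protein athlete effect, γ_{pb} ~ N(0,
batch_location_sd²) and δ_{pb} = exp(N(0, batch_scale_sd²)) batch
location/scale perturbations, and ε ~ N(0, technical_sd²) injection noise.
QC injections share the pooled baseline μ_p (no athlete or treatment
terms) and differ only by batch effects and technical noise. Positivity of
intensities is automatic.

Planted archetypes: *acute* proteins multiply intensity by fold-change *f*
at D1post/D2post/D3post under the exercise arm; *chronic* proteins at R1
and/or R2 under exercise (default both); *null* proteins have f = 1.
Whether an athlete responds is Bernoulli(prevalence) per (protein,
athlete), frozen by seed; default prevalence 0.8.

Defaults, chosen once as plausible for DBS proteomics and then left alone:
baseline_log_mean 14.0 (≈1.2·10⁶ intensity units), baseline_log_sd 1.0,
athlete_sd 0.3 (~30% between-athlete biological CV), batch_location_sd 0.2,
batch_scale_sd 0.1, technical_sd = sqrt(log(1 + CV²)) calibrated so the QC
replicate CV hits its target (default 10%; the lognormal identity
CV = sqrt(exp(σ²) − 1) is inverted exactly). Fold-change default 2.0. No
missing values by default (a missingness rate parameter exists); the
distribution and missingness of the real data were never published, so
these are stated assumptions, not reconstructions.

What the generator deliberately does not model: carryover between crossover
periods (the emulated design uses a 3-week washout), peptide
misidentification, intensity-dependent (heteroscedastic) technical noise,
and correlated protein modules. Passing tests therefore demonstrate
correctness of the pipeline's statistics under a clean repeated-measures
lognormal world, not robustness to every artifact of real DIA data.

## Preprocessing

Fixed order: peptide→protein rollup, then batch correction, then row-max
normalization (correction deliberately precedes normalization).

* **Top-3 rollup.** Per protein, the three most abundant peptides (mean
  intensity across study samples; ties broken lexicographically by peptide
  id) contribute; fewer than three means all contribute. The protein
  quantity is the mean of the top peptides' log intensities (equivalently
  the geometric mean intensity) — the common top-3 convention, monotone in
  each peptide. The peptide set is fixed across samples so that sample
  comparisons are not driven by changing peptide selections. Proteins with
  zero peptide records are dropped with a warning.
* **Batch correction.** A transparent parametric empirical-Bayes
  location/scale adjustment on the log scale: per protein, data are
  standardized against the grand mean and pooled within-batch SD; per-batch
  means and variances are shrunk across proteins (normal prior on
  locations, inverse-gamma on variances, the usual fixed-point iteration)
  and removed. QC samples participate and are retained. A single batch is
  a logged no-op; a batch with one sample is an error naming the batch.
  Degenerate priors (no across-protein heterogeneity) fall back to the
  unshrunk estimates. Because each athlete is one batch, the correction
  also absorbs athlete-level mean differences; within-athlete contrasts
  are unaffected.
* **Row-max normalization.** On the intensity scale, each protein row is
  divided by its own maximum, so every row has maximum exactly 1 and
  values in (0, 1]. Idempotent and scale-equivariant; a non-positive row
  maximum is an error naming the protein.
* **Technical CV.** Computed *intra-batch*: within each batch holding ≥ 2
  QC injections, sd/mean of the QC intensities (pre-normalization scale),
  summarized as the median across batches. The intra-batch form isolates
  injection noise from batch-location differences, which in this design are
  confounded with athlete identity. An alternative `zscore` mode (z-score
  the protein across all samples, then sd/|mean| of QC z-scores) implements
  a literal reading of "CV in the z-score"; it is exposed but not the
  default because it is unstable when the QC mean z is near zero. Proteins
  with an undefined CV are gated at the strict α (conservative).

## Per-protein inference

A marginal model with the 16 time-by-condition cells as a categorical
predictor is estimated by GEE (Gaussian family, exchangeable working
correlation by default, independence available), clustered by athlete.
With only 10 clusters, plain sandwich variances are biased downward, so
the Mancl–DeRouen bias-reduced covariance is used with a t reference at
n_clusters − 1 degrees of freedom; this combination is calibrated — the
empirical size of the day-1 acute contrast over 500 simulated null
proteins is within 0.05 ± 0.02 — and its calls agree ≥ 90% with an exact
within-athlete sign-flip permutation test on both null and extreme-effect
instances. A constant response is handled as a degenerate exact fit (all
contrasts zero); non-converged proteins are flagged with status codes and
excluded from classification, never silently dropped.

The five reported contrasts are planned differences-of-differences of cell
means. Recovery contrasts are baselined to each arm's D1pre by default (an
unbaselined mode exists); baselining removes arm-level offsets while
keeping the exercise-vs-rest comparison. Multiplicity over the 16-level
pairwise family is reported via the studentized range: p_adj =
P(Q₁₆,df > |t|·√2), with a Bonferroni-over-5 fallback mode; adjusted
p-values are floored at the raw ones and a single-member family is left
unadjusted.

**Which p-value decides significance.** Classification judges each
contrast on its own (raw) p-value against the CV-gated α. The five
contrasts are planned differences-of-differences — they are not members of
the all-pairs family the studentized-range correction protects — so
applying that correction to them would control a family nobody tests while
costing most of the design's power at n = 10. The family-adjusted
p-values are still computed and reported per contrast, and classification
can be switched to them (`use_adjusted` / `classify_on: adjusted`).

## Classification rules

Significant positive = p ≤ gated α and estimate > 0. acute_sustained
requires all three acute contrasts significant positive; chronic_FOR
requires ≥ 1 recovery contrast significant positive and, in `strict` mode
(default), no acute contrast significant in either direction; `lenient`
mode tolerates at most one acute day significant positive. acute_sustained
takes precedence over acute_day1; acute and chronic labels are mutually
exclusive — a protein elevated on two or more exercise days is never
chronic_FOR. A further manual narrowing step (graphical pattern,
literature support, biological plausibility) is represented only as empty
annotation columns in the report; it is curation, not computation.

## Power simulation

Per replicate: one protein's data for n athletes are drawn as normal
log-intensities y = a_i + ε (random athlete intercept, technical noise);
responders (Bernoulli 0.8 per athlete) receive a mean shift of
effect_size · technical_sd at the tested contrast's exercise-arm cells.
A linear mixed model (random athlete intercept, 16-cell categorical fixed
effect, REML) is fit and the contrast tested two-sided at α = 0.05/5
(five-protein panel Bonferroni), t reference with residual df. Power is
the rejection fraction with mc_se = sqrt(p(1−p)/reps). The fixed-effect
design is parameterized as intercept + 15 treatment dummies — equivalent
for sum-zero contrasts and numerically far better conditioned than 16
indicators. The athlete-intercept SD is set to twice the technical SD; it
cancels from within-athlete contrasts, so its value does not drive power.
Cohort grid 10–50 in steps of 10; the effect size in SD units is a
required sweep parameter (no published value exists to anchor it), and no
numeric power value is asserted against external results — only size
under the null and monotonicity in n and effect size.

## Problem sizes and numerical choices

Default analysis scale: 200 proteins × 10 athletes (the package's standard
demonstration scenario); calibration checks use 500 null proteins; power
sweeps use 500 Monte-Carlo replicates in the verification suite and 200 in
the narrative driver (mc_se ≤ 0.035). The permutation oracle enumerates
all 2ⁿ sign patterns exactly for n ≤ 20 athletes. The EB fixed point
iterates to 10⁻⁶ (max 200 iterations). The CV gate reads "exceeded 15%"
as a strict inequality, so CV = 0.15 exactly selects α = 0.05. All
randomness flows from explicit integer seeds; identical config + seed
yields byte-identical artifacts (manifests deliberately contain no
timestamps).

## Known limitations

* Athlete and batch are perfectly confounded by design; batch correction
  therefore removes athlete-level location differences along with batch
  effects. Within-athlete contrasts are immune, but absolute abundance
  comparisons across athletes are not meaningful after correction.
* Row-max normalization ties every value to a single (noisy) maximum
  sample per protein; t statistics are invariant to row scaling, but the
  normalized estimates themselves depend on that maximum.
* The EB batch correction is ComBat-style, not a bit-exact port of any
  particular implementation.
* With 10 athletes and Bernoulli responder sampling, a protein drawing few
  responders is genuinely hard to detect; sensitivity figures are
  scenario-level averages, not per-protein guarantees.
* The published cluster counts from the original cohort depend on
  undeposited raw data and are not reproduced here; recovery is assessed
  against planted synthetic truth instead.
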