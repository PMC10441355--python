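# Methods

This package implements the computational core of a plasma-fraction
rejuvenation analysis: elastic-net epigenetic clocks over methylation beta
matrices, a rejuvenation-percentage statistic for three-arm treatment
studies, a per-CpG EWAS with unwanted-variation correction and
empirical-Bayes moderation, and an IgG N-glycan aging analysis.  Because
no real rat methylome of the required design is bundled, every analysis
runs against synthetic data with planted ground truth; this note records
the models, the defaults, and what the synthetic results do and do not
demonstrate.

## Epigenetic clocks

A clock is a sparse linear predictor of (transformed) age from CpG beta
values, fitted by elastic-net regression with mixing parameter fixed at
0.5 — the midpoint between ridge and lasso, deliberately not tuned.  The
penalty strength is chosen by an internal 10-fold cross-validation
minimizing mean squared error over a geometric path of 40 candidate
strengths spanning two decades below the smallest penalty that zeroes all
coefficients.  Fitting uses scikit-learn's coordinate descent on raw
(unstandardized) betas; the choice not to standardize is recorded in the
clock metadata.  A test cross-checks the solver against R's `glmnet` at a
fixed penalty, mapping glmnet's internal response standardization onto
the equivalent coordinate-descent objective; agreement is at optimizer
tolerance (1e-6).

Two response transforms are supported:

* **identity** — age in years;
* **relative** — age divided by the species' maximum lifespan
  (rat 3.8 years, human 122.5 years), mapping both species onto [0, 1].
  This is what lets a single clock serve species whose lifespans differ
  thirtyfold: an absolute-age clock fitted to a combined panel
  concentrates its loss on the long-lived species and degrades on the
  short-lived one, while the relative-age clock ranks ages well within
  each species separately.

Cross-validation (leave-one-out or k-fold) refits the entire procedure —
internal penalty selection included — on every training subset, so no
held-out sample ever influences its own prediction.  Reported metrics are
the Pearson correlation between held-out DNAm age and chronological age,
and the median absolute error in years.  Back-transformed ages below zero
are reported as-is; clipping would bias the error metrics.  Degenerate
training sets with a constant response yield a zero-weight clock whose
intercept is the common transformed age.

Epigenetic age acceleration defaults to the difference
(DNAm age − chronological age); the residual-on-age definition common in
human cohort work is available behind an explicit `mode="residual"` and
is labelled differently in the output so the two can never be confused.

## Rejuvenation percentage

For a three-arm study (young control / old control / old treated) scored
by one or more clocks,

    rejuvenation% = 100 · (mean old-control DNAm age
                           − mean old-treated DNAm age)
                        / (mean old-control DNAm age)

computed per tissue × clock from arithmetic means of per-sample DNAm
ages.  This form makes "more than halved the epigenetic age" equivalent
to rejuvenation% > 50, which is the property that pins the definition
down.  A gap-closure variant, 100·(old − treated)/(old − young), is
reported alongside under its own label.  Per-tissue values average the
per-clock ratios (the ratio of per-tissue mean ages is also reported, as
the other averaging order); the grand average is the unweighted mean of
per-tissue values.  Group comparisons use one-way ANOVA across the three
arms, the classical equal-variance Student t between the two old arms
(Welch behind a flag), and a two-sided Kruskal-Wallis test; identical
degenerate groups return H = 0, p = 1 rather than an error.

## EWAS

Each probe's betas are regressed by OLS on a shared cell-means design:
one indicator per treatment condition (no global intercept), plate and
array-column dummies (first level dropped), and k unwanted-variation
factors.  Rank deficiency is an error that names the aliased columns.
Working on the beta scale matches the pipeline's "normalized beta values"
input; an M-value transform is deliberately out of the fitted path and
can be applied upstream if wanted.

**Unwanted variation.**  Negative-control probes are selected
empirically: probes are ranked by |Pearson r| with age and by the
across-condition ANOVA F statistic, and the `n_controls` (default 500)
probes with the smallest rank-sum are taken, with lexicographic
tie-breaking for determinism.  Factors are the top-k right singular
vectors (sample loadings, orthonormal) of the row-centred control
submatrix, k = 2 by default.  A log-count transform would be
inappropriate for bounded betas, so the SVD operates on centred betas
directly.  The control list is part of the logged output, because
empirical controls are a modelling choice, not an oracle.

**Moderation.**  Per-probe residual variances s² with d residual degrees
of freedom are shrunk toward a prior by moment matching on log s²
(prior df d0 and prior variance s0² from the mean and excess variance of
log s² under the scaled-F model, with a Newton trigamma inversion).
When the observed dispersion of log s² does not exceed its sampling
dispersion, d0 = ∞ and the posterior variance is the pooled mean —
complete pooling.  Moderated t statistics use the posterior variance with
d0 + d degrees of freedom, capped at the pooled residual df across
probes.  Zero variances are offset by 1e-8 times the smallest positive
variance before logs.  A test verifies exact agreement (d0, s0², t, p)
with Bioconductor limma's `eBayes` on a shared fixture.

**Contrasts and the reversal summary.**  Contrasts are linear
combinations of condition coefficients — treatment = old_treated −
old_control, age = old_control − young_control — tested two-sided with
Benjamini-Hochberg adjustment within each contrast and a q < 0.05
significance flag.  The reversal summary counts, among age-significant
probes, those whose treatment estimate has the opposite sign, split by
age-gain and age-loss probes.  Under independence this proportion sits at
0.5, which the tests assert; values near 1 indicate per-CpG reversal of
the aging pattern.

## Glycan analysis

Raw chromatogram areas are normalized to the total within each sample ×
IgG subclass (IgG2a, IgG2b, IgG2c), giving glycoform proportions on the
simplex.  Before modelling, abundances are mapped to normal scores by
rank-based inverse-normal transformation, Φ⁻¹((rank − 0.5)/n) with
average ranks for ties — this equalizes variances across glycoforms so
their effect estimates are comparable.

Cross-sectional age association fits, per glycoform, OLS of the
transformed abundance on age in years with sex as a covariate, BH across
the glycoform panel.  The age coefficient is therefore in normal-score
units per year.  Longitudinal treatment analysis fits, per glycoform, a
linear mixed model with fixed time (baseline → follow-up) and
time × treatment effects and a per-subject random intercept, by REML;
fixed-effect p-values use the normal approximation to the Wald statistic.
At the default 6 + 6 subjects this approximation runs slightly liberal
(realized type-I error ≈ 8% at nominal 5% in the null simulations), a
known small-sample property that the tests document rather than hide.
Non-convergence of one glycoform's fit is reported in its result row and
does not abort the rest of the panel.  "Change from baseline" per subject
is provided as an export convenience only, not as an inference path.

## Synthetic data

The generator produces the statistical structure the analyses assume,
with all randomness flowing from a single integer seed through named
`numpy` generator streams (no global state; identical seeds give
bit-identical outputs).

**Methylomes.**  For aging probe i and sample j,

    beta_ij = clip01( invlogit( b0_i + s_i · relage_j
                                + tissue_ij + plate_ij + column_ij )
                      + ε_ij ),   ε ~ N(0, noise_sd)

where relage = age / species maximum lifespan.  Linearity in
logit(beta) against relative age keeps betas bounded, makes elastic-net
recovery well-posed, and makes the two-species shared-signal construction
exact: a rat and a human at the same relative age have identical expected
betas at shared-signal probes.  Non-aging probes have s_i = 0.  Defaults
(the standard panel): 2,000 probes, 200 aging CpGs with slope magnitudes
|N(4, 1)| in logit units and a 50/50 gain/loss split, probe baselines
N(0, 1), four tissues × 60 samples, ages uniform on 0.04–2.3 years,
tissue offsets N(0, 0.3), plate effects N(0, 0.2) with within-plate
column effects at half that, beta-scale noise sd 0.03.  Samples are
placed on 12-sample plates in random order, as array randomization would
do, keeping batch separable from biology.  The batch magnitudes are
stated defaults, not estimates — no inter-lab effect sizes were available
to calibrate them.

Probe-level parameters (baselines, slopes, the aging-probe set, tissue
offsets) are drawn from the seed's probe stream only, so two datasets
generated from configs sharing a seed describe the same CpG population:
clocks trained on one transfer to the other.  Sample-level draws use
separate streams.

**Treatment study.**  Three arms per tissue (n = 6 each by default):
young at 0.58 y (30 weeks), old control at 2.1 y (109 weeks), and old
treated generated at effective age old_age · (1 − R/100) but annotated
with its chronological old age.  Planting the treatment as a reduced
effective age makes the planted R exactly the quantity the rejuvenation
statistic estimates, so recovery is a genuine end-to-end check.  The
default R is 67.40%.

**Glycans.**  Per subject × subclass × glycoform random intercepts
N(0, 0.02); control follow-up drifts by per-glycoform slopes
(G0 +0.04, G1 −0.01, G2 −0.03 — toward agalactosylation); the treated arm
additionally shifts by the planted treatment effect (G0 −0.05, G1 +0.01,
G2 +0.04 — the reversal); residual noise sd 0.02; compositions are
renormalized to the simplex per sample × subclass.  Drifts and shifts sum
to zero within a subclass, so in the noise-free limit renormalization is
the identity and planted effects are recovered exactly.

**What the synthetic data does not emulate:** probe-level chemistry
(dye bias, detection failures), cell-composition heterogeneity,
inter-lab batch structure beyond simple plate/column shifts, nonlinear
(e.g. developmental) aging trajectories, and any coupling between the
methylation and glycan panels.  Passing tests therefore demonstrate that
the estimators recover what was planted under their own model
assumptions — not that real tissue would behave this way.

## Numerical choices and scale

* Internal CV penalty selection: 40-point path, path floor at 1e-2 of
  the maximal penalty, coordinate-descent tolerance 1e-4, max 5,000
  iterations.  Ties in CV error resolve to scikit-learn's selected
  optimum.
* Clock coefficients serialize at %.17g, which round-trips IEEE doubles
  exactly; file parsing uses round-trip float precision.
* The trigamma inversion iterates Newton steps to relative 1e-10 with
  asymptotic starts for extreme arguments.
* Standard study sizes (240-sample panel, 150 + 150 two-species panel,
  5-seed rejuvenation recovery, 200-replicate null calibrations) were
  chosen as the smallest designs at which the planted effects are
  comfortably identifiable; the full leave-one-out run on the standard
  panel refits 240 clocks and is the long pole of the suite.

## Known limitations

* The rejuvenation estimator inherits a small attenuation from penalized
  shrinkage: predictions are pulled toward the training mean, so the
  recovered grand average sits ~1–2 percentage points below the planted
  value at the default training size.  This bias shrinks with training
  n and is visible (and bounded) in the recovery tests.
* Empirical negative controls assume most probes are unassociated with
  age and condition; on panels saturated with signal the control set
  would be contaminated.
* Mixed-model inference uses Wald-normal p-values; no Satterthwaite or
  Kenward-Roger small-sample correction is implemented.
* The EWAS models betas directly; variance is mean-dependent near the
  [0, 1] boundary, which moderation absorbs only partially.
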