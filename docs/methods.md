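# Methods

## The compositional model

Daily behaviour durations carry only relative information once the 24 h
constraint is imposed, so all inference happens in isometric log-ratio (ilr)
space. We use pivot coordinates: with parts ordered
(x1, ..., x5), coordinate j is

    z_j = sqrt((5-j)/(5-j+1)) * ln( x_j / gm(x_{j+1}, ..., x_5) ),  j = 1..4

where `gm` is the geometric mean. The canonical order is (sitting,
standing, LPA, MVPA, sleeping), so z1 is the sitting-versus-rest balance.
The 5×4 contrast matrix has orthonormal columns orthogonal to the ones
vector, which gives three facts the tests rely on: the map is an isometry
(distances are preserved), it is scale-invariant (closure before
transforming is optional), and any two lead-part orderings span the same
coordinate space, so fitted values, R², predictions, substitution estimates
and grid rankings are identical across orderings — only the coordinate-wise
coefficients rotate. The relative order of the four non-lead parts inside
the geometric mean is implementation-defined (it rotates coordinates 2–4
without changing the first coordinate or any model output); we keep the
canonical relative order.

Zero durations are a hard error rather than being imputed: log-ratios are
undefined at zero, imputation silently changes estimates, and both the
upstream aggregation and the synthetic generator guarantee positivity. The
internal unit is minutes/day with total 1440; `h:mm` strings appear only in
report columns.

## Outcomes

Six outcomes enter as z-scores (sample mean/SD, n−1 denominator): waist
circumference and the Matsuda index on their natural scale; FPG, 2-h
post-load glucose and HbA1c after natural-log transformation (their
residuals are closer to normal on that scale). The Matsuda index
`10000 / sqrt(FPG·FPI·meanG·meanI)` is computed on whatever concentration
units are supplied — its absolute level is unit-dependent, but z-scores are
invariant to multiplicative unit changes, and HbA1c given in % is converted
to mmol/mol at ingest (the two scales are affine, so log-z-scores would
otherwise differ). The clustered cardiometabolic risk score averages five
standardised components (waist, ln FPG, ln triacylglycerol, ln HDL with the
sign flipped, mean blood pressure), so its sample mean is zero by
construction; it is re-z-scored by default purely to put its regression
coefficients on the same SD scale as the other outcomes.

Glycaemic status uses the WHO 2006 OGTT bands. Two readings of the
type-2-diabetes rule exist (FPG ≥ 7.0 *or* 2hPLG ≥ 11.1 versus the joint
*and*); the `or` reading is the default, the `and` reading is available via
`t2d_conjunction`. At one-decimal reporting precision the impaired-fasting
band 6.1–6.9 is implemented as `6.1 ≤ FPG < 7.0`, which keeps the
(FPG, 2hPLG) plane an exact partition under both settings. Glucose-lowering
medication overrides to T2D.

## Regression and substitution

Ordinary least squares of each outcome z-score on the four ilr coordinates
plus covariates; inference uses the t distribution on residual degrees of
freedom (no robust errors). Categorical covariates are treatment-coded with
the first alphabetical level as reference (recorded in the fit — the choice
cannot affect composition effects); continuous covariates are centred at
their sample means, which moves only the intercept. Complete-case analysis
throughout. The optional waist-circumference adjustment is disabled
automatically when the outcome is waist or the risk score (waist is one of
its components). Composition-by-stratum interaction is tested by an F-test
comparing the shared-ilr model against one with a separate ilr block per
stratum level (identical span to main-effects-plus-interactions); the
per-level lead-coordinate coefficients come directly from that cell-means
parameterisation.

Isotemporal substitution moves Δ minutes (default 30) between two
behaviours starting from the sample's compositional geometric mean
(per-stratum means for stratified estimates): the estimate is
`(ilr(new) − ilr(base))·β̂`, its variance `dᵀVd` with V the ilr-block
covariance, CI at 95% by default. Because the model has no
composition-by-covariate interactions the estimate is covariate-free, which
the tests assert against a brute-force prediction-difference oracle.
Estimates are reported on the z scale; back-transformation through the
stored scaler is available and labelled approximate for log-scaled
outcomes.

## Optimal zones

Candidates are enumerated on an inclusive 10-min lattice inside the
footprint (per-behaviour 1st–99th percentile bounds, linear-interpolation
quantiles rounded to the nearest step; a published footprint can be
injected verbatim, and with the published bounds the lattice holds exactly
142,938 days). Ranking uses only the compositional part of the linear
predictor — covariates shift all candidates equally — and the engine
refuses fits with composition-by-stratum interactions, which must be ranked
per stratum. The selected set keeps `k = ceil(fraction · N)` candidates
(ceiling guarantees non-emptiness; ties break by predicted value then
lexicographic composition, so selection is deterministic), from the low end
for adverse markers and the high end for insulin sensitivity. The
overlapping zone intersects the per-outcome sets at the smallest fraction
in the 5%→10% schedule (1% steps; the endpoints are the published ones, the
step is our choice) that is non-empty, the same fraction for all outcomes;
an empty overlap at 10% is a reported result with pairwise diagnostics, not
an error. Zone centres are part-wise geometric means closed to 1440 then
rounded per part to the nearest 10 min — rounded parts need not sum to
exactly 24 h. Tetrahedron export fixes sleep at 8 h (nearest lattice level
otherwise, with a warning), renormalises the four waking parts and maps
them barycentrically onto a regular tetrahedron.

## Wear-day aggregation

The first measured day is always dropped; the final day is dropped when it
contains ≤ 14 h of recorded information (this recorded-hours rule applies to
the last day only — intermediate days are judged by waking time); remaining
days need ≥ 840 min of waking time. Stepping epochs split at 100 steps/min,
with exactly 100 counting as MVPA. Behaviours average arithmetically over
valid days; sleep is 1440 minus mean waking time. Day-level waking time may
exceed the sum of classified behaviours (monitors leave a remainder
unclassified); the default spreads the shortfall proportionally over the
four waking behaviours so the 24 h identity holds, and a strict mode raises
instead. Sub-day non-wear within otherwise valid days is not modelled.

## The synthetic cohort

The generator emulates the structure of a three-stratum (NGM/IGM/T2D)
middle-aged cohort of 1341/363/684 participants. Compositions are
logistic-normal: stratum centres at the published medians (e.g. sitting
9.1/9.6/10.2 h, sleep ≈ 8.2 h), log-scale SDs (0.16, 0.28, 0.35, 0.55,
0.09) with negative sitting–activity correlations — the covariance is
invented but plausible, as no real covariance is published. Covariate
distributions (age, diet score, sex, education, smoking, medication) match
the published stratum frequencies.

Each raw marker derives from a latent linear response: stratum offset +
ilr·β + covariate effects + Gaussian noise, mapped to raw units by
`exp(loc + scale·latent)` for log-scale markers and affinely otherwise
(identity-scale markers are clipped far in the tail to preserve
positivity). Stratum offsets are solved internally so the realised stratum
centres land on configured raw targets; the IGM 2-h glucose target is set
to 9.2 mmol/l — slightly above the published 8.4 — so that WHO-band
classification recovers the intended stratum for ≥ 95% of participants
under realistic within-stratum spread (the generator is approximate by
design: only medians and IQRs are published). Fasting and mean OGTT insulin
are solved from the target Matsuda latent, generated FPG and a
glucose-correlated mean OGTT glucose, so the marker pipeline reproduces the
intended insulin-sensitivity latent exactly.

The truth record stores, per outcome, the coefficient on the analysis
(z-score) scale, `beta_z = β / SD(latent)`, with the latent SD computed
analytically from the generating mixture (between-stratum mean spread +
within-stratum ilr, covariate and residual variance); the derived risk-score
coefficient additionally uses the analytic covariance between its five
components. Fitting the pipeline's z-scored raw markers estimates `beta_z`
up to O(1/n) scale-estimation noise, which is what the recovery tests
verify (bias ≪ 0.02 SD, CI coverage 93–97% at n = 2388). What passing these
tests shows is that the estimator is unbiased and calibrated *when the
generating model is true*; the generator has Gaussian noise, no
within-stratum confounding beyond the modelled covariates, no missing data
and no measurement error, so it says nothing about robustness to those
features of real data.

Day-level records (8 days; day 1 is the clinic day; the last day's recorded
hours are drawn short often enough to exercise the last-day rule; 3% of
mid-week days fall below 14 h waking; 6% log-normal day-to-day jitter; 2%
of waking left unclassified; four cadence epochs per day straddling 100
steps/min) exist to exercise the aggregation stage, not to mimic
accelerometer signal structure.

One seed governs everything through spawned sub-streams, so identical
(config, seed) pairs give byte-identical tables.

## Numerical conventions and simulation sizes

Closure tolerance 1e-6 min; ilr round-trips are accurate to ~1e-13. Grid
set-operations encode lattice rows as base-2048 integers (exact for
minute-valued parts). Simulation-based tests use sizes chosen to keep the
default suite under a minute while leaving wide Monte-Carlo margins:
200 replicate cohorts at n = 2388 for recovery/coverage, 1000 redrawn-noise
replicates on a fixed n = 300 design for interaction-test calibration (the
F-test is exact under Gaussian errors at any n, so this checks
implementation, not asymptotics), 50 replicates at n = 2000 with unit noise
for monotone-optimum recovery (the true-optimum grid point sits ~10× inside
the top-5% boundary at these sizes).

## Known limitations

Cross-sectional associations only; no causal or longitudinal claims. No
mixed models, survey weights, splines, robust errors or multiple
imputation. Raw monitor event processing and sleep/wake detection are
upstream of this package. The public contract is five parts; internals
generalise but are not exposed for other D.
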