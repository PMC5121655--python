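# Methods

This note documents the models implemented in `telodyn`, the
synthetic-data generator they are validated against, and the design
choices made where the problem was genuinely open.

## The scientific setting

Relative telomere length (RTL) in a wild population of edible dormice
is measured repeatedly in the same individuals over several active
seasons. Three questions structure the analysis: how RTL varies with
age across the population; how RTL *changes* within individuals,
after guarding against regression to the mean; and whether the
within-individual change switches regime over the lifespan — from
attrition in young animals to elongation in old ones — in parallel
with a rising, eventually saturating probability of reproduction.

## qPCR quantification

A well's raw fluorescence is modelled as baseline + optional linear
drift + amplification signal. The efficiency estimator works in the
window-of-linearity tradition:

1. baseline = mean of the pre-amplification cycles (default cycles
   3–8; a linear drift can be co-estimated);
2. the fitted exponential is extrapolated back into the baseline
   cycles and removed, and the baseline re-estimated — iterating
   until the selected window stabilises. Without this
   reconstruction, early exponential growth inflates the baseline and
   biases the slope; with it, clean curves are recovered to machine
   precision;
3. the exponential window is the 4–6 cycle span maximising the R² of
   log10(signal) vs cycle, restricted to cycles above 10× baseline
   noise and below 95% of the plateau; `E = 10^slope`. Near-ties go
   to wider, later windows (higher signal, less baseline leverage);
4. Ct is interpolated on the log scale at a run-constant threshold,
   set to a fixed fraction (default 0.2) of the run's median plateau.
   The threshold rule is a package choice; any run-constant threshold
   cancels out of the RTL ratio to first order.

RTL uses the run-mean efficiency per assay by default (per-well
efficiencies are available behind `per_well_efficiency=True`); which
of the two a given laboratory protocol used is rarely stated, so both
are exposed. Replicates deviating more than 0.5 cycles from their
median are excluded as outliers — triplicate protocols typically
state no explicit rule, and a half-cycle is far outside pipetting
variation at robot precision. Flat or plateau-only curves get a
`no_amplification` flag; a sample with no surviving replicate on
either assay is fatal for that sample only.

## Mixed models

Cross-sectional model: `rtl ~ sex + age + age² (+ age³) + body_mass +
reproductive_active + day_of_year`, with crossed random intercepts
for animal and plate. Crossed factors are expressed as variance
components inside a single all-encompassing group (the standard
formulation for crossed effects in `statsmodels` MixedLM). The cubic
age term follows a fit-and-drop rule: retained only when p < 0.05.
Random factors with a single level are dropped with their variance
reported as 0; if the numerical fit fails or the response is
noise-free (zero residual variance breaks the profiled likelihood),
the model falls back to ordinary least squares, which is exact in
that case.

Fixed-effect p-values use the normal approximation to the Wald
statistic. Satterthwaite degrees of freedom are not available in
this backend; at the cohort sizes used here (≥49 subjects, ≥100
observations) the difference is negligible, but p-values near 0.05
at much smaller sizes should be read with care. One test
cross-checks the fixed effects against an independent lme4 (REML)
fit of the identical model.

The change model regresses `RTL_t` on `RTL_{t−1}`, the covariates
above and the sampling interval. Conditioning on the previous value
is the regression-to-the-mean adjustment: with measurement noise on a
stable latent value, the coefficient on `RTL_{t−1}` is attenuated
below 1 and naive change scores would show spurious decline in
animals that started high. The residual formulation — residuals of
OLS of RTL loss on initial RTL — is provided as
`rtm_residual_correction`; by the Frisch–Waugh theorem it yields the
same age-term inference as the joint fixed-effects fit when the
comparison is done on initial-RTL-residualised predictors, and the
corrected changes sum to zero exactly.

`r2_full` is the squared correlation between fitted (fixed + BLUP)
and observed values; `r2_random` the same for the random-effect
predictions alone. Correlation-based r² is one of several mixed-model
r² conventions; it is reported for orientation, not inference.
AICc = AIC + 2k(k+1)/(n−k−1) ranks candidate random structures, with
k counting fixed effects, variance components and the residual
variance, and candidates with n ≤ k+1 excluded.

## Within-subject centering and the change point

Age is decomposed as `age_ij = mean_age_i + delta_age_ij`. The
centered model `response ~ mean_age + delta_age (+ interaction) +
initial_rtl` separates the between-subject age profile from the
within-subject rate of change; `initial_rtl` (the subject's first
measurement) adjusts segment comparisons for initial telomere length
and, being a between-subject covariate, leaves the within-subject
slope estimand untouched.

Because the within-subject effect reverses sign over the lifespan, a
single pooled slope is meaningless; segment models are fitted to
subjects below and above a candidate mean-age split. Candidates are
midpoints between consecutive distinct mean ages — any split between
the same two subjects induces the identical partition — and
candidates leaving a segment with fewer than `min_group_subjects`
(default 5, protecting the small old group) are skipped. The
reported split minimises combined RSS.

Two open choices and their resolutions:

- **Segment-model form.** Plain regressions are the default for the
  search: their RSS is directly comparable across partitions, whereas
  mixed-model residuals involve BLUP shrinkage whose strength varies
  with segment size, which empirically mis-locates the split more
  often and attenuates the old-segment slope. A mixed mode (random
  intercept per animal) is available via `mode="mixed"`.
- **"No supported break".** A raw relative-RSS-improvement floor
  cannot flag the null case: splitting doubles the segment
  coefficients and the argmin over candidates inflates improvement
  under the null (median ≈ 8% at this design). The `supported` flag
  therefore requires the split model to win a BIC comparison in which
  it is charged for both segments' coefficients plus one parameter
  for the searched split location, alongside a 1% raw-improvement
  floor. This is conservative: weak true breaks may be flagged
  unsupported; the RSS profile is always returned for inspection.

Split-age uncertainty is available by subject-level bootstrap
(seeded; default off).

## Reproduction

The yearly probability that a female reproduces is a Bernoulli GLMM:
logit p = β₀ + β₁·age + u_year + v_animal. Estimation is penalised
quasi-likelihood — a joint Newton step for fixed and random effects
given variances, alternating with Laplace variance updates
σ²_g ← (‖b_g‖² + tr T_gg)/m_g — with Aitken extrapolation of the
slowly converging variance fixed point. Convergence is declared on
the Laplace log-likelihood: with one record per animal-year, the
animal variance direction is nearly flat and keeps drifting long
after the likelihood (and every reported quantity) has stabilised;
this weak identification also shrinks the estimated animal SD below
its generating value, a known limitation of the design rather than
of the optimiser. The age effect is tested by a likelihood-ratio
chi-square between Laplace log-likelihoods with and without age.

The prediction curve is population-averaged: the logistic is
integrated over the pooled fitted random-effect distribution by
Gauss–Hermite quadrature (25 nodes), giving the "averaged over years
and individuals" curve; it is bounded in [0,1] and monotone for a
positive slope. Complete or quasi-complete separation (e.g. every
old female reproducing) is detected by fixed-effect divergence and
handled by a bias-reduced (Firth/Jeffreys-prior) logistic fallback,
which always has finite estimates.

Litter size is tested against age by a likelihood-ratio between
Gaussian mixed models (animal random intercept, ML) with and without
age; the summary also reports the sample mean and SD. A Gaussian
family on counts mirrors the mean-±-SD framing of litter sizes around
5–6 pups; a Poisson variant would be preferable for small counts.

## The synthetic generator

The generator is the analysis model run forward, so that parameter
recovery is well-posed. Defaults encode the emulated study design:

- 49 subjects; 2/3/4/5 captures for 15/15/12/7 of them; entry ages
  1–8 with weights 15, 20, 1, 4, 4, 2, 1, 2; capture interval
  178.3 d with ±30 d uniform jitter (the interval enters the change
  model as a covariate); entries spread over the April–October active
  season.
- Observed RTL = Q(m_i) + u_i + s(m_i)·(age − m_i) + plate + resid,
  where m_i is the subject's realised mean age,
  Q(m) = 1.0 − 0.14·m + 0.019·m², and s(m) is −0.097 RTL/y for
  m ≤ 5.3 and +0.410 above.
- Variance defaults: sd_resid = 0.22 (chosen so the young-segment
  slope SE at this design, sd_resid/√ΣΔ², reproduces the target
  magnitude ≈ 0.042), sd_subject = 0.10 (cross-sectional SEs near
  0.07 / 0.007), sd_plate = 0.05 (consistent with inter-run
  agreement of R ≈ 0.96 and slope ≈ 1.1). Observations are assigned
  to plates of 30 in randomised order, so plate is not confounded
  with age.
- qPCR curves: F(c) = baseline + drift·c + min(q0·E^c, plateau) +
  noise, with q0 of the telomere assay proportional to true RTL,
  efficiencies 1.9630/1.9486, fluorescence noise 0.002 of a plateau
  of 1, and log-normal pipetting error (σ = 0.003) giving
  replicate-Ct CVs of order 10⁻⁴.
- Reproduction: animals enter at age 1, survive with probability
  0.65/yr; logit p = −2.8 + 1.4·age + year + animal effects (SDs 1.0
  and 0.5 — year-to-year food supply dominates in a masting-dependent
  breeder), clamped to 1 at age ≥ 5; 1529 animal-years produce ≈800
  litters. Litter sizes are drawn from a discretised normal truncated
  at 1 whose latent parameters are solved so the realised mean/SD are
  exactly 5.49/2.14 (naive rounding+truncation would inflate the mean
  by ≈0.06 pups).

**A structural caveat.** The between-subject profile is quadratic in
*mean age* and exact there; the cross-section in *observed* age is
only approximately quadratic, because the within-subject drift term
(s(m) − Q′(a))·(age − m) is orthogonal to every function of mean age
and can be cancelled by no between-subject profile — with a steep
old-age within-slope this is a theorem, not a tuning failure. Two
consequences, visible in the tests: the pooled cross-sectional
quadratic is distorted by roughly (−0.04, +0.005) on noise-free data,
and the mixed model adds a within-information pull in the same
direction (growing with sd_subject²/sd_resid²), so recovered
cross-sectional coefficients sit near (−0.20, 0.026) against the
configured (−0.14, 0.019) — within two standard errors at the
49-subject design, which is how the recovery suite checks them. The
within-subject slopes and the split location are unaffected; they are
the estimands the centering machinery isolates exactly.

What the generator does **not** emulate: hibernation physiology,
body-temperature records, survival processes (a
selective-disappearance flag exists but is off by default),
assay-plate spatial effects, melt-curve specificity. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery at this design, not robustness to every failure mode of
real field data.

## Problem sizes and numerics

The recovery suite uses the study's own scale: 50 replicate
49-subject cohorts for the segment slopes and split (the
package's acceptance script reports their means/medians), one
200-subject cohort to tighten the cross-sectional SEs, and the full
1529 animal-year reproduction table. Type-I-error calibration of the
litter-size LRT runs 200 null replicates at 150 litters each. All
randomness flows from numpy `SeedSequence`s; fixed seeds make every
simulation, bootstrap and pipeline output byte-reproducible.
Degenerate inputs are handled explicitly: zero-variance responses
fall back to OLS, single-level random factors report zero variance,
constant initial RTL in the residual correction warns and
mean-centres, and a flat amplification curve is flagged rather than
fitted.
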