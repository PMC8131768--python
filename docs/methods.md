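# Methods

This note documents the models behind `osmofit`, the choices made where
the methodology was genuinely open, and what the synthetic-data generators
do and do not emulate.

## Dose–response model and LC50

Acute tolerance data are replicate boxes (default 10 adults) exposed to a
salinity series and censused at 48, 72 and 96 h; dead individuals are
removed at census, so counts are cumulative survivors. For each exposure
time and population we fit a binomial GLM with logit link of the death
probability on **untransformed** dose. Log-dose, the ecotoxicological
default, is unavailable here because the design includes a true 0 ppt
(freshwater) control. Mortality rather than survival is modelled so that
LC50 — the dose at which half the population dies within the exposure
window — is the 0.5 point of the fitted curve directly, LC50 = −β₀/β₁.

Each exposure time is fitted independently on the cumulative survivor
counts. This matches how per-time LC50 tables are conventionally reported,
at the cost of ignoring the interval-censored time-to-death structure (the
72-h data contain the 48-h deaths); a joint time-to-event dose–response
model is out of scope.

Fitting uses maximum likelihood (IRLS, deviance tolerance 1e-8, 100
iteration cap). Separation is flagged when any coefficient exceeds 30 on
the logit scale, when a standard error is non-finite, or when the data are
degenerate (every replicate all-dead or all-alive — the deviance then
flattens at a finite iterate although no finite MLE exists); flagged fits
are returned with `converged=False` rather than raised.

**LC50 uncertainty.** The default SE is the delta method applied to
g(β) = −β₀/β₁: Var ≈ ∇gᵀ Σ ∇g with ∇g = (−1/β₁, β₀/β₁²), giving a
symmetric interval on the dose scale — the standard match for "LC50 ± SE"
reporting. A Fieller interval (inversion of the ratio test; asymmetric,
unbounded when the slope is not significantly non-zero) is available via
`method="fieller"`. Monte-Carlo calibration under the design (9 doses × 5
replicates × 10 adults, truth 8.69 ppt, slope 0.5/ppt) gives delta-method
95% coverage ≈ 0.94.

**Fit quality.** No unique R² exists for a binomial GLM; the reported `r2`
is the squared Pearson correlation between observed and fitted replicate
mortality proportions, and the definition is carried in the result object
(`r2_definition`).

**Between-population comparison.** An ANCOVA-style linear model on
replicate-level survival proportions with dose (covariate), population and
their interaction, sequential F-tests, box as the unit. Replicate
proportions — not the LC50 point estimates — are the response: with two
populations × 9 doses × 5 replicates this yields the residual degrees of
freedom (≈ 86) that LC50-level responses could not produce.

## Fitness surrogates

Per common-garden box (the independent unit): adult survival = survivors
at the 30-day horizon / initial adults; fecundity = total eggs; oviposition
rate = eggs per observed day; number of immatures = F1 juveniles counted
before wing development. Sex-specific survival keeps the **whole-box
denominator** (5 + 5 adults), so male + female survival equals overall
survival — this is the convention under which published per-sex means add
up to the overall mean. The oviposition denominator is the fixed
observation window (default 30 d, stored per box), not days with surviving
females; published rate ≈ fecundity/30 consistency supports this reading.
Cell summaries report mean and SE (sample SD/√n over boxes); single-box
cells report SE 0 with a degenerate-cell warning.

## LA and MA indices

LA = (Wₙ − Wf)/mean(Wₙ, Wf) per population × site × trait. Properties
relied on by the tests: antisymmetry under swapping native/foreign, scale
invariance (fitness units cancel), range [−2, 2] for non-negative fitness.
When both fitness means are zero the index is **undefined and flagged**,
not set to 0 — a 0/0 site carries no information about adaptation.
Trait-averaged LA is the unweighted mean over the four core surrogates;
any exclusion of a trait (e.g. averaging only reproductive surrogates) is
an explicit argument, never silent.

MA = 1 − W_realized/W_ideal, i.e. the difference after standardising the
ancestral population's home-site fitness to 1.0. The alternative reading
(raw difference W_ideal − W_realized) is not scale-invariant and does not
reproduce the conventional survival benchmark on the shipped means, so the
ratio form is used. MA > 1 is impossible; MA < 0 (derived population
exceeding the ancestral benchmark) is reported as-is with an
`exceeds_ideal` flag rather than clipped.

Home sites default to 0 ppt for the ancestral FW population and 1 ppt for
the derived BW population (whose treatment water is its home-lagoon
water); the mapping is caller-configurable.

**Known non-matches.** On the shipped published means the stated
definitions give MA(fecundity) = 0.78, MA(oviposition) = 0.78,
MA(immatures) = 0.87, whereas the published narrative rounds these to
0.69/0.70/0.72 — values that instead equal 1 − (BW-in-FW mean)/(ideal),
i.e. a different realized cell than MA(survival) uses. Similarly the
narrative's BW trait-average at 1 ppt (−0.22) and FW immatures LA at 1 ppt
(0.26) are not recoverable from the published cell means (−0.09 and 0.43).
The package computes and asserts the definition-consistent values and
documents the discrepancy instead of special-casing those entries;
unrounded raw data would be needed to arbitrate.

## Supporting inference

Box-level aggregates are the response everywhere, so the box is the
independent unit and all models are **fixed-effects**; no random box
intercept is fitted (the mixed-model analogue would need the within-box
raw data). Factorial tables use sequential (Type I) sums of squares with
factors entered treatment, sex, origin, then treatment:origin, and report
both the F-test and a likelihood-ratio χ² per term from nested refits.
One-way ANOVA is computed in closed form (the full SS decomposition is
part of the return contract) and cross-checked against
`scipy.stats.f_oneway`; Tukey HSD adjusted p-values come from scipy's
studentized-range distribution; ties in any letter display resolve by
lexicographic group order. Welch's t uses Satterthwaite degrees of
freedom (the appropriate test when group variances differ, as indicated
when a reported df falls below the pooled value). No multiple-testing
correction is applied across traits.

## Survival time

Kaplan–Meier product-limit curves (via lifelines) per population ×
treatment, pooling individuals across boxes; deaths are assigned to the
census day on which a count dropped. Adults alive at day 30 are censored
at 30 (they are removed from the boxes then); F1 survivors are censored at
90. Greenwood's formula gives the per-time SE. The median is the first
event day with S ≤ 0.5; a curve that never reaches 0.5 has an undefined
median, reported as "≥ last follow-up day". No log-rank test is provided.

## Synthetic-data generators

`simulate_tolerance`: each individual dies in the first interval with
probability expit(slope × (dose − LC50)); survivors of each later census
face a conditional hazard of `hazard_scale` × that probability (default
0.5). Defaults follow the study design: doses (0, 1, 3, 5, 10, 15, 20,
25, 33) ppt, 5 replicates × 10 adults, true LC50s 8.69 (FW) and 10.58
(BW) ppt. The slope 0.5/ppt (mortality 12%→88% over ±4.4 ppt around LC50)
is a realism choice; acute bioassay curves for osmoconforming insects are
steep but not step-like.

`simulate_garden`: per box, daily Bernoulli deaths per individual by sex;
daily egg clutches drawn while ≥ 1 female is alive (a flag decouples this
for null tests) from a Poisson (φ = 0) or negative-binomial count with
variance = mean × (1 + φ), default φ = 2 because published box-level SEs
exceed equidispersed expectations; offspring are a binomial thinning of
eggs; F1 death days are geometric with a constant daily hazard, censored
at 90 d. Design defaults: 5F + 5M per box, 10 boxes for the FW population
at 0 ppt and 8 elsewhere.

**Calibration is analytical**, not fitted: daily death probabilities
invert the target 30-day sex-specific survival contributions
(p = 1 − f^(1/30)); the egg rate divides target fecundity by the expected
number of days with ≥ 1 female alive (Σ_d 1 − (1 − s^d)^5); the thinning
fraction is target immatures / target fecundity. `implied_cell_means`
returns the resulting generator truth, so recovery tests compare pipeline
estimates against exactly what the generator encodes. Default targets are
the packaged published cell means; the implied oviposition rate is
fecundity/30 and therefore only approximates the independently rounded
published rates.

What the generator does **not** emulate: within-box correlation beyond
shared parameters, age- or density-dependent hazards, egg-to-immature
development lags, individual heterogeneity in fecundity, and
non-independence between boxes sharing water sources. Passing recovery
tests therefore demonstrates estimator correctness under the stated
stochastic model, not robustness to those real-data features.

## Problem sizes and numerical conventions

Monte-Carlo checks in the test suite use 200 replicate experiments for
power/recovery studies, 1,000 for the LC50 CI coverage study (the
coverage estimate's binomial noise must be small against the ±0.02
acceptance band), and 2,000 for type-I error calibration — sizes chosen
so each estimate's MC error is several times smaller than the margin it
is compared against. Deviance tolerance 1e-8 and iteration cap 100 for
all GLM fits; trade-off quadrant boundary tolerance 1e-9 on LA; all
generator streams derive from a single master seed via spawned
substreams, so adding boxes or cells never reshuffles earlier draws and
equal seeds give byte-identical CSV output.

## Limitations

- Fixed-effects only; genuinely hierarchical data (individual-level
  covariates within boxes) are collapsed to box aggregates.
- Per-exposure-time LC50 fits ignore interval censoring across censuses.
- LA/MA are computed from cell means; uncertainty in those means is not
  propagated into the indices (a bootstrap over boxes would be the natural
  extension).
- The logit link is the only dose–response link offered.
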