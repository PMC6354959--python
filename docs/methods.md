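# Methods

This note documents the statistical models implemented in `mrkit`, the
synthetic-data generator's assumptions, the numerical choices, and the
known limitations.  Notation: γ_j is variant j's per-allele association
with the exposure, Γ_j its association with the binary outcome on the
log-odds scale, β the causal effect of the exposure on the outcome
(log-odds per exposure unit).

## Estimators

**Genetic risk score.** score_i = Σ_j w_j g_ij / m with weights w_j taken
from the exposure discovery GWAS on its published scale, divided by the
variant count m, then standardized to mean 0, SD 1.  Missing dosages are
mean-imputed as 2·eaf (the behaviour of standard score-profiling tools).
Both the raw divided-by-m scale and the standardized scale are available;
all downstream estimation uses the standardized score.

**TSPS (forward, one-sample).**  Stage 1 regresses the exposure on the
instrument (score or single-variant dosage) plus covariates *among
controls only*: if the disease feeds back on the exposure, cases'
exposures are post-outcome, and restricting the first stage to controls
keeps the instrument–exposure association clean.  Fitted values are
predicted for all individuals and the disease is regressed on them by
logistic regression.  The reported SE is the stage-2 SE of the substituted
regressor; for a single instrument this equals the first-order
delta-method term √(Var(Γ̂))/|γ̂| of the ratio Γ̂/γ̂.  A second-order
option adds β̂²·Var(γ̂)/γ̂² (off by default; with first-stage F in the
hundreds the term is negligible).  A first-stage |t| < 2 raises a
weak-instrument error rather than returning an unstable ratio.

**Per-variant one-sample route.**  TSPS is run per instrument variant and
the estimates are pooled by DerSimonian–Laird random effects — the
heterogeneity across variants is real (pleiotropy), so a common-effect
pooling would be overprecise.  Weak variants are skipped and logged.

**TSLS (reverse).**  The binary disease becomes the exposure.  With the
`log-odds` coding the first stage is logistic and the fitted linear
predictor enters a linear second stage: the estimate is outcome change per
unit log-odds of disease, ×0.693 (= ln 2) for "per doubling of odds".
With `linear01` the first stage is a linear-probability model and the
estimate reads as the case-versus-control outcome difference attributable
to genetic liability.  The reverse first stage uses all individuals (no
control restriction: the exposure here *is* the case/control label).

**Two-sample estimators.**  Per-variant Wald ratios r_j = Γ_j/γ_j with
first-order SEs σ_Γj/|γ_j| (second-order optional everywhere, default
off).  IVW is the σ_Γ⁻²-weighted regression of Γ on γ through the origin,
algebraically identical to the fixed-effect meta-analysis of the Wald
ratios (a cross-module identity asserted in tests); its default SE is
fixed-effect, with a multiplicative random-effects inflation
max(1, √(Q/df)) behind a flag.  MR-Egger adds an intercept (average
directional pleiotropy) after orienting all γ_j ≥ 0; its SEs use the
conventional multiplicative scale floored at 1.  The weighted median
interpolates the ratio at standardized cumulative weight
s_j = (Σ_{i≤j} w_i − w_j/2)/Σw_i = 0.5.  The MBE maximizes a
σ⁻²-weighted normal-kernel density over the ratios with the modified
Silverman bandwidth 0.9·min(SD, 1.4826·MAD)·k^(−1/5) × a user bandwidth
factor (default 1.0).  Weighted-median and MBE SEs come from a parametric
bootstrap (resample γ_j, Γ_j from their SEs; default 1,000 replicates; a
seed is mandatory).  The MBE density argmax uses a 32,768-point grid for
point estimates and a 2,048-point grid inside the bootstrap; the point
grid is finer than the 1e-4 oracle scan the tests compare against.

**Meta-analysis and conversions.**  Fixed-effect inverse-variance pooling
with Cochran's Q and I² = max(0, (Q−df)/Q); DerSimonian–Laird
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)) for random effects, with REML available
behind a flag (direct bounded maximization of the restricted likelihood).
The small-study Egger test regresses β_i/se_i on 1/se_i by OLS with
t-distribution p-values.  Conversions: OR = exp(1.81·SD·SMD) and its
inverse (the 1.81 ≈ π/√3 logistic scaling factor; the SD multiplier is an
explicit argument, never hard-coded); per-SD → per-unit division by the
exposure SD (default constant 4.6 kg/m²); ×0.693 doubling-of-odds
rescaling.  SEs recovered from printed ORs assume log-symmetric 95% CIs:
se = (ln U − ln L)/3.92.  CI multiplier is fixed at 1.96 everywhere;
p-values are two-sided normal (t for the small-study test); rounding
happens only in the report layer.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, not any real
cohort:

    X_i = μ + Σ_j γ_j (g_ij − 2·maf_j) + κ_x U_i + ε_i
    P(Y_i = 1) = logistic(α₀ + β X_i + κ_y U_i + Σ_j α_j g_ij)

* g_ij ~ Binomial(2, maf_j), maf_j ~ U(0.05, 0.45), variants independent.
* γ_j have random signs and uniform 0.5–1.5× relative magnitudes, rescaled
  so the variant block explains exactly h² of Var(X).  Variable magnitudes
  are required for MR-Egger identifiability: after the non-negative
  orientation Egger applies, equal-magnitude effects collapse the design
  matrix [1, γ] to exact collinearity.
* U ~ N(0,1) is the shared confounder, kept in the cohort object for
  oracle checks only; Var(ε) is set so total Var(X) equals the target SD².
* α₀ is calibrated by bisection so the expected prevalence over the
  realized sample matches the target to 1e-4; an unreachable target raises
  an error naming the bound.
* Pleiotropic α_j ~ mean + sd·z; the directional mean acts in the
  direction of the exposure-raising allele (sign(γ_j)), which is what
  "directional" means after harmonization — a sign-agnostic constant mean
  would cancel out of both the IVW bias and the Egger intercept.  An
  InSIDE violation correlates z with γ_j (ρ = 0.7).
* RNG is `numpy.random.default_rng` (PCG64); identical config + seed gives
  bit-identical cohorts on any platform.

Defaults are the study conditions the package targets: 97 variants,
h² = 2.7%, exposure mean 27.4 and SD 4.8 kg/m², per-unit causal OR 1.09,
prevalence 5% (inside the 1.5%–5.8% range of the cohorts emulated, near
the upper end so simulated cohorts of 20,000 carry ~1,000 cases),
confounder effects κ_x = 1.5 kg/m² and κ_y = 0.3 log-odds per SD of U
(strong enough to visibly bias the observational logistic estimate while
leaving the IV analyses valid), and published-weight SEs computed at a
discovery-GWAS size of 322,154.  Covariate columns (age, sex, two
principal components, genotyping platform) are inert noise with realistic
marginals — they exist to exercise covariate plumbing, not to confound.

Per-variant summary statistics are derived from a cohort by closed-form
simple OLS (exposure side) and a batched 2-parameter Newton–Raphson
logistic solver (outcome side) that matches per-variant statsmodels fits
to 1e-6 but runs vectorized across ~100 variants.  The index-based
`split` partitions individuals into disjoint exposure/outcome subsamples
(split = 1 reuses the full sample, a one-sample mimic).  A separate
summary-level generator draws harmonized (γ, Γ) pairs directly under the
IV model for estimator-calibration studies, with outcome-side SEs sized
like a case/control GWAS and an option to plant a cluster of invalid
instruments as a ratio-scale offset.

In the recovery studies the exposure-side associations are the generator's
published-weight records (the external discovery-GWAS analogue), not
re-estimated from a half-split of the cohort: at h² = 2.7% over 97
variants a 10,000-sample first stage has per-variant F ≈ 3 and would add
~25% regression dilution that the emulated two-sample design (exposure
GWAS an order of magnitude larger than the outcome cohort) does not have.

**What passing tests do and do not show.**  The generator produces
independent biallelic variants, exact logistic disease risk, normal
confounding and homoscedastic exposure noise.  It does not emulate LD,
imputation uncertainty, array batch effects, assortative mating,
population stratification, selection into the cohort, or disease
misclassification — agreement on these simulations validates the
estimators' statistical machinery, not robustness to those real-data
features.

## Numerical and design choices

* Harmonization: outcome records are re-oriented by allele match, swap or
  strand flip; palindromic (A/T, C/G) variants are dropped when the
  exposure frequency is in [0.42, 0.58] (configurable; frequency cannot
  resolve the strand there) and otherwise oriented by frequency; missing
  outcome variants are replaced by a proxy with r² ≥ 0.8 from a
  user-supplied table, taking the proxy's association as published on its
  own effect allele (positive-phase convention).  All exclusions are
  logged with reasons.
* Logistic fits use Newton iterations to tolerance 1e-10 (the
  single-instrument TSPS/Wald identity holds to ~1e-12).
* The variance-heterogeneity check bins the score by quantiles and applies
  the Brown–Forsythe (median-centred Levene) test; bins with fewer than
  two observations raise an error suggesting fewer bins.
* Pipeline outputs are pure functions of (inputs, config, seed): JSON is
  written with sorted keys and no timestamps, and the manifest records
  package versions, the seed and SHA-256 hashes of all input files, so an
  identical rerun byte-reproduces the bundle.
* Monte-Carlo problem sizes: the recovery study uses 200 cohorts of
  20,000 (≈2 minutes); Egger calibration 500 summary-level replicates;
  robustness 100 replicates with outcome-side dimensions of a 34,772-
  sample, 38%-case GWAS, 30% invalid instruments with a ratio-scale offset
  of 0.3.

## Known limitations

* The logistic outcome model makes marginal per-variant and
  score-substitution effects slightly non-collapsible: estimators target
  an effect attenuated by ~3–4% relative to the conditional β at 5%
  prevalence.  This is a property of odds ratios, not an estimator defect;
  the recovery study's 5% tolerance absorbs it.
* Weighted-median and MBE parametric-bootstrap SEs are conservative when
  per-variant ratios are noisy (per-variant F small): their CIs over-cover
  (≈99–100% at nominal 95% under the default conditions).  The analytic-SE
  estimators (TSPS, IVW, Egger) are calibrated (94–96% observed).
* One-sample weak-instrument bias is guarded only by the |t| ≥ 2 first-
  stage rule; no Fieller or Anderson–Rubin intervals are provided.
* No LD-aware operations: instrument lists are assumed pruned to
  independence by their maker, and proxies come from a user file, never a
  remote lookup.
* Relatedness, survey weights and time-to-event outcomes are out of scope.
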