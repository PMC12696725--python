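# Methods

## Scope and data model

The package analyzes a split-brood rearing experiment: full-sib families
of a polyphagous butterfly divided across three host plants, with
individual development times and fresh masses, and stop-flow syringe
respirometry at up to three developmental stages (3rd instar, 4th
instar, pupa). Every quantity flows through tidy tables: a cohort table
with one row per (individual, stage) measurement, a V̇CO₂ table with one
row per processed session, and a merged metrics table carrying the
derived statistics.

## Trace processing

A session consists of a pre-injection reference segment (scrubbed
carrier air) followed by the injection bolus. Processing:

1. **Baseline.** A first-degree polynomial fitted to the reference
   segment (window = trace start to the injection marker by default; at
   least 5 samples required). A constant-mean option exists for traces
   without drift. The linear default absorbs analyzer drift exactly when
   drift is linear; residuals of this fit also estimate the noise SD
   used for bolus detection.
2. **Fraction and flow.** Baseline excess in ppm × 10⁻⁶ gives the CO₂
   air fraction; multiplied by the carrier flow (mL min⁻¹) and
   integrated over time (minutes, trapezoidal rule) it yields the CO₂
   volume that passed the analyzer.
3. **Bolus window.** Auto-detected as the contiguous region around the
   post-injection peak where excess exceeds k × noise-SD (k = 3,
   overridable), padded by 5 samples. On noiseless traces a tiny
   relative threshold (10⁻⁶ of the peak) is used so the full bolus is
   captured. An undetectable bolus in an animal session is a QC failure:
   the record is flagged `no_bolus_detected` and kept, never dropped.
4. **Rate.** The paired control's integral (over the same window) is
   subtracted first, then the difference is scaled by syringe/injected
   volume and divided by the incubation time. Negative corrected volumes
   are retained with a `negative_volume` flag — truncating at zero would
   bias low rates upward. No temperature or pressure standardization is
   applied (single-temperature protocol), and the animal's body volume
   is not subtracted from the syringe volume.

Numerical accuracy: with the default 1 s sampling and 10 s Gaussian
bolus, trapezoid error plus tail truncation keep the round-trip error of
a noiseless trace below 10⁻⁸ mL min⁻¹; the tests enforce 10⁻⁶.

## Derived statistics

- **Growth rate** = log(mass × 1000)/development time. The milligram
  conversion keeps the logarithm positive for sub-gram larvae. The log
  base is selectable (natural by default; base-10 available) because the
  convention is ambiguous in the field; the choice rescales the rate
  uniformly and cannot affect host comparisons.
- **Growth cost** = (development time / mass) × 24 × 60 × V̇CO₂, in mL
  CO₂ per g. The formula extrapolates the measured per-minute rate over
  the whole development; note that although it is sometimes glossed as a
  per-hour quantity, the expression as written yields a total volume per
  gram, and it is implemented exactly as written. Costs are computed
  per measurement row; host-effect models use the 4th-instar rows.

## Statistical models

- **Mass scaling.** ln(rate) ~ ln(mass) + host by OLS (= Gaussian ML),
  larval stages only. Host-specific slopes are assessed by a
  likelihood-ratio test against the interaction model (df = hosts − 1,
  χ² clamped at 0). Coefficients are reported back-transformed,
  a = exp(host intercept), under the documented convention rate in
  mL h⁻¹ at mass 1 g. Rates ≤ 0 (possible after control subtraction)
  are excluded from the log-scale fit and counted.
- **Mixed models.** Gaussian linear mixed models fitted by REML
  (statsmodels MixedLM), family random intercept; the metabolic-rate
  model adds an individual-within-family variance component for the
  repeated larval measurements. If the default optimizer fails to
  converge the fit is retried with derivative-free methods (Powell,
  then CG) before a non-convergence is reported; all optimizer warnings
  are kept on the fitted object. Fixed-effect LRTs, when wanted, go
  through an ML refit (`refit_ml`), since REML likelihoods of models
  with different fixed effects are not comparable.
- **Type-II Wald χ² tests.** For term T with higher-order relatives R
  and remaining terms O, the tested contrast is L β with
  L = [0_O, I_T, A_R], A = (X_Tᵀ M_O X_T)⁺ X_Tᵀ M_O X_R, M_O the
  projection complement of the O columns — the Wald analogue of
  SS(T | O): marginality-respecting, equal to the plain Wald test when T
  has no relatives, and equal to sequential tests in balanced orthogonal
  designs (verified against ANOVA sums of squares in the tests).
- **Contrasts.** Estimated marginal means average model predictions over
  the levels of the other factors with covariates at their means; all
  pairwise differences are tested with the studentized-range (Tukey)
  adjustment, k = number of levels, on the asymptotic (infinite-df)
  reference — consistent with the large-sample Wald χ² tests above and
  negligibly different from finite-df references at these sample sizes
  (n ≈ 300–450, ≥ 15 groups). At k = 2 the adjustment reduces exactly
  to the unadjusted z-test. When a fit interpolates the data (residual
  variance ≈ 0) both the differences and their SEs are rounding noise;
  such 0/0 contrasts are reported as exact ties (p = 1) instead of
  dividing noise by noise.

## Synthetic-data generator

The generator emulates the study conditions, not any particular real
cohort:

- **Design.** 15 families, per-(stage, host) replicate counts
  49/52/56 (3rd instar), 88/97/109 (4th instar), 18/21/29 (pupae) for
  Urtica/Salix/Ribes. The 4th-instar counts define each host's roster;
  families are assigned round-robin with the remainder by seeded
  shuffle, so every family appears on every host; 3rd-instar and pupal
  records are seeded subsets of the same individuals, giving the nested
  random effect real repeated measures.
- **Rates.** rate(mL h⁻¹) = a_host · mass^b · exp(family + residual),
  b = 0.84, a = 0.43/0.39/0.44 mL h⁻¹ at 1 g, family ~ N(0, 0.05²) and
  residual ~ N(0, 0.10²) on the log scale. The residual is drawn per
  measurement; persistent individual deviations beyond mass are not
  simulated, so the fitted individual-within-family variance is
  expected to be ≈ 0 on synthetic data.
- **Masses and times.** Lognormal; medians 0.045/0.16/0.30 g at 3rd
  instar/4th instar/pupa (σ_log 0.25, host-invariant — absolute masses
  are a free choice, as is making them host-independent), development
  times ordered Urtica < Salix < Ribes at every stage (4th-instar
  medians 12/13.3/16.5 d, σ_log 0.12). The 4th-instar medians were
  chosen so that the *median growth cost* is nearly equal on Urtica and
  Salix while Ribes is ≈ 40% more expensive — the qualitative pattern
  the analysis is meant to resolve. Within an individual, stages share
  lognormal quantiles, so mass and development time increase with
  stage.
- **Traces.** Baseline 5 ppm with 0.002 ppm s⁻¹ drift and 0.5 ppm
  Gaussian noise at 1 Hz; injection marker at 150 s; Gaussian bolus
  (width 10 s) whose excess area carries exactly
  (rate · incubation + ambient) · injected/syringe mL of CO₂ at
  100 mL min⁻¹ flow. The Gaussian shape is a modelling convenience —
  area-based processing is shape-agnostic, which the tests exploit. A
  small identical ambient CO₂ volume (0.01 mL) is placed in animal and
  control syringes alike so the control subtraction does real work; it
  cancels exactly. Animals are batched (8 per batch, within stage) and
  each batch gets one empty-syringe control, mirroring the protocol's
  one-control-per-run bookkeeping. 20 mL syringes, 7 mL injected for
  3rd instars, 10 mL for 4th instars and pupae, 60 min incubation.
- **Determinism.** One integer seed fans out through a SeedSequence
  spawn tree (cohort, then one child per session), so identical
  (config, seed) pairs give byte-identical studies and stages are
  independently reproducible.

What the generator does **not** emulate: real bolus shapes and analyzer
response kinetics, activity or stress metabolism, family effects on
development time or mass (the family intercept acts on the rate only),
sex effects, and host-dependent mass distributions. Passing tests
therefore demonstrate correctness of the calculation chain and the
statistical machinery under the stated stochastic structure — not that
the biology of any real cohort satisfies that structure.

## Simulation sizes and calibration checks

The parameter-recovery check uses one full default study (451 larval
measurements) through complete trace synthesis and processing. The
type-I-error and pattern checks run 200 and 50 replicated cohorts at
cohort level (latent rates stand in for processed ones): the
respirometry stage is separately proven to be an exact round trip, so
replicating it would add runtime without adding information. The
variance-recovery check uses 30 families × 20 observations with
residual SD 0.5 so the variance ratio is well identified; the Tukey
oracle uses 10⁵ Monte-Carlo range draws.

## Known limitations

- Wald χ² and Tukey p-values are asymptotic; with few families (15) and
  non-Gaussian responses they can be mildly anticonservative. The null
  calibration test quantifies this under the default conditions.
- The growth-cost model is Gaussian on the raw cost scale while the
  generator's cost is approximately lognormal; this mirrors the standard
  analysis choice and the mild misspecification is visible in the
  calibration test rather than hidden.
- Flow-through respirometry, O₂/RQ analysis, joule conversion and
  assimilation budgets are out of scope.
- The allometric coefficient's absolute scale is a convention
  (mL h⁻¹ at 1 g); comparisons across packages must match conventions
  before comparing coefficients.
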