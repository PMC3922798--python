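# Methods

`pmcalib` estimates *regression-calibration coefficients* for fine-particle
(PM2.5) exposure: the slope γ₁ obtained by regressing a "true" personal
exposure X on the error-prone surrogate Z that an epidemiologic study would
actually use. γ₁ = 1 means the surrogate introduces no multiplicative bias;
γ₁ < 1 means chronic health-effect estimates based on Z are attenuated
roughly in proportion. The package provides the full analysis chain —
exposure construction, hierarchical model fitting, heterogeneity testing,
meta-regression, cross-validation — together with a synthetic panel
generator with known ground truth, so every stage is testable without the
original (undeposited) field data.

## The analysis unit and exposure construction

The analysis unit is the **person-month**: subject j in city i contributes
monthly averages indexed k. Two definitions of the true exposure are
supported:

* **Total personal PM2.5** — the monthly mean of the subject's daily
  personal gravimetric measurements.
* **PM2.5 of ambient origin** — estimated by the *sulfate tracer*: because
  SO₄²⁻ has essentially no indoor sources and disperses like PM2.5, the
  personal/ambient sulfate ratio approximates the fraction of ambient PM2.5
  that infiltrates indoors and stays airborne, so
  X = (SO₄ᵖᵉʳˢ / SO₄ᵃᵐᵇ) × PM2.5ᵃᵐᵇ.
  The ratio is formed from monthly means of the daily sulfate values (more
  robust to low ambient-sulfate days than averaging daily ratios; the daily
  ratio variant is available via `ExposureConfig(tracer_daily_ratios=True)`),
  and the ambient PM2.5 factor is the nearest-monitor mean over the
  subject's sulfate sampling days. A time-weighted alternative
  (`ambient_origin_timeweighted`) covers panels that recorded home
  infiltration efficiency and time indoors instead of personal sulfate; it
  takes the infiltration efficiency as an input.

Two surrogates are attached to each person-month:

* **Nearest monitor** — the ambient monitor minimising haversine
  great-circle distance (sphere radius 3958.8 mi) to the residence, capped
  at 30 mi; monthly mean over *all* monitor days in the month by default.
  A sensitivity mode (`matched_days=True`) averages only the subject's
  sampling days, falling back day by day to the nearest monitor with data.
  Distance ties break by lexicographically smallest monitor id.
* **Outdoor-home model prediction** — a monthly predicted concentration at
  the residence, supplied as an input column (the package does not fit a
  spatio-temporal prediction model; the generator emulates predictions as
  ambient plus error).

Season is assigned from the calendar month (October–March winter,
April–September summer; the model codes winter = 1). Subjects younger than
18 are excluded. A person-month needs at least `min_days_per_month`
(default 1) sampled days.

## The calibration mixed models

All models are Gaussian linear mixed models fitted by REML (ML by flag):

* **Model 1 (pooled, heterogeneous):**
  X = (γ₀ + g₁ᵢ + g₂ᵢⱼ) + (γ₁ + g₃ᵢ)Z + γ₂·winter + ε, with independent
  g₁ᵢ ~ N(0, σ²city), g₂ᵢⱼ ~ N(0, σ²subject), g₃ᵢ ~ N(0, σ²CF-city),
  ε ~ N(0, σ²W).
* **Model 2:** Model 1 without the city random slope g₃ᵢ.
* **Model 3:** Model 1 plus city-level covariates and their Z-interactions
  (γ₃, γ₄) — meta-regression on city characteristics.
* **Model 4:** one city at a time, subject random intercepts only, giving
  the observed city-specific coefficient γ̂₁ᵢ.

Design choices worth knowing:

* The subject random intercept induces compound-symmetry (exchangeable)
  within-subject correlation; no separate residual correlation block is
  fitted, as it would be redundant with (and unidentifiable next to) the
  subject intercept.
* City random intercept and slope are independent (no covariance term),
  exactly as the model equations write two separate normal terms.
* Wald 95% CIs use normal quantiles; no Satterthwaite/Kenward-Roger
  degrees-of-freedom correction is applied. With ~10 cities this makes
  city-level inference mildly anticonservative (simulated coverage ≈ 0.91
  at the default study scale) — inherent to the normal-quantile choice,
  not to the implementation.
* Model 3 covariates are z-scored across cities by default
  (`standardize_covariates=False` gives per-raw-unit γ₄, needed to
  reproduce worked examples quoted on the raw scale).
* The test of H₀: γ₁ = 1 uses (γ̂₁ − 1)²/var(γ̂₁) ~ χ²₁.
* Effect modification (season; senior/COPD/MI/CHD subgroups) is tested via
  a Z×flag interaction at α = 0.05; when significant, stratified slopes are
  reported as linear combinations with delta-method CIs (the reference
  level's CI coincides with the main-effect CI by construction).

### Estimation

The fitter (`pmcalib.reml`) maximises the profiled REML criterion over log
variance ratios r_k = σ²_k/σ²_W; β and σ²_W are profiled analytically.
Every random effect is nested in a blocking factor (city; subject for
Model 4), so the marginal covariance is block diagonal, and the Woodbury
identity reduces each criterion evaluation to q×q solves per block
(q ≈ subjects per city + 2). This makes the ~1,500 refits of the
simulation studies run in minutes. Numerical details: L-BFGS-B on log
ratios bounded in [−30, 12], scale-aware starts (0.5/mean(column²)),
three jittered restarts on failure, a boundary-pinning polish for
components drifting to zero, and a Nelder-Mead fallback after line-search
failures. Convergence: criterion tolerance 1e-12, gradient 1e-7. A
component below 1e-8 × var(y) is reported as 0 with a boundary flag.
Degenerate layouts (a random intercept with one observation per group) are
flagged as non-identifiable against the residual. The REML criterion
includes the −½log|X′V⁻¹X| adjustment and all 2π constants, matching the
statsmodels MixedLM convention (verified to 1e-10 in the tests).

## Between-city heterogeneity, selection, cross-validation

H₀: σ²CF-city = 0 lies on the boundary of the parameter space, so the REML
LRT comparing Models 1 and 2 (identical fixed effects, so REML is valid) is
referred to a 50:50 mixture of χ²₀ and χ²₁: p = 0.5 exactly when the
variance estimate is 0 (or LRT = 0), else p = 0.5·P(χ²₁ > LRT). Negative
statistics within 5e-3 (optimiser noise) are treated as boundary; larger
deficits raise an error rather than being clamped.

When heterogeneity is detected, **forward step-wise selection** adds, at
each step, the candidate city covariate whose Z-interaction has the
smallest Wald p-value below α, then reports the residual heterogeneity
(mixture LRT of the random slope inside the final Model 3). Forward rather
than backward selection because with ≤ 9 cities a full candidate set is
rank deficient; candidates collinear across cities (|r| > 0.99) or constant
are dropped with a warning.

**Leave-one-city-out cross-validation** re-runs the selection on the
remaining I−1 cities (an assertion guarantees the held-out city never
enters training) and predicts the held-out coefficient as
γ̂₁ᵢ⁻ = γ̂₁₍₋ᵢ₎ + Σ_c γ̂₄c,₍₋ᵢ₎·v_ci (covariates transformed with
training-set statistics). Predictions are compared with the observed
Model-4 coefficients via Pearson correlation (Spearman by flag), the mean
relative bias mean[(γ̂₁ᵢ⁻ − γ̂₁ᵢ)/γ̂₁ᵢ], and the mean absolute value of the
same ratio. Cities whose Model-4 fit fails are excluded from the metrics
with the count disclosed. Forest plots weight city markers by inverse
variance.

## The synthetic panel generator

`simulate_panel` emulates a pooled multi-city validation panel: subjects
nested in cities, several months per subject spread across the year (so
both seasons appear), a block of consecutive sampling days per month, one
central monitor per city, monthly outdoor-home predictions, city
covariates (vehicles per housing unit, heating degree days in thousands,
residents per unit), ages uniform on [40, 90] (minors only via an explicit
flag, to exercise the exclusion filter), and binary comorbidity flags.

Two modes:

* **regression-truth** — surrogates are drawn first (city-month ambient
  field, flat within month) and the true monthly exposure is generated
  from the calibration model itself, so Model-1 estimates are directly
  comparable to the configured truth. The sulfate columns are constructed
  to make the tracer reproduce the generated ambient-origin exposure
  exactly, and total personal adds an independent non-ambient source term.
* **mechanistic** — each subject has an infiltration ratio drawn from a
  normal truncated to [0, 1.5] (stable within subject — infiltration is a
  home/behaviour property; shifted down by 0.11 in winter), ambient-origin
  exposure is ratio × ambient, monitors observe ambient plus daily
  instrument error, predictions add model error. The truth record stores
  the implied attenuation slope E[r]·var(A)/(var(A) + σ²mon/30).

Defaults are fixed at the pooled-study scale: ambient field 15.9 ± 5.0
µg/m³, sulfate ratio 0.64 ± 0.25, non-ambient personal sources 15 ± 8
µg/m³, γ₀ = 5, γ₁ = 0.54, winter effect −1.5 µg/m³, σcity = 1,
σsubject = 2, σCF-city = 0.1 (between the homogeneous and clearly
heterogeneous surrogate regimes), σW = 3; 9 cities × 30 subjects × 6
months × 7 days. Generated personal concentrations are floored at zero
(gravimetric values cannot be negative in the stored records); at the
defaults ~0.1–1% of person-months are floored, attenuating γ̂₁ by less
than 0.005 — visible as a tiny negative bias in the recovery simulations
but well inside their tolerance.

What the generator does **not** emulate: spatial covariance structure of
the prediction model's errors, multiple monitors per city, missing-data
patterns of real networks, day-to-day within-month exposure dynamics
(day-level and instrument noise are folded into σW), or ETS exposure.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative assumptions, not robustness to every
feature of real field data.

## Simulation studies wired into the test suite

Problem sizes were chosen to give small Monte-Carlo error while keeping the
full suite in the tens of minutes:

* Parameter recovery and CI coverage: 400 panels at 10 × 30 × 6 with
  γ₁ = 0.54 (mean γ̂₁ within 0.02 of truth; coverage in [0.90, 0.99]).
* Test calibration: 500 panels from the joint null world (γ₁ = 1 and
  σ²CF-city = 0 in the same replicates) — the configuration in which both
  tested hypotheses hold simultaneously — checking that the Wald test and
  the mixture LRT both reject at rates in [0.03, 0.08] at α = 0.05, and
  that the naive χ²₁ LRT is directionally conservative relative to the
  mixture version.
* Tracer physics: one large mechanistic panel with constant ratio and
  noise-free monitors (slope → ratio within 0.02).

## Known limitations

* No AR(1)/heteroscedastic residual options, crossed random effects or
  intercept–slope covariance; no Bayesian fitting.
* Normal-quantile Wald inference (see above): city-level CIs are slightly
  narrow with few cities.
* LOOCV relative-bias metrics are unstable when an observed city
  coefficient is near zero (such cities can dominate the absolute bias).
* Calibration coefficients estimated here characterise surrogate error;
  they are not intended as direct multiplicative corrections to published
  health-effect estimates.
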