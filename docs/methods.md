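# Methods

This note documents the models, the data-generating process behind the
scenario simulator, the numerical choices, and the known limitations of the
package.

## Estimand and reporting scale

The target throughout is the average causal risk difference
β = E[Y₁(1)] − E[Y₁(0)] for a binary treatment X and binary study-period
outcome Y₁.  Every estimator reports on this scale via an average marginal
effect (AME): the mean difference of model-predicted event probabilities
with the treatment term toggled to 1 and 0 while all other covariates stay
at their observed values.  The risk difference is collapsible, so estimates
from methods with different adjustment sets target the same quantity and can
be compared directly — an odds ratio would not allow this.

AME standard errors use the delta method through the final-stage coefficient
covariance (inverse observed information).  The estimation noise of the
first-stage treatment model in the IV-type estimators is deliberately *not*
propagated; this mirrors the common two-stage-plus-margins workflow, and on
the default designs the resulting SEs agree with patient-level bootstrap SEs
to within a few percent (tested at 15% tolerance).  When first-stage noise
matters — weak instruments — the bootstrap covariance in the triangulation
module is the appropriate alternative and is used for all dissimilarity
testing anyway.

## The estimators

* **CaT** — logistic Y₁ ~ X + W₁ (+ Z, + Y₀ on request); AME of X.  The
  instrument is added as a covariate whenever it directly affects the
  outcome (then it is simply a measured confounder), and the prior outcome
  is added whenever it directly affects Y₁.
* **PSM** — logistic propensity X ~ W₁ (+ Y₀); greedy 1–1 nearest-neighbour
  matching on the score without replacement, treated patients processed in a
  seeded random order, distance ties broken by lowest patient id, no caliper
  unless requested; then the CaT fit on the matched subset.  Diagnostics
  carry the matched fraction and standardized mean differences before/after
  matching.  Zero-variance covariates are dropped from the propensity model
  rather than crashing the design matrix.
* **IV** — stage 1: logistic X ~ Z + W₁; stage 2 (logistic by default,
  linear optional): Y₁ ~ X̂ + W₁ with X̂ the predicted treatment
  probability; the estimate is the AME of moving X̂ from 0 to 1.  With no
  covariates and a linear second stage this reduces exactly to the Wald
  ratio of outcome and treatment differences across instrument levels
  (tested to 10⁻⁹).
* **CF** — stage 1 as IV; the residual Δ̂ = X − X̂ and its interaction Δ̂·Z
  enter the logistic outcome model alongside X and W₁; AME of X.
* **DiD** — one logistic regression on the 2n-row period stack
  Y* ~ P* + X* + P*·X* + W* + W*·P* (+ Z + Z·P* on request).  Rows are
  treated as independent in fitting; bootstrap resampling is by patient.
  The reported effect is the *difference in AMEs*: the study-period
  treatment contrast of average predicted probabilities minus the
  prior-period contrast, each patient evaluated at their period-appropriate
  confounder value.  With a linear family and no covariates this equals the
  classical four-group-mean formula exactly; for the logistic family the
  interaction coefficient alone is not a risk difference, which is why the
  contrast form is used.
* **POA-IV / POA-CF** — stage 1: logistic X ~ Z + W₁ + Y₀ + Y₀·Z, with the
  interaction acting as the instrument; stage 2 controls Z and Y₀
  explicitly (Y₁ ~ X̂ + W₁ + Z + Y₀, or the CF form with Δ̂ and Δ̂·Z).
  Because Z and Y₀ are controlled, validity only needs the interaction to be
  relevant and Y₀ itself to be unconfounded — not the exclusion restriction
  and not the no-prior-outcome-effect condition of DiD.

Instrument strength is summarized as the squared Wald z of the instrument's
first-stage coefficient (a single-instrument F); values below 10 trigger a
`WeakInstrumentWarning`, never a hard error.

## Dissimilarity statistic

For a set *e* of estimates, Q_e = (β̂ − β̂_IVW)ᵀ Σ̂⁻¹ (β̂ − β̂_IVW) with the
inverse-variance weights taken from the diagonal of Σ̂ so that the pool and
the quadratic form use one internally consistent covariance.  Σ̂ is the
empirical covariance of the estimate vector over B non-parametric bootstrap
resamples (patients redrawn with replacement; a cluster bootstrap that
redraws whole providers is available because the instrument is
cluster-constant, but the patient bootstrap is the default and is what the
rejection-rate studies use).  Under the null of one common target, Q_e is
referred to χ² with |e|−1 degrees of freedom; no small-sample correction is
applied.  Resamples on which any method fails to converge are dropped and
counted (more than 10% is an error).  A covariance with condition number
above 10¹⁰ is an error — near-duplicate methods (e.g. the same estimator
twice) make Q_e numerically meaningless and silently pseudo-inverting would
hide that.

## The simulator

Each simulated cohort has n patients in n_g equal clusters (defaults 5000
and 50, emulating a primary-care cohort nested in providers).  Generation
order: cluster-level instrument Z ~ Bernoulli(0.5); per patient U ~ N(0,1)
(unmeasured), W₀ ~ N(0,1), W₁ = ρW₀ + √(1−ρ²)·noise with ρ = 0.5; prior
outcome Y₀ from a probability-scale model; treatment X from a logistic
model; both potential study outcomes Y₁(0), Y₁(1) from a probability-scale
model with the additive effect β, coupled through a single uniform draw per
patient, and Y₁ = Y₁(X).  Outcome models are specified on the probability
scale precisely so that the true estimand *is* the configured β; all
probabilities are clamped into [ε, 1−ε] with ε = 0.01, and a scenario whose
coefficients clamp more than 1% of patients raises a calibration error
rather than silently distorting the estimand.

Six structural switches map the named scenarios: unmeasured confounding
(U→X and U→Y₁), prior-outcome-driven treatment (Y₀→X), a direct instrument
effect on the outcome (Z→Y₁), a direct prior-outcome effect (Y₀→Y₁),
confounding of the prior outcome (U→Y₀), and the preference-by-prior-outcome
interaction (Y₀·Z→X).  In the base scenarios with unmeasured confounding the
U→Y₀ path is active with the same coefficient as U→Y₁, so the confounding is
time-constant and differencing it out remains valid; in the first two POA
scenarios the prior outcome is deliberately left unconfounded, which is the
condition the augmented estimators need.

### Default coefficients — calibrated, not transcribed

The exact coefficient values behind the published scenario grid are not
available to this package, so the defaults here are *calibrated*: chosen
once so that (i) outcome prevalence stays rare-ish (≈ 12% baseline, ≈ 17%
in the treated study period) while keeping probability clamping below 0.5%
of patients, (ii) the preference instrument is strong (first-stage F ≈ 300
at n = 5000) and the interaction instrument clearly relevant (F ≈ 100), and
(iii) the qualitative estimator-by-scenario failure pattern is reproduced
with the published magnitudes' sign and order: DiD bias ≈ −0.19 under
prior-outcome-driven treatment, IV/CF bias ≈ +0.14 under exclusion
violation, CaT bias ≈ +0.03 under unmeasured confounding.  Cell-level bias
magnitudes therefore match published tables in sign and pattern, not digit
by digit.

One calibration detail is worth recording: with a strongly positive Y₀→X
effect the treatment probability for prior-event patients sits near the top
of the logistic curve, so a *positive* Y₀·Z coefficient adds almost no
probability-scale variation and leaves the interaction instrument weak.
The default interaction is therefore negative (−3.0): provider preference
expresses itself for patients without a prior event and is suppressed for
patients with one.  This keeps the overall Y₀–X association positive (so
the DiD failure keeps its negative sign) while giving the interaction
instrument real leverage.

### What the simulator does not emulate

Equal cluster sizes and no provider random effect beyond the shared Z;
homogeneous treatment effects; a single confounder per period; no
time-to-event structure, censoring, measurement error or missingness.
Passing tests show the estimators behave as the theory predicts under this
clean design — not that they are robust to the messier failure modes of
real records.

## Monte-Carlo studies

Replicate seeds derive from a master seed through a counter scheme
(`SeedSequence([master, index])`, truncated below 2³¹), so every replicate
is individually reproducible and independent.  Performance cells report
bias, empirical SE, MSE, 95%-CI coverage and the rejection rate of the
zero-effect test, each with its Monte-Carlo standard error (empSE/√R,
empSE/√(2(R−1)), SD(squared errors)/√R, and √(p(1−p)/R) respectively); the
rejection rate is a type-1 error only for runs re-simulated at β = 0, which
is how the null studies are executed (fresh draws, not reused ones).
Scenario-appropriate adjustment sets are applied automatically (Z into the
CaT and DiD models when the exclusion restriction is broken; Y₀ into the
single-period outcome models when it directly affects Y₁); a strict mode
disables this for ablation.  Coverage is assessed against the configured β:
with clamping held under 1% the truncation-induced gap between β and the
realized average potential-outcome difference is below 10⁻³, an order of
magnitude inside Monte-Carlo noise at the replicate counts used.

Problem sizes in the shipped checks are chosen to keep the full suite fast
while leaving Monte-Carlo error well inside the assertion bands: 500
replicates at n = 5000 for the bias-pattern and coverage grids, 250–300 for
single-cell coverage targets, and 100 runs × 200 bootstrap resamples at
n = 2000 for the dissimilarity rejection-rate studies.

## Preference instrument construction

From longitudinal prescribing records (provider, within-provider order,
treatment), each patient's instrument is the treatment the same provider
chose for their *previous* patient; the provider's first patient has no
history and is excluded.  A window option generalizes this to the majority
of the last w prescriptions (ties to 1); the default w = 1 is the
most-recent-prescription rule.

## Known limitations

* The logistic second stage of the IV-type estimators enters X̂ as a
  continuous regressor; the 0→1 AME is exactly the risk difference only in
  the linear case, and small non-collapsibility bias (≈ 0.2–0.3 percentage
  points at the default design, inside Monte-Carlo noise of the shipped
  checks) is visible for the logistic default.
* Delta-method DiD standard errors treat the two rows of a patient as
  independent; under the POA designs (strong prior-outcome effects on
  treatment) they can undershoot the empirical SE, though coverage of the
  DiD estimator is not a design goal in exactly those scenarios.
* Q_e relies on the asymptotic χ² reference; with few bootstrap replicates
  the covariance noise inflates the null rejection rate slightly above the
  nominal level.
* Multi-set hierarchical testing with family-wise error control is out of
  scope, as are time-to-event outcomes and effect heterogeneity.
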