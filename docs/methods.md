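# Methods

## KDM biological age

The estimator combines `m = 7` clinical-chemistry markers (albumin, alkaline
phosphatase, serum creatinine, C-reactive protein, HbA1c, systolic blood
pressure, total cholesterol) with chronological age.  Two estimation
directions circulate for the per-marker lines.  We regress each **marker on
age** (`x_j = q_j + k_j·age`, `s_j` = residual RMSE in marker units): this is
the only direction under which the scoring equation is dimensionally
consistent (each term of the numerator has units yr⁻¹, of the denominator
yr⁻²) and under which a person lying exactly on every line scores
`BA_EC = CA` — an identity the test-suite enforces to 1e-10 years.  The
alternative wording ("age regressed on marker") breaks both properties.

`s_BA²` is estimated as the empirical variance of `BA_E − CA` over the
reference cohort, where `BA_E` omits the CA anchor; a configuration override
accepts a fixed value instead.  For the independent-noise generative model
the analytic value is `1/Σ(k_j/s_j)²`, which the empirical estimate matches
closely and which the parameter-recovery tests use as the generative truth.

Numerical choices: a cohort with (near-)zero marker noise yields `s_j = 0`
and `s_BA² = 0`, outside the estimator's domain; the fit floors both at 1e-8
so that slope/intercept recovery on noiseless cohorts still produces a
scorable parameter set.  Constant markers raise an error naming the marker;
missing markers refuse to score (no imputation).  CRP is scored on the raw
scale by default with an optional natural-log flag — the transformation is
exposed, never silent.  Scores are invariant to positive rescaling of any
marker (refit included) to 1e-8, and `BA_EC` is strictly increasing in any
marker with positive slope.

Weight adjustment regresses follow-up biological age on the change in body
weight by OLS and returns residual + cohort mean: "follow-up biological age
assuming no change in weight".  The variant operating on the change in
biological age is available through `mode="change"`.  A constant
weight-change vector leaves the regression undefined and raises.

Responder classification: non-responder (flag 1) iff follow-up `BA_EC`
strictly exceeds baseline; exact ties count as responders, reading "increased"
strictly.

## Gompertz proportional-hazard survival

Per-record log-likelihood under right censoring:
`δ(log λ + γt) − λ(e^{γt} − 1)/γ`, with `(e^{γt} − 1)/γ` evaluated via
`expm1` and the `λt` limit taken for |γ| < 1e-12.  Maximisation uses BFGS
with the analytic score, restarting from γ ∈ {0.05, 0.2, 0.01} on
non-convergence and polishing with Nelder–Mead as a last resort; standard
errors come from the inverse observed information (numerical Hessian).  The
parametrisation agrees with `scipy.stats.gompertz` under `c = λ/γ`,
`scale = 1/γ`, which the tests use as an independent check of both the
survival algebra and the event-time sampler.

Median remaining life expectancy is solved numerically (Brent on
`s(t) − 0.5`, bracket doubled from twice the closed-form value) and
cross-checked against `t = ln(1 − (γ/λ)ln½)/γ` to 1e-8 years on randomized
parameter grids.  For γ < 0 survival plateaus at `exp(λ/γ)`; when the plateau
exceeds 0.5 no median exists and the solver raises.  Predicted median age at
death is chronological age plus the solved t.

Competing risks are implemented as cause-specific hazards — deaths from other
causes censored — because that reuses the same likelihood machinery the
all-cause model employs; no subdistribution (Fine–Gray) modelling is
attempted.  Time origin is the baseline examination with age, biological age
and (optionally) weight as fixed covariates; "assuming no change in weight"
scenarios put baseline weight in both the baseline and post-intervention
hazard.

Cause-specific fits need enough events to be stable: with few events the
biological-age coefficient can come out sign-flipped by sampling noise, so
pipeline risk tables for rare causes should be read with their event counts
in mind (the all-cause row is the robust summary at the problem sizes the
default configuration uses).

## Lifecourse simulation of annual FMD

Within a year: point A (start), point C after three diet cycles, point D
after the rebound, with the two linear response surfaces given in the README.
"Age" enters both surfaces as the age at point A; next year's A-state is this
year's D-state and chronological age advances by one.  Composing the two
surfaces gives the affine map `B' = aB + bA + c` with `a = 0.57710752`,
`b = 0.28757816`, `c = 0.81116136`; the iterative engine is required to match
this closed form to 1e-10 at every year, and the stabilised annual increment
equals `b/(1−a) ≈ 0.6800` years per year from any starting state.  Because
`a < 1` the map is contracting: the early decline is steep and the trajectory
then tracks a line of slope 0.68 — meaning biological age rises 0.32
years/year more slowly than chronological age under sustained annual use.

Coefficient standard errors are not published, so the default simulation is
deterministic (all SEs 0); supplying SEs redraws all seven coefficients
normally per Monte-Carlo draw.  Survey-weighted aggregation selects
`k = round(weight/548.5)` of the available draws (round half away from zero;
clamped to ≥ 1 so every person contributes) uniformly without replacement and
averages them; requesting more draws than simulated raises, and the
population-level runner caps k at the configured draw count so scaled-down
runs remain valid.

The effect-decay sensitivity rule is stated as "divide by 2 multiplied by
years since baseline" with worked examples of one half and one quarter in
years 2 and 3.  The literal formula gives 1/(2y) — 1/2, 1/4, 1/6, … — while
the examples also admit halving each year — 1/2, 1/4, 1/8, ….  The two
coincide exactly where examples exist and diverge from year 3; both are
implemented (`linear`, the literal reading, is the default) rather than
guessing silently.  Decay applies to both within-year changes by default,
configurable to the cycle change only.  Under either decay mode the late
trajectory freezes while chronological age keeps advancing — a model
artifact of the vanishing effect, flagged here deliberately.

Mortality during the simulation is ignored by design; trajectories run to
the horizon age (default 70) regardless of survival probability.

## Synthetic data

The reference generator emulates a national-survey population: ages uniform
on 30–90 (the simplest structure satisfying the linear-in-age assumption),
markers linear in age with independent Gaussian noise at clinically plausible
intercepts/slopes/spreads, body weight normal, survey sampling weights
log-normal clipped so the 548.5-divisor rounding spans roughly 6–1000, and
Gompertz event times (closed-form inversion of the survival function, KS-
tested against the analytic law at n = 10,000) censored at a 23-year horizon.
Cause codes are drawn from a configurable multinomial at event time.  An
optional per-person latent aging deviation (`bioage_sd`) shifts all markers
coherently; it defaults to 0 so the zero-noise limit puts every marker
exactly on its line.  A separate survival-record simulator draws biological
age as age + N(0, 5 yr) so the age and biological-age coefficients are
separately identified for parameter-recovery checks.

What the generator does **not** emulate: real marker marginals or their joint
covariance, missing data, measurement batch effects, or informative
censoring.  Passing tests therefore demonstrate correctness of the estimators
under the stated generative assumptions, not robustness to real survey data.

The trial generator produces paired baseline/follow-up panels with configured
signed marker shifts, re-draw noise scaled to 0.3 of the cross-sectional
marker noise (within-person short-term variation is smaller than
between-person spread), normal weight change defaulting to −1.5 ± 1.5 kg
(modest diet-induced loss), and a seeded non-responder fraction whose shifts
are sign-flipped.  The default arm size of 52 matches the cohort size the
trial statistics are sized to.

## Trial statistics

The paired pre/post change analysis uses the Wilcoxon signed-rank test on
per-person differences (the design is paired; a two-sample rank-sum variant
is provided for completeness).  Zeros are dropped.  For n ≤ 12 the null is
enumerated exactly over all 2ⁿ sign patterns using midranks, which remains
valid under ties; above that an Edgeworth-corrected normal approximation is
used — the null is symmetric, so the leading correction is the fourth-cumulant
term (κ₄ = −Σrᵢ⁴/8) applied with a continuity correction, which keeps the
approximate p within about 1e-3 of the exact enumeration already at the
crossover n.

Biweight midcorrelation follows the standard definition: median-centred,
9×MAD-scaled observations weighted by (1−u²)² inside |u| < 1 and zero
outside; p-values use the t-approximation with n−2 degrees of freedom
(permutation p is not implemented; the t form is what the reported analyses
use).  Zero MAD raises unless a Pearson fallback is explicitly requested.

Responder logistic regression is maximum likelihood via statsmodels (IRLS);
perfect or quasi-separation is detected (non-finite standard errors or
|coefficient| > 50) and raised with the offending covariate named.  Type-I
error calibration is verified at the 5% nominal level over 200 seeded
replicates.

HOMA-IR is glucose·insulin/405 (mg/dL × µU/mL).  The lymphoid-to-myeloid
ratio defaults to lymphocytes/(neutrophils+monocytes); eosinophils and
basophils can be added to the denominator since the ratio's exact components
are not standardised.

## Problem sizes and reproducibility

Default verification sizes — 5,000-person reference cohorts for KDM recovery,
20,000 records for Gompertz recovery, 1,000 identity configurations, 100
solver cross-checks, 200 logistic replicates, 25–1,000 simulation draws —
were chosen so each check's sampling error sits well inside its assertion
band.  Every stochastic routine takes an explicit seed; the pipeline derives
per-stage child seeds from one master seed via `SeedSequence`, and
deterministic modes (zero coefficient SEs) are verified to be seed-
independent.  Pipeline outputs carry seed and configuration-hash sidecars and
are byte-identical across reruns.

## Known limitations

- Absolute life-expectancy and risk levels depend on the synthetic cohort's
  generative mortality parameters, not on any fitted national reference, so
  only relative statements transfer.
- The published stabilized simulation increment (0.85 yr/yr) is not
  derivable from the published response-surface coefficients, whose fixed
  point is ≈ 0.68 yr/yr; the package reports the coefficient-implied value
  and makes no attempt to force agreement (unpublished coefficient
  uncertainty, weighting and figure-level summarisation are plausible
  sources of the difference).
- Marker noises are independent by default; real panels are correlated.
- No missing-data handling: scoring refuses incomplete panels.
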