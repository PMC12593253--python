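# Methods

`igsense` implements, end to end, an analysis that asks whether infants'
sensitivity to the *information gain* of visual events predicts their later
cognitive outcomes. Because the participant data of such studies are
typically under restricted access, the package pairs every analysis stage
with a synthetic-data generator that reproduces the statistical structure
the analysis assumes, so the whole pipeline is testable by parameter
recovery.

## Task model

The experiment is a probabilistic cue–target task: 16 sequences of 15
trials, each trial ending with a stimulus appearing in one of four screen
quadrants (A–D). Within a sequence one quadrant is modal, realized at a
100%, 80% or 60% predictability level (4, 6 and 6 sequences respectively).
Predictability is implemented as an **exact proportion** — exactly 15, 12
or 9 modal trials per sequence — rather than i.i.d. sampling, because the
design frequencies are realized quantities. Deviant trials sit at uniform
random positions (no positional exemption) and land uniformly on the three
non-modal quadrants. The sequence order is rejection-sampled until no two
consecutive sequences share a modal location (cap 10,000 retries, then a
constraint error); rejection sampling is unbiased over feasible orders.
Each of eight stimuli is assigned to exactly two sequences at random.
Trial-phase durations (cue 1000 ms, ISI 750 ms, target 1500 ms, ITI
750 ms) are carried as metadata only.

## Ideal learner

The learner holds a Dirichlet-categorical belief over target locations
with symmetric prior pseudo-count α (default 1, Laplace add-one — this
value exactly reproduces the canonical 25% → 40%/20% single-observation
example). Per trial it reports, in nats:

- **information gain**: D_KL(posterior predictive ‖ prior predictive), the
  movement of beliefs caused by the observation. The direction
  (posterior‖prior) encodes "how much the event changes prior beliefs";
- **surprise**: −ln p(observed) under the pre-update predictive;
- **predictability**: negentropy ln 4 − H(predictive) of the pre-update
  belief. The negentropy form is an explicit modelling choice; the
  literature this task descends from does not print a formula.

Beliefs reset at each sequence boundary, with no forgetting within a
sequence and no carry-over between the two presentations of a stimulus.
All three metrics for trial *t* depend only on trials 1..*t* (online
causality), which the tests assert via a prefix property.

## Synthetic cohorts

`simulate_infants` draws per-infant parameters from independent normal
population distributions. Defaults encode the study conditions the
pipeline is meant to operate under:

| parameter | mean (SD) | notes |
|---|---|---|
| baseline looking time | 900 (120) ms | mid-window looking at average predictors |
| sensitivity to IG | 66 (40) ms/SD | population effect at the group-analysis scale |
| surprise effect | −18 (10) ms/SD | small negative, as in group analyses |
| predictability effect | −58 (15) ms/SD | longer looking at unpredictable sequences |
| trial effect | −8 (4) ms/trial | within-sequence decline |
| residual SD | 250 (40) ms | trial-level noise |
| saccade base latency | 400 (60) ms | predictable-trial latency |
| predictability advantage | 180 (40) ms | slow-down on unpredictable trials |
| look-away intercept | −2.2 (0.4) logit | ≈10%/trial hazard → ≈8 trials/sequence |
| look-away IG coefficient | 0.5 (0.2) | higher IG retains attention |
| continue logit | 1.95 (0.6) | ≈0.875/sequence → ≈7 sequences watched |

Looking time is a linear function of z-scored information gain, surprise,
predictability and trial index plus Gaussian noise, clipped to the
[0, 1500] ms target window (a censored-Gaussian view of the same process
is available by disabling clipping). Look-away is a per-trial Bernoulli in
the IG z-score — a trial-granular simplification of the continuous 1-s
criterion — and truncates the remainder of the sequence; an experiment
-level continuation probability produces realistic attrition in watched
sequences. A 90-infant default cohort with ~22% unusable eye-tracking and
~14% follow-up dropout yields ≈60 analyzable children.

IQ outcomes derive from the *standardized true* sensitivity slope z
through a configurable link f — linear (a·z), exponential (b·exp z,
default b = 3.75) or thresholded — plus an SES term and noise:
FSIQ = 99.8 + f(z) + 2·(SES − 3) + N(0, 9²), calibrated so the default
exponential link gives FSIQ ≈ N(106, 12.6). SES is the mean education
level (1–4) of two caregivers drawn from a distribution with ~94% of
households having at least one higher-educated caregiver. The three
subindices share the curiosity signal with loadings (1.0, 0.7, 0.6),
index means (106, 103, 109) and correlated noise (VCI–VSI 0.4, VCI–WMI
0.5, VSI–WMI 0.2), giving the positive verbal-comprehension correlations
seen in such batteries.

What the generator does **not** emulate: fussiness dynamics, calibration
loss, gaze-stream artefacts, age effects, or any dependence of look-away
on surprise/predictability. Passing recovery tests therefore show that
the pipeline is consistent — it recovers what this generator plants —
not that real looking times obey the linear-Gaussian form.

## Hierarchical sensitivity model

For infant *i*, trial *j*:

y_ij = β₀ + β_IG·zIG_ij + β_S·zS_ij + β_P·zP_ij + β_T·trial_ij
&nbsp;&nbsp;&nbsp;&nbsp;&nbsp;&nbsp; + u₀ᵢ + u₁ᵢ·zIG_ij + ε_ij,
ε ~ N(0, σ²), u₀ ~ N(0, τ₀²), u₁ ~ N(0, τ₁²).

Random effects are intercept + IG slope only; surprise and predictability
act at the population level. Priors are weakly informative for a 0–1500 ms
response: N(0, 500²) on coefficients, half-N(0, 300²) on σ, τ₀, τ₁ (all
scales configurable). The likelihood is Gaussian by default; setting
`censor_at=1500` treats window-pinned trials as right-censored via
truncated-normal data augmentation.

Sampling is blocked Gibbs designed to avoid the two classic pathologies
of hierarchical Gaussian models: the fixed-effect block is drawn with the
random effects **integrated out** (Woodbury identities per infant), and
the three SDs are slice-sampled on the log scale against the same
collapsed likelihood, removing the funnel coupling between u and τ.
Random effects are then drawn from their exact 2×2 Gaussian conditionals,
vectorized across infants. Four chains of 300 warmup + 700 kept draws run
in a few seconds on one CPU at the study scale and give min ESS well
above 400 and split-Rhat below 1.01 (computed with ArviZ over the fixed
effects, SDs and per-infant slopes; the `divergences` field is kept for
interface parity and is always 0 — Gibbs has no divergence notion).
Non-convergence produces a `ConvergenceWarning` and a flagged
diagnostics object, never a silent result.

The per-infant *sensitivity to information* is the posterior mean of
β_IG + u₁ᵢ (posterior mean chosen over median/MAP for its shrinkage
optimality under squared loss), standardized across infants to mean 0,
SD 1 (population SD convention).

## Outcome analyses

- **Outlier screen**: one-pass rule removing infants more than k (default
  3) sample SDs from the mean sensitivity; mean/SD computed once on the
  full input, so the rule is order-invariant and non-iterative.
- **Group-level mixed models** (statsmodels MixedLM, REML): looking time
  on zIG + zSurprise + zPredictability + saccadic latency + trial with a
  per-infant random intercept; saccadic latency on trial type
  (predictable/unpredictable) + trial with a random intercept. t-tests
  use residual-style df (n − k − groups + 1); with thousands of trials
  the df convention is immaterial to inference, so the heavier
  Satterthwaite computation was not reimplemented.
- **Additive model**: FSIQ ~ s(sensitivity) + SES. The smooth is a cubic
  P-spline (k = 10 basis functions, uniform extended knots, second-order
  difference penalty, sum-to-zero constraint absorbed by a QR null-space
  reparametrization). The smoothing parameter maximizes the exact
  restricted likelihood: after a Demmler–Reinsch split of the smooth into
  its unpenalized (linear) direction and i.i.d. random directions, σ² is
  profiled out and a one-dimensional criterion is optimized over the
  variance ratio. Reported: approximate F test of the smooth against the
  covariates-only model on edf-scaled df, edf (trace of the influence
  matrix), Bayesian-covariance t tests for parametric terms, adjusted R²
  and a Gaussian AIC on n log(2πRSS/n) + n + 2(edf+1) (computed
  identically for the linear model so the comparison is meaningful).
  Simulation at n = 60 puts the smooth test's type-I error near 7% at
  nominal 5% and its power against the default exponential link near
  100%. If the response lies numerically in the fixed-effect span
  (noise-free data) the smooth is penalized down to its linear null
  space (edf → 1). Bases auto-shrink with a warning when the covariate
  has fewer unique values than basis functions.
- **Exponential model**: FSIQ ~ intercept + b·exp(z) + SES by least
  squares — linear in parameters; standardization of z is enforced to
  keep exp bounded.
- **Tertile stratification**: rank-based Low/Medium/High split with sizes
  differing by at most one (remainder 2 → outer groups, giving 20/19/20
  at n = 59; remainder 1 → middle group; ties broken by stable input
  order), then the additive model within each group.
- **Partial adjusted R²**: two-term hierarchical partitioning — each
  term's incremental adjusted R² averaged over both entry orders; the
  shares sum exactly to the full model's adjusted R².
- **Subindex models**: the additive model per VCI/VSI/WMI; exploratory,
  no multiplicity correction (flagged in output metadata).

The author-written additive model is cross-checked in the test suite
against R `mgcv` (REML, `bs="ps"`) on a fixed dataset: edf within 1,
adjusted R² within 0.05, AIC within 3.

## Problem sizes and numerical choices

Recovery tests use 60-infant cohorts on the complete 240-trial design
(the size at which per-infant slopes are identifiable; r(truth, posterior
mean) ≈ 0.85) with 2 chains × (200 + 400) draws, and 20–30-infant
truncated cohorts for the qualitative properties (shrinkage, null
coverage). Calibration simulations use 200 null and 50 alternative
replicates at n = 60. Recovery simulations for the latency model generate
a homogeneous 180 ms effect because that model estimates a shared fixed
effect (no trial-type random slope); heterogeneous generation would make
its nominal interval target a different estimand. KL computations are
validated against a brute-force four-term sum at 1e-12. The REML search
runs over log-ratio ∈ [−25, 25] with a 1e-8 tolerance; penalty
eigenvalues below 1e-10 of the maximum count as null space.

## Known limitations

- The Gaussian looking-time likelihood ignores the hard floor at 0 ms
  even in censored mode (only the 1500 ms ceiling is treated); at the
  default calibration the floor is ~3.6 SDs below baseline and rare.
- The look-away model is trial-granular; it cannot express within-trial
  disengagement times.
- The additive-model F test is approximate (penalized edf in the
  numerator df); its finite-sample type-I error sits slightly above the
  nominal level, consistent with its behaviour in standard software.
- Random effects are assumed independent (no intercept–slope
  correlation), matching the model the estimates feed.
- The exponential outcome model fixes the rate inside exp() at 1/SD of
  the standardized slope; only its amplitude is estimated.
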