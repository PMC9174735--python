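# Methods

`coalrank` re-implements, as a tested pipeline, an event-level analysis of
male coalitionary aggression: how single coalition events relate to the
participants' and the target's subsequent dominance trajectories, and how
dominance in turn predicts siring success. The package bundles a synthetic
study-population generator with known ground truth, so every inferential
stage can be exercised and checked without field data.

## Dominance ratings

Dominance strength is scored by sequential Elo-rating. Each decided dyadic
contest moves points from loser to winner:

    R_w <- R_w + k * (1 - E(R_w - R_l)),    R_l <- R_l - k * (1 - E(R_w - R_l))

with start value 1000 and k = 100 (common choices in the macaque Elo
literature; both configurable). The expected-score function `E` is selectable:
the base-10 logistic with scale 400 (`logistic-400`, the chess convention,
default) or the Gaussian CDF with SD 200·√2 (`normal-cdf`, the classical
form). Both satisfy E(0) = ½ and E(d) + E(−d) = 1, so every update conserves
the contestants' rating total. Ratings are step functions of time
(carry-forward); on an update day the post-update value is used. Newly
immigrated males start at 1000. Coalition events themselves do **not** enter
the rating updates — only dyadic agonism does — to avoid circularity between
the response (future rating) and the events whose effects are estimated.
Undecided contests are excluded at ingest.

Standardized ratings rescale the co-resident males of a group on a given day
to [0, 1] by min–max (highest 1, lowest 0); the map requires at least two
males and a non-degenerate range.

## Coalition metrics

A coalition is simultaneous aggression by ≥2 participants against ≥1 target.
Configuration compares day-of-event ratings: *all-up* (every participant
strictly below the target), *all-down* (no participant below), *bridging*
(participants on both sides). A participant exactly tied with the target
counts as "not lower" (ties are measure-zero with continuous ratings; they
are logged when they occur). Multi-target events are classified and scored
against the highest-rated target and flagged; the metrics are defined for
single targets.

Feasibility is f = Σ s(participants) − s(target) on the standardized scale,
standardized among **all** males present in the group that day. By
construction f > 0 whenever any participant outranks the target, hence for
every all-down and bridging event; only all-up events can have f ≤ 0.

## Control variables

* **Hierarchy stability** S ∈ [0, 1] over a trailing 30-day window: one minus
  the mean, over consecutive day-pairs, of the fraction of male pairs whose
  ordinal rank order flips between the two days. S depends only on ordinal
  ranks, so it is invariant under monotone transforms of the ratings. This
  inversion-count definition is a transparent stand-in on the conventional
  [0, 1] scale (1 = fully stable); the module exposes it behind a plain
  function so a weighted variant can be swapped in.
* **Male competition index** C: co-resident adult-male headcount (simplest
  reading of male competition; a callable hook accepts variants such as
  males per fertile female when such data exist).
* **Aggression rate**: aggressive events per focal hour over a trailing
  30-day window; zero observation effort yields a missing value, never a
  zero rate.
* **Age**: (date − birth date)/365.25 in years.

Window lengths (30 days) are configuration defaults, not empirical claims.

## Analysis tables

The rank table links each event to twelve future time points: every involved
male contributes one row per offset Δt ∈ {10, 20, …, 120} days while he
remains resident; offsets after emigration are dropped, not imputed (once the
male leaves, the group that defines his standardized rank no longer contains
him). The response is the raw Elo rating at the future date. The day-0 rating
enters only as the "current rank" control. All numeric predictors are
z-scored on the assembled table (raw columns retained). Day-0 rows are not
response rows — the twelve-offset reading is used, with day 0 as control
only.

The paternity table has one row per candidate male × infant, candidates
being the males present on ≥1 day of the 11-day window centred on the
estimated conception date; the rating is the mean of daily standardized
ratings over the days present. Paternity is analysed per conception event,
never in aggregated time blocks.

An optional autocorrelation control is built by a two-pass scheme: residuals
from a first-pass fit are combined, per row, as a weighted mean of the same
male's residuals at the other offsets of the same event with weights
1/(1 + |ΔΔt|/10). The construction is configurable off (default off in the
model spec; the pipeline enables it when asked).

## Models

**Rank model.** A Gaussian linear mixed model for the future rating with
fixed effects role × configuration × feasibility (all lower-order terms),
time distance and role × time distance, plus controls (group, current rank,
age, aggression rate, stability, competition, optionally the autocorrelation
term). The default random structure crosses male ID and event ID (random
intercepts) with random slopes for time distance (by male and by event) and
feasibility (by male), implemented as independent variance components in
`statsmodels.MixedLM`. When a slope component prevents convergence, slopes
are dropped in the order feasibility-by-male, time-by-event, time-by-male,
and the reduction is recorded on the results object.

An alternative structure, `SERIES_RANDOM_STRUCTURE`, adds an event × male
series intercept and series time-slope. Role, configuration and feasibility
are constant within each event × male series, so with strongly
autocorrelated responses the series components keep those predictors from
absorbing series-level noise — but they also absorb much of a genuine role
effect at desk scale (substantial power loss) and multiply the fitting cost
(one dense variance-component column per series). The default follows the
published structure; the series variant is the conservative option and the
size/power trade-off between them is quantified below.

Fits for likelihood-ratio tests use ML, not REML; REML is available for
variance-component reporting. Each fit runs L-BFGS and then a BFGS
refinement warm-started from the first solution, keeping the higher
log-likelihood: an LRT statistic is a *difference* of log-likelihoods, and
incomplete convergence of either fit biases it noticeably.

The full-vs-null LRT compares the full model with a null containing the same
random structure and controls but no term involving any main predictor:
χ² = 2Δll, df = the fixed-effect design-column difference (13 under the
default specification), reference χ²(df). Published analyses of this design
report 22 numerator df, which implies additional interaction terms whose
exact composition is not recoverable from the main text; the specification
is configurable should they become known.

**Paternity model.** A binomial GLMM: logit P(sired) = α + β·s + u_male with
u_male ~ N(0, σ²), fitted by maximum likelihood with adaptive Gauss–Hermite
quadrature (15 nodes; each male's integrand re-centred at its mode and
re-scaled by the curvature there). The implementation is validated against
direct numerical integration (agreement ~1e-12 on small instances, far
inside the 1e-3 documentation tolerance) and against plain logistic
regression in the σ → 0 limit. Standard errors come from the numerically
differentiated observed information; σ's SE is delta-method transformed from
the log scale. Coefficients beyond ±15 raise a separation error.

**Bootstrap bands.** Parametric bootstrap: responses are simulated from the
fitted model (fixed effects + fresh random-effect and residual/Bernoulli
draws), the model is refitted, and predictions are evaluated on a grid with
numeric covariates at 0 (their mean on the z-scale) and categorical
predictors at reference levels; feasibility grids span only the observed
range per configuration. Default B = 1000 curves; failed refits are excluded
and more than 20% failures abort the band. Whether the original analysis
bootstrapped parametrically or by resampling events/males is not stated;
parametric is this package's default.

## Synthetic data generator

The generator emulates the study's statistical structure with known truth:

* **Demography**: 2 groups, 12 adult males each at start, 800 study days;
  migration as exit plus entry of a new identity (no return migration), with
  exits blocked at 7 and entries blocked at 18 males so the headcount stays
  inside the observed 7–18 band. Entry ages uniform on 9–20 years.
* **Latent strength**: per-male baseline ~ N(0, 1) (this defines the
  strength unit) plus slow AR(1) drift (stationary SD 0.3, daily
  autocorrelation 0.98). Latent strength is the generative truth; Elo
  ratings are downstream estimates of it, so recovery tests compare against
  injected effects, never against latent strength directly.
* **Contests**: per co-resident dyad-day an encounter with probability 0.05;
  the winner is logistic in the strength difference with scale τ = 1. The
  random stream depends only on presence and the encounter rate, so
  re-simulating with the same seed on a perturbed population reproduces the
  identical schedule with outcomes flipped only where the perturbation tips
  them — with zero injected effects the regenerated table is byte-identical.
* **Coalitions**: events per group-day with probability 0.08 after a 30-day
  burn-in (≈ 120 events over the default horizon, matching the observed
  order of magnitude); participant count from a truncated geometric on
  {2..6} with mean 2.2 (the observed mean; the distribution beyond
  mean/median/range is a modelling convenience); configuration drawn from
  the exact observed mixture 88:24:16 and realized by choosing members by
  current rating order. From the event day the target's strength drops by
  δ_T·g(f) and each participant's rises by δ_P, decaying linearly to zero
  over H = 120 days; g(f) = max(0.1, 1 + 0.5·f) for all-up events
  (feasibility-modulated, increasing) and 1 otherwise. Defaults δ_P = 0.3,
  δ_T = 0.6 strength units produce clearly detectable but not overwhelming
  effects at τ = 1 (roughly +50/−100 Elo points at equilibrium).
  `select_by_rating=False` switches to a neutral world (members and roles
  uniform at random) for null experiments.
* **Conceptions**: 19 conception events; per candidate male the sire
  indicator is Bernoulli with logit = α + 1.43·s + u_male, α = −3.1 (≈ one
  expected sire per conception with 12 candidates), u_male ~ N(0, 0.2).
  The single-sire constraint is deliberately **not** enforced: the fitted
  model is an unconditional binomial GLMM, so the generator matches that
  likelihood exactly; conditioning on exactly one sire would turn the truth
  into a conditional-logit model and bias recovery. A standalone cohort
  generator (`simulate_paternity_cohort`) draws the same structure without
  the population machinery for recovery experiments.
* **Focal effort**: 20–60 min protocols at rate 0.1 per male-day, with
  Poisson aggressive-event counts at a lognormal per-male rate.

What the generator does **not** emulate: female behaviour and reproductive
state, infant survival, observation error in conception dating, kin
structure, seasonal variation, and any feedback from rank onto coalition
propensity. Passing tests therefore demonstrate that the pipeline recovers
effects of the assumed form at realistic sizes — not that real data satisfy
those assumptions.

## Calibration experiments and their design

* **Type-I error of the rank LRT** (`lrt_type1_experiment`): responses are
  simulated from a null mixed model (controls only; crossed male/event
  random intercepts SD 30/20, residual SD 50, on the rating scale) over a
  fixed event-rich covariate design (110 events, two groups, offsets at
  40-day steps), then full and null are refitted by ML and the LRT recorded;
  500 replicates. The design deliberately contains many events because
  configuration and feasibility vary at the event level: the χ²(13)
  reference is only trustworthy when events are numerous, and event-poor
  designs inflate the test size regardless of row count (~24% at 15 events,
  ~7% at 110 before the convergence polish; ~5–6% with it).

  A caution documented on purpose: simulating a *world* with zero injected
  effects and running the whole pipeline does **not** produce a null
  hypothesis for this model. Members are selected by rating order, so role
  predicts future rank via regression-to-the-mean even with no causal
  effect, and Elo trajectories carry random-walk serial correlation within
  each event × male series that no tractable LMM covariance fully absorbs.
  In such pipeline-level runs the LRT rejected 44–63% of the time under the
  default random structure, and still ≈18% under `SERIES_RANDOM_STRUCTURE`
  in a neutral (random-selection) world. The flip side of the series
  variant is power: on a 43-event world with clearly injected effects it
  fails to reject (p ≈ 0.4) where the default structure rejects decisively.
  The calibration experiment therefore simulates from the model — the
  standard meaning of type-I calibration of the test machinery — and the
  pipeline-level behaviour of both structures is documented here rather
  than asserted by a test.
* **Paternity slope recovery** (`paternity_slope_recovery`): 200 cohorts of
  19 conceptions × 12 candidates at slope 1.43; mean recovered slope within
  ±0.15 (measured bias ≈ +0.02, MC SD ≈ 0.8 per replicate).
* **Sign-and-decay recovery** (`sign_recovery_experiment`): 200 single-group
  worlds (10 males, 400 days, ≈ 30 events) with the default injected
  effects; the model (fitted with crossed random intercepts, the fastest
  structure adequate for a direction check) predicts participants above
  targets at Δt = 10 in ≥95% of replicates, and the predicted gap is
  largest at Δt ≤ 30, shrinking toward 120 (the linear role × time
  interaction mirrors the lack of curvature in the published effect). The gap is computed by
  G-computation — every observed row predicted with role counterfactually
  set to participant and to target — which stays on the observed covariate
  support; evaluating interaction terms outside a configuration's observed
  feasibility range is unstable and was avoided for that reason.

Problem sizes for all repeated experiments (event counts, replicate world
sizes, bootstrap B in tests) are the package's choices balancing Monte-Carlo
precision against desk-scale runtimes; the defaults written above are the
ones the test suite runs.

## Numerical choices and degenerate inputs

* Z-scoring uses ddof = 0; a zero-variance column maps to zeros with a
  logged warning rather than NaN.
* Rows with missing covariates (e.g. no focal effort in the window) are
  dropped at model construction with a logged count, keeping the design
  matrix and the grouping vectors aligned.
* A constant response raises an explicit error (residual variance 0).
* Ties: tied ratings classify as "not lower" (above); tied stability
  comparisons count as no inversion.
* LRT statistics are floored at 0; identical specifications return
  χ² = 0, p = 1 with df 0.
* Within-day contest order follows recorded order in memory and a canonical
  sort after CSV validation, so shuffled input files validate to identical
  outputs.
* Percentages in descriptive tables round half-away-from-zero (12.5% → 13%),
  matching the convention of the published shares (69/19/13 from 88/24/16
  of 128, which print to a 101% total).

## Known limitations

* The stability and competition indices approximate quantities whose exact
  published formulas live in supplementary material not reproduced here.
* The full model's published 22 numerator df cannot be reconstructed from
  the main text; the default specification has 13 (see above).
* MixedLM variance components are independent (no intercept–slope
  correlations).
* The paternity model supports a single random intercept (male ID), which is
  the published structure, not a general GLMM.
* Pipeline-level LRT inflation for Elo-based responses (documented above) is
  a property of the design, not a software defect; users analysing real
  rating trajectories should interpret small LRT p-values with that in mind.
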