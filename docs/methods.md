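# Methods

This note documents the models, algorithms, defaults and design choices
behind `lexirt`, and what the synthetic-data experiments do and do not show
about real lexical-decision data.

## Response model

All accuracy modelling uses the guess-floored logistic item response
function

P(correct | θ) = c + (1 − c) σ(a (θ − b)),  σ(z) = 1 / (1 + e^(−z)),

with the lower asymptote fixed at c = 0.5, the chance rate of a
two-alternative forced choice. Two variants are estimated:

* `rasch_g`: one slope `a` common to all items, per-item difficulty `b`.
  The latent scale is identified by fixing the prior to Normal(0, 1) and
  estimating the common slope (equivalent, up to reparameterization, to
  fixing the slope and freeing the latent variance).
* `twopl_g`: per-item slope and difficulty.

The fixed floor has consequences that recur throughout this note: fitted
probabilities can never fall below 0.5, so any behaviour that drives an
item's observed accuracy to or below chance is *boundary-censored* — the
likelihood is maximized by parameters that flatten the curve at P ≈ 0.5,
where every standardized residual equals 1 and the item becomes invisible
to residual-based diagnostics.

## Estimation

Marginal maximum likelihood via EM (Bock–Aitkin): the latent density is
discretized on 61 equally spaced nodes over [−6, 6] (configurable) with
normalized Normal(0, 1) weights. The E-step computes each person's
posterior over nodes and accumulates expected response counts per item and
node; the M-step maximizes the expected complete-data log-likelihood with
safeguarded per-item Newton updates (vectorized across items, backtracking
until the per-item objective does not decrease), so the algorithm is a
generalized EM and the marginal log-likelihood is non-decreasing — a
property the test suite asserts at tolerance 1e−8 per step.

* Convergence: maximum absolute parameter change < 1e−4, or 500 iterations
  (non-convergence is logged and flagged, not raised).
* Bounds: a ∈ [0.05, 5], b ∈ [−8, 8]. Items at a bound (e.g. answered
  correctly by everyone, or at/below chance overall) are flagged in
  `bounded_items` rather than dropped.
* The reported `loglik` is recomputed at the returned parameters on a dense
  reference grid (2001 nodes on [−8, 8]) so that it agrees with direct
  numerical integration to ~1e−6 relative; the per-iteration EM trace uses
  the fitting grid.
* Abilities: EAP (posterior mean and sd on the grid). A grid-argmax ML
  scorer exists for diagnostics only.
* Marginal reliability: var(θ̂) / (var(θ̂) + mean(se²)), the EAP form;
  clipped into [0, 1] with a warning if degenerate.

Item fit uses the standard mean-square statistics evaluated at the EAP point
abilities with the guess-floored P: outfit is the unweighted mean of
squared standardized residuals, infit the information-weighted version.
Item information is I(θ) = a² ((P − c)/(1 − c))² (1 − P)/P, which reduces
to a²/12 at θ = b when c = 0.5.

## Selection pipeline

1. **Correlation screen** (r > 0.10 against both the full-set total score
   and the external criterion; removal rule `either` by default, i.e. an
   item must clear both). Zero-variance items are removed as degenerate.
   The total score is uncorrected by default; an item-rest option exists.
2. **Rasch fit window** [0.6, 1.4] on infit and outfit, refitting after each
   removal wave until stable (all out-of-range items removed per wave; 50
   wave limit). The final fit is returned with the report.
3. **2PL slope floor** a < 0.7 (strict), on a fresh 2PL fit.
4. **Assembly**: per-list size is `2 · floor(min(n_real, n_pseudo) /
   n_lists)` when class-balanced. The abundant class is subsampled by
   greedy nearest-match to the scarcer class's difficulty quantiles
   (ties broken by summed item information at the reference quartiles, then
   by seeded order); the scarcer class keeps evenly spaced order statistics.
   Items are dealt serpentine by difficulty, then a multi-restart local
   search over same-class cross-list swaps minimizes
   var(list mean b) + 0.1 · var(list mean length) (serpentine start plus
   four seeded random restarts, full improving-swap sweeps, 1000-swap
   budget per restart). On a 12-item pool this lands within a factor two of
   the exhaustive-search optimum; on study-sized pools the between-list
   mean-difficulty spread is ~0.003 logits against a 0.1 tolerance.

### What the fit window can and cannot catch

Because of the floor, the mean-square statistics are far less sensitive
than intuition suggests:

* An item whose responses are *inverted* for the upper half of abilities
  ends up below chance overall and is boundary-censored: infit = outfit =
  1.0 exactly. Steps 2–3 cannot see it; the step-1 correlation screen
  removes it instead (its item–total correlation is strongly negative).
  The generator's `misfit_inverted` pathology implements exactly this and
  is used to document the censoring.
* Uniform random lapses are largely absorbed by refitting a flatter curve
  (outfit 1.1–1.4 at 500 persons) and are usually caught by the slope
  floor, not the fit window.
* What the window reliably catches is misfit where the model is confident:
  the `misfit_lapse` pathology plants a very easy, steep item on which
  persons in the top ability quartile respond at chance (high performers
  not attending to trivially easy items). Their errors occur at fitted
  P ≈ 0.95–0.99, which drives outfit to 1.5–1.9 at 500 persons.
* A `null_discrimination` item has a_true = 0 and is flat at
  irf(θ, 0, b, 0.5) = 0.75; the 2PL drives its slope to the lower bound
  and step 3 removes it. (A flat item at exactly 0.5 accuracy would
  instead be boundary-censored — another reason the correlation screen
  comes first.)
* The window's false-positive rate on clean data is not negligible:
  outfit's sampling distribution is heavy-tailed wherever fitted
  probabilities approach 1 (a handful of surprising errors dominate the
  mean of squares), giving ~1–2% per-item false removals at 500 persons
  with difficulties spanning [−2, 2]. Clean-retention assertions are
  therefore ≥ 90–95%, not "zero removals".

## Response-time analyses

Order of operations is fixed: participant exclusion → absolute window →
per-person IQR trim → log transform → correct-trials-only modelling.

* Participant rule: median RT (raw seconds by default) more than 3 sd below
  the sample mean of medians; one-sided, since implausibly *fast* medians
  are the signature of random key-mashing.
* Trial rules: RT outside [0.2 s, 5 s], then per-person fences at
  Q1 − 3·IQR and Q3 + 3·IQR computed on the windowed data.
* Effects: a two-stage estimator. Stage 1 fits each person's OLS of log RT
  on the requested terms (jointly when several are requested, so each
  coefficient is adjusted for the others; the classic single-effect models
  run on their class subsets). Stage 2 averages coefficients across
  persons. The length-by-ability interaction is collinear with length
  within a person, so it is estimated by regressing the per-person length
  slopes on an externally supplied ability score.
* Standard errors: lexicality, frequency and length are item-level
  covariates, so their uncertainty is dominated by the finite item sample —
  item random intercepts shift every person's coefficient identically and
  are invisible to the cross-person spread (the language-as-a-fixed-effect
  problem). Reported SEs therefore combine the cross-person component with
  the coefficient SE of the between-item regression of per-item mean log RT
  on the same design, in quadrature. This mirrors what a crossed
  random-effects model reports, keeps the estimator dependency-free, and
  restores nominal ~95% coverage of the generating effects (purely
  cross-person SEs cover in only ~20–70% of bank draws at the default item
  intercept sd). A full mixed-model backend can be plugged in at the same
  interface.

Calibration: with all generator effects zeroed, each term's |t| > 2 rate
across 100 seeded runs is ~3–4% (slightly conservative). Note that the
*familywise* rate over five jointly estimated terms is necessarily
~1 − 0.95⁵ ≈ 23% for any calibrated estimator; calibration claims in the
tests are per-term (or on the single-term default model) for that reason.

## Synthetic data

The generator produces the structures the analyses assume, not realistic
English:

* **Items**: arbitrary lowercase strings (real orthographic plausibility is
  out of scope); length uniform on 3–10 letters; log lexical frequency
  Normal(1.5, 1.2) for real words only; log bigram/trigram/neighbor
  frequencies Normal(2.5, 0.8) / Normal(2.0, 0.8) / Normal(1.0, 0.8).
  Difficulties are stratified-uniform over the requested spread within each
  lexicality class (default [−3, 3]); slopes default to lognormal with
  median 1.2 and σ = 0.3 (constant and uniform specs available).
  c = 0.5 throughout.
* **Persons**: θ ~ Normal(0, 1) by default (uniform available for
  full-range validation cohorts); criterion_true = 40 + (80/6)·θ maps
  θ ∈ [−3, 3] onto a 0–80 raw-score-like scale; observed criterion adds
  Normal(0, 4.4) noise, putting the latent validity near 0.95. Configurable
  fractions have a missing criterion or are non-compliant.
* **Sessions**: every person sees the same block/item assignment with
  per-person presentation order; accuracy is Bernoulli of the response
  function with the pathology rules above; non-compliant persons respond
  Bernoulli(0.5) with fast lognormal RTs (median 0.25 s).
* **RTs**: log RT = μ₀ + 0.11·[pseudo] − 0.021·logfreq·[real] +
  0.035·logbigram·[pseudo] + 0.031·length − 0.010·length·θ + person
  intercept + item intercept + residual, with μ₀ = −0.30 and sds
  0.15 / 0.10 / 0.25 (chosen so the effects are recoverable at cohorts of
  100–150 persons; the fixed-effect defaults are the study conditions).
  3% of compliant trials are contaminated (one-third anticipations with
  median 0.10 s, two-thirds slow lapses with median 4 s, log-sd 0.5) —
  the material the RT filters exist to remove; at these defaults the
  filters excise ~2.5–3% of trials.
* **Seeding**: every stream derives from one integer seed through
  `numpy.random.SeedSequence` spawn keys, with per-person substreams, so
  outputs are byte-identical across runs and partial regeneration is
  stable.

## Experiment conditions used in the validation suite

These sizes were chosen once as the package's standing validation design:

* *Difficulty recovery*: 500 persons × 40 Rasch items (common a = 1),
  b ∈ [−3, 3]. RMSE is dominated by the few items near ±3, where the floor
  leaves little information (per-item SE up to ~0.5–1 logit); typical RMSE
  0.26–0.35, correlation ≥ 0.98.
* *Slope recovery*: 500 persons × 60 items, b ∈ [−2, 2], slopes lognormal
  (median 1.2, σ = 0.5). Slopes of items far outside the cohort's ability
  mass are weakly identified under the floor, so the recovery bank keeps
  |b| ≤ 2; typical slope correlation 0.8–0.9.
* *Planted recall*: 180 Rasch-conforming clean items (common a = 1.5,
  b ∈ [−2, 2]) plus 20 planted pathologies (null-discrimination and
  lapse, alternating), 500 persons, five seeds. Steps 2–3 catch ≥ 95% of
  planted items while retaining ≥ 96% of clean ones.
* *Form equating*: a retained-pool-like bank (114 real + 185 pseudo,
  b ∈ [−2.5, 2.5], slopes lognormal median 1.75, σ = 0.3 — the range
  calibrated banks show after screening) and a 150-person validation
  cohort with uniform θ ∈ [−3, 3], i.e. a sample spanning the full reading
  range. Information curves are evaluated under the common-slope model, the
  same convention used to equate the forms. Typical results: information
  ratios within [0.98, 1.02], single-form score ICC ≈ 0.91, composite
  (average-measure) ICC ≈ 0.97, composite marginal reliability ≈ 0.97.
* *RT machinery*: 150 persons × 500 items with 2% planted fast guessers;
  all five effects recover in sign and within 2 SE, and the 3-sd rule
  catches every planted guesser.

Because the generator is the ground truth, passing these experiments shows
that the pipeline's logic and estimation are correct and well calibrated
under its assumptions — unidimensional ability, a clean 0.5 floor,
lognormal RTs, independent items. It does not show robustness to the things
real lexical-decision data add: multidimensionality (orthographic vs
phonological routes), position and practice effects, differential item
functioning across ages, or floor violations from response biases.

## Degenerate inputs and numerical choices

* Probabilities are clipped to [1e−12, 1 − 1e−12] inside likelihoods and to
  a configurable ε in fit statistics (clips are logged).
* Perfect-score items/persons: parameters bounded and flagged; EAP keeps
  perfect scorers finite under the prior.
* Zero-variance inputs: correlation routines raise; the screen removes
  zero-variance items as degenerate; a zero IQR disables the fence for that
  person; identical medians exclude nobody (sd = 0).
* All correlation routines are pairwise-complete and report the n used.
* ICC: two-way consistency, single-measure, by default (label-shift
  invariant, the right variant for interchangeable forms); agreement and
  average-measure variants are available. Composite reliability is
  reported three ways (marginal IRT reliability, average-measure ICC,
  Spearman-Brown) because they answer slightly different questions.
* Disattenuation supports both the two-instrument convention
  r/√(rel_x·rel_y) and the single-instrument r/√(rel_x); values above 1
  clip with a warning.
* Kruskal-Wallis uses the tie-corrected statistic with a chi-square
  p-value; an exact permutation p is available for small samples.
* p-values are two-sided except the participant RT screen, which is
  one-sided by construction.
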