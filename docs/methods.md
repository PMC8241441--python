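# Methods

## The model family

`mooddyn` models momentary mood reported during a probabilistic gambling
task in which a participant repeatedly chooses between a certain amount
C_t and a gamble between two values (high_t, low_t), observes an outcome
A_t, and rates mood on a bounded unhappy–happy scale every 2–3 trials.

Every model in the family predicts the mood rating at trial t as a baseline
plus exponentially discounted, coefficient-weighted sums of per-trial
regressor streams:

    M_t = m0 + sum_v beta_v * sum_{j<=t} gamma^(t-j) X_v(j) + eps_t

with gamma in (0, 1) the discount factor, beta_v >= 0 the sensitivities,
and eps_t ~ Normal(0, sigma) rating noise (generative use only).  The
members differ in the expectation stream E and in which trials feed which
stream:

- **Recency** (the standard account): E_t = (high_t + low_t)/2, the current
  gamble's mean; streams C (certain amount when chosen), E and R = A - E
  (on gamble trials only).  Because each regressor is tied to its own trial
  and discounted, the influence of trial i on mood at trial t scales as
  gamma^(t-i): recent events dominate.
- **Primacy**: E_t = mean(A_1 .. A_{t-1}), the plain average of *all*
  previous outcomes (gamble and certain trials alike; E_1 = 0 by
  convention); streams E and R only, active on every trial.  Early outcomes
  enter every later expectation and are then re-summed with discounting, so
  their aggregate influence on mood *decreases* with recency even though
  the RPE stream itself is recency-weighted.
- **Recency variants**: without the certain term; with a dynamic win
  probability p(t) = (wins + 5)/(gambles + 10) (Bayesian shrinkage
  equivalent to 10 pseudo-observations at 0.5) replacing the fixed 50% in
  E_t = p·high + (1-p)·low; with the previous outcome as the expectation;
  and the dynamic-win/no-certain combination.
- **Decayed-window family**: primacy-like accumulation whose expectation is
  a decay-weighted mean of the last t_max outcomes (weight w^k on the
  outcome k steps back, normalized).  With w = 1 and an unbounded window it
  reduces exactly to the primacy model.  The within-expectation weighting
  may favor recent outcomes, yet the accumulated effect on mood retains the
  primacy shape — `influence_curve` makes this measurable.

Mood is kept on the normalized unit scale; monetary quantities stay in raw
task points, so the beta coefficients absorb the units (defaults of order
0.01 per task point keep predictions on-scale).  Predictions are not
clamped during fitting; generative simulation clamps ratings to [0, 1].

`influence_curve` computes the model-implied weighting of past events by
central finite differences of the final-trial mood against a perturbation
of each earlier trial (outcome perturbation for history-based expectations;
a joint shift of the trial's offered values and outcome for current-gamble
expectations).  The default step is 1e-4 task points; because every model
here is linear in the perturbed quantities, any step is exact up to float
cancellation, and a coarser step (e.g. 0.25) is preferable when weights
span many orders of magnitude.

## Task environments

All three environments share the session geometry: 81 trials, 34 mood
ratings separated by gaps of 2 or 3 trials.  Rating slots are placed by
constrained backtracking so the totals hold exactly; in the blocked tasks
the 34 ratings split 11–12 per block.  Generators are pure functions of
(config, seed); congruency and outcome schedules are laid out at exact
proportions and shuffled, not drawn i.i.d., so the design constants hold in
every session rather than in expectation.

- **Random**: the gamble mean is drawn from a uniform grid (0 to 10 in
  steps of 0.2 — the source design states only the RPE range, so the value
  scale is a package choice) and the RPE magnitude from a 0.1-step grid up
  to 2.5; the outcome is high or low with probability 1/2 and the certain
  amount equals the gamble mean.
- **Structured**: three 27-trial blocks with reward prediction errors +5,
  -5, +5 relative to the gamble mean; exactly round(0.30·27) = 8 trials per
  block are incongruent with magnitude 1.5 and opposite sign.  A scheduled
  RPE of r is realized by drawing the high value from the adaptive task's
  grid and placing the low value 2|r| below it, so outcome - mean = r
  exactly.
- **Structured-adaptive**: the same block design, but each rating updates a
  proportional–integral controller.  The mood error M_E in [0, 1] is the
  normalized distance of the rated mood from the block target (top, bottom,
  top of scale).  The next trials' RPE magnitude is
  baseline·M_E + I (congruent) or baseline·M_E + I/3 (incongruent), with
  baseline = 14 points, I the running within-block sum of mood errors
  (including the current one), and the sign set by block valence (flipped
  on incongruent trials).  The integral resets to zero at each block start.
  Before the first rating the controller assumes a neutral mid-scale error
  of 0.5 (proportional term only) — the rating cursor starts mid-scale, and
  the source design does not state pre-first-rating behavior.  When a
  trial group spans a block boundary, the mood error is re-aimed at the new
  block's target from the latest rating without entering the fresh
  integral.  Gamble values follow the published rule: high drawn from the
  grid from -1.5 upward in steps of 0.2 (the printed upper endpoint 14 is
  not commensurate with the step; the grid tops out at 13.9), low = high -
  |RPE|, certain = mean unless that exceeds 2 points, then half the low
  value.  Note this realizes an experienced outcome-minus-mean RPE of half
  the controller magnitude; the rule is implemented as published.

Display-level details (stimulus timing, screen side of each value, button
mechanics, payment) are out of scope.

## Synthetic participants

Choice behavior is not part of the mood models, so agents use deliberately
simple policies; the default gambles with fixed probability 0.7, keeping
certain-choice trials present for the certain-term stream.  Population
defaults: m0 ~ Uniform(0.3, 0.7); each active beta ~ |Normal(0, 0.01)|
(per task point); xi ~ Normal(0, 1) so gamma centers on 0.5; sigma = 0.05
on the unit mood scale.  These keep noise-free predictions mostly inside
the scale under the default tasks.  Ratings are noisy only at rating times
and are clamped to [0, 1] — the only nonlinearity in the generator.

`simulate_cohort(require_interior=True)` (open-loop tasks) redraws a
subject's parameters until the noise-free predicted series stays strictly
inside the unit scale.  This is the regime where simulated ratings are an
exact realization of the linear model and parameter recovery is well
defined; with clamping active, high-discount subjects' observations come
from a different (censored) process and no estimator of the linear model
can recover them exactly.

What the generator does *not* emulate: real choice behavior (risk
attitudes, value sensitivity), within-session parameter drift, fatigue,
scale-use habits (edge avoidance, rounding), or any dependence of choices
on mood.  Passing tests therefore certify the estimator and comparison
machinery on data that satisfy the model assumptions, not that human data
do.

## Fitting

All subjects are fit jointly by minimizing

    sum_s sum_{t in T} (Mhat_s(t) - M_s(t))^2
      + lambda_xi * Var(xi) + lambda_beta * sum_v Var(beta_v)

where T is each subject's rated-trial set restricted to trial >= 11 (early
ratings are dropped to minimize window effects) and Var is the population
variance across subjects — a group-level shrinkage that stabilizes the
per-subject coefficients.  Defaults lambda_xi = 10 and lambda_beta = 100
follow the published calibration; `select_regularization` reproduces that
calibration by exhaustive search over the powers-of-ten grid 1e-3..1e4,
scoring each pair by z-scored per-parameter recovery MSE on simulated
cohorts.

Parameterization: gamma = 1/(1 + exp(-xi)) (unbounded xi), beta =
softplus(b) for smooth non-negativity.  The optimizer is L-BFGS with
analytic gradients (the discounted sums and their gamma-derivatives follow
a two-term recursion, vectorized across subjects).  Initialization sets m0
to the subject's first rating, gamma to 0.5, and the coefficients near
0.01; restarts sweep xi over {±1.1, ±2.2} with jitter on the rest, because
the loss surface has genuine basins in gamma.  Convergence is declared on
relative objective change below 1e-10 (or 10,000 iterations, flagged but
not discarded); the returned fit is the best restart and never exceeds the
initial objective.

Degenerate inputs: a cohort with constant ratings is fit essentially
perfectly but is not identifiable subject-by-subject (a flat prediction
can be produced by several parameter combinations; the variance penalties
vanish when subjects agree), so only the predicted series, not the
parameters, is meaningful there.  Sessions whose ratings all precede trial
11 raise an explicit empty-fit error.

## Model comparison

Two criteria are computed per subject: the training MSE of the joint fit,
and the streaming prediction error — for each rating index k from 4
upward, the model is refit on ratings 1..k-1 (no early-trial discard in
these prefix fits) and rating k is predicted from the full trial history;
squared errors at rating indices below 11 are discarded from the summary
MSE, where the criterion is unstable for want of data.  Prefix fits are
warm-started from the previous prefix's solution; a cold-started
refit-from-scratch loop is the test suite's independent oracle for the
protocol, and the two agree to optimization tolerance.  Regularization
weights stay at their defaults across prefixes.

Models are compared across subjects with a one-sided Wilcoxon signed-rank
test at alpha = 0.05 (the conservative null being that the candidate is no
better).  Zero differences are dropped and tied magnitudes mid-ranked.
With 25 or fewer effective pairs the exact null is enumerated by dynamic
programming over sign patterns (tie-aware); above that, the normal
approximation with continuity and tie corrections supplies z and p.  Model
recovery simulates a cohort from each candidate and requires the generator
to beat every alternative on every criterion; `holdout_validate` reruns a
comparison on a seeded 40% subsample and confirms the winner on the full
sample.  `coefficient_contrast` is a paired t-test of beta_E against
beta_R with a flagged infinite statistic when the differences have no
sampling variance.

## Problem sizes and numerical choices

The test suite exercises the full pipeline at the sizes its statistics
need and no larger: model recovery uses two cohorts of 40 subjects on the
structured task (both criteria, all four comparisons significant);
noise-free parameter recovery uses 20 subjects and three seeds with
penalties off (see above for why lambda = 0 is the well-posed noise-free
regime); closed-loop behavior uses 20 single-session seeds; oracle
equivalences run on 3-subject toys.  Discounted-sum equivalence holds to
1e-10; optimizer-dependent equivalences (streaming vs naive loop) to 2e-3
on the unit mood scale.

## Known limitations

- The exact published forms of the five alternative weighting models are
  not available in the source text; the decayed-window family implemented
  here is the generic decay-plus-window form they describe.
- The incongruent branch of the controller divides only the integral term
  by 3 (the literal reading); observed incongruent RPEs in the source data
  are smaller on average than this reading produces at large mood errors.
- The adaptive task's published gamble rule yields an experienced RPE of
  half the controller's magnitude relative to the gamble mean; it is
  implemented as published rather than rescaled.
- Whether the certain amount enters the recency model when offered but not
  chosen is resolved as "only when chosen" (C_j = 0 otherwise), and the
  baseline mood m0 is fitted freely and left unpenalized.
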