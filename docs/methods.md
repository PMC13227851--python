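# Methods

## The estimands

For one activity class (SED, LPA, MVPA) and one subject, the bout lengths
accumulated on a given day of week `d` form a sample `x_1..x_n` (minutes,
all >= the 1-minute recordable floor `x_min`). The alpha index
`1 + 1/mean(log(x_i/x_min))` is the maximum-likelihood density exponent of
a Pareto law with known scale `x_min`; the Gini index is the half relative
mean absolute difference, computed here in `O(n log n)` from the sorted
sample (`G = sum_i (2i - n - 1) x_(i) / (n sum x)`), which is algebraically
identical to the defining double sum. Conventions:

- `x_min` is the instrument floor (1 min), never the sample minimum; a
  sample below the floor is a contract violation, not a clamped value.
- An empty sample, or one with every bout at the floor (`M = 0`), yields a
  missing index rather than an infinity, keeping design matrices finite.
  The frequency of this degeneracy is visible in the index table as rows
  with missing alpha but positive counts.
- Gini is exactly 0 for constant samples and bounded by `1 - 1/n`; both the
  scale invariance of Gini and the joint scale invariance of alpha
  (lengths and floor multiplied together) are enforced by property tests.

Two aggregation modes map valid days onto (subject, day-of-week) indices:
`pool` concatenates the bout lengths of the (typically two) valid same-dow
days before computing each index; `per_day_mean` computes per-day indices
and averages them. Pooling is the default throughout the pipeline.  The
modes are not interchangeable for inference about day-level effects: when
the outcome responds to each *day's* realized index, the pooled index is a
noisy surrogate for the average of the daily indices, and the regression
suffers classical errors-in-variables attenuation (about 45% for MVPA at
~7 bouts/day in the synthetic cohort). Recovery-style analyses therefore
use `per_day_mean`, where the regressor is exactly the averaged daily
index.

## The regression model

One observation per subject and day of week: outcome `Y_i(d)` (day-level
median accurate RT in ms, or mean correct trials), predictors
`alpha_i(d)`, `G_i(d)`, the mean daily bout count `N_i(d)` of the same
class, and subject-constant age, sex (1 = male), and two education
indicators (reference: up to high school). Every coefficient is a curve on
the 7-point weekly circle, expanded in `K` periodic cubic B-splines
(default `K = 5`, knots evenly spaced on a circle of circumference 7) with
a circulant second-difference penalty whose null space is the constant
curve. `K = 7` with zero penalty is the saturated escape hatch: it spans
all functions on 7 points, and without the random intercept the fit then
equals seven per-day OLS regressions exactly (verified to 1e-6).

Within-subject correlation across the week is carried by a scalar random
intercept. The full fit is a penalized linear mixed model estimated by
REML: for smoothing parameters `lambda_1..lambda_8` (one per curve) and
variance ratio `rho = var(u)/var(e)`, the profiled criterion

```
(n - M_p) log sigma^2_hat + log|C'C + G| - log|G|_+
```

is minimized, where `C = [X Z]`, `G = blockdiag(lambda_j S_j, I/rho)`,
`M_p = 8` unpenalized constant directions, and
`sigma^2_hat = (RSS + penalty)/(n - M_p)`. The random-intercept block is
eliminated analytically (its cross-product is diagonal), so each criterion
evaluation costs one dense Cholesky of the fixed-effect dimension (8K x
8K); the search is coordinate-wise bounded golden-section on `log10`
scales (lambda in [-6, 8], rho in [-6, 6]), swept until the criterion
changes by less than 1e-8 (at most 15 sweeps, deterministic, no random
starts). GCV smoothing with a moment-estimated intercept variance and
fully fixed smoothing are available alternatives.

Uncertainty uses the Bayesian posterior covariance of the penalized
coefficients, `sigma^2 (C'C + G)^{-1}`; pointwise bands at `d = 1..7` are
normal intervals on `B theta_j`. Each curve's null test is Wald-type on
the curve values with the covariance truncated to its effective rank
(term EDF rounded to the nearest integer, capped at the numerical rank):
under strong smoothing a null curve collapses onto its unpenalized
constant direction, and testing only the retained directions keeps the
empirical size near nominal (measured 0.03–0.05 at the 0.05 level over
hundreds of null cohorts). The standalone `wald_test` utility instead uses
the full numerical rank, matching its general-purpose contract. Adjusted
R^2 is `1 - [RSS/(n - edf)] / [TSS/(n - 1)]` with `edf` the trace of the
full smoother (fixed part plus shrunk random intercepts); RSS uses
conditional residuals (random intercepts predicted).

Known inference properties, documented rather than hidden: pointwise
Bayesian bands have good average coverage but can miss sharp local
features — a curve that is exactly zero on one day and constant elsewhere
is outside the span of the smooth `K = 5` basis, and REML shrinks the
isolated day toward its neighbours at any `K`. Pattern-recovery studies
therefore use the saturated unpenalized variant, whose pointwise intervals
are ordinary frequentist ones.

## The synthetic cohort

The generator emulates the study design the analysis assumes: 87 subjects
(defaults; any size) x 14 days, a 06:00–22:00 wake window, four prompts
per day roughly 2.5 h apart with +/-30 min jitter, 18 trials per prompt
answered independently with probability `compliance` (0.85). Each day, per
class, a Poisson number of bouts (means 28 / 35 / 7 for SED / LPA / MVPA,
matching the emulated protocol's daily counts) receive Pareto lengths with
density exponents 2.5 / 3.0 / 3.5 and scale 1 min, are shuffled, separated
by OTHER (quiet standing) filler, and tiled exactly into the wake window;
bouts are randomly dropped only if a day's draws cannot fit, which slightly
truncates the longest tails relative to the unconstrained Pareto law. MET
values are drawn inside each class's defining interval, SED events always
seated/reclined. A configurable fraction of days (`low_wear_prob`, default
0 in the raw generator, 0.04 in the pipeline default config) is generated
with under 10 h of coverage to exercise the exclusion rules.

Latent day-level outcome means are linear in the day's *realized* indices:
baseline (2300 ms RT; 17.5 correct trials) + subject intercept
(SD 250 ms / 0.3 trials) + planted day-of-week coefficients times the
day's true Gini/alpha per class + day residual (SD 250 ms / 0.3 trials),
so the ICC knob is `subject_sd^2/(subject_sd^2 + residual_sd^2)` = 0.5 on
the latent scale. Default planted Gini curves mirror the qualitative
pattern of interest — null on Sunday, constant on weekdays, half-size
Saturday: −600 ms (MVPA on RT), +300 ms (SED on RT), +1.5 trials (LPA on
accuracy) per unit Gini — with all alpha effects null. Classes with no
bouts on a day contribute nothing that day. Sessions then add measurement
noise: per-trial correctness is Bernoulli at the day mean, accurate-trial
RTs are log-normal with sigma 0.25 centred so the session median is the
day mean.

Two deliberate gaps between generator and reality: observed (session-
level) outcomes carry finite-trial noise on top of the latent day mean, so
the *observed* ICC is attenuated below the knob — the ICC invariant is
asserted on the latent truth table; and real accelerometer data contain
posture misclassification, naps scored as sitting, and non-Pareto bout
tails, none of which are modelled. Passing tests certify the estimators
and the inferential machinery under the stated model, not those
artefacts.

A vectorized day-level fast path (`simulate_dow_table`) draws the same
bout and outcome model but skips event tiling and per-trial simulation,
approximating the trial noise analytically (median standard error
`1.2533 * sigma * RT / sqrt(n_accurate)` for RT; binomial counts for
accuracy). It produces analysis tables directly and is what the
Monte-Carlo calibration, coverage, and recovery studies run on (hundreds
of cohorts in minutes on one CPU); the event-level path is exercised end
to end at smaller sizes, and the two share `sample_bout_lengths` and the
index ground truth contract (`true_indices` is an independently coded
alpha/Gini path that must agree with the `indices` module to 1e-12).

## Quality control and alignment

A protocol day is valid iff wear time within the wake window is >= 10 h
and at least one session is complete (all 18 trials); when both rules
fail, low wear is the recorded reason. Days present in cognition but
absent from accelerometry count as zero wear. Outcomes are averaged over
the valid same-dow days; a valid day whose complete sessions had no
accurate trial contributes to accuracy but not to RT. Rows missing all
index sets are dropped; a subject missing demographics is a hard error.
Study day and study week are deliberately never covariates.

## Power study

The power module reproduces the design-stage question: days nested in
subjects, a standard-normal day-level covariate, a constant standardized
effect beta, unit total outcome variance split by the ICC, and a Wald test
of the slope in a REML random-intercept fit (a purpose-built profiled
fitter whose 1-d variance-ratio search makes 500 simulations per cell run
in seconds; it is cross-checked against statsmodels MixedLM). Because the
covariate varies within subject, raising the ICC at fixed total variance
*reduces* the residual against which the slope is tested, so power
increases with ICC — at beta = 0.05 and 87 x 14 observations the measured
power rises from ~0.53 (ICC 0.3) through ~0.66 (0.5) to ~0.89 (0.7). The
observed ICCs of the emulated study are unknown, so results are reported
as an ICC-by-beta grid; empirical size at beta = 0 stays within Monte-
Carlo error of the nominal 0.05.

## Problem sizes and numerical choices

Monte-Carlo studies use sizes chosen to give decisive margins at modest
cost: 500 null cohorts of 200 subjects for test calibration (binomial
MCSE ~0.01 at rate 0.05), 200 replicates of 300 subjects for pattern
recovery, 20 replicates for the constant-effect bias (per-replicate MC
spread ~14%, so the 20-replicate mean estimates bias to ~3%), and 400–500
simulations per power cell. Cholesky solves get a relative jitter of
1e-10 only on factorization failure (relevant only near the saturated
zero-penalty corner); eigenvalues below `max_eig * K * eps` are treated
as numerical zeros in Wald pseudo-inverses; even-count medians use the
midpoint convention everywhere; timestamps are timezone-naive local clock
time with events contiguous iff the gap is <= 1 s, and an overlap
tolerance of 5 ms absorbs serialization rounding.

## Limitations

The random intercept is scalar — a subject-level curve (functional random
effect) would capture subject-specific weekly shapes; cluster-robust
covariances are not yet wired in as the alternative correlation treatment.
Accuracy is modelled as a Gaussian day-level mean although it is a bounded
count near its ceiling. Predictors enter on their natural scales by
default (`standardize=True` z-scales the continuous ones); effect-size
magnitudes are therefore scale-bound. The pooled aggregation default is
faithful to the estimand definition but, as noted, attenuates day-level
causal coefficients; analysts comparing against planted truth should use
`per_day_mean`.
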