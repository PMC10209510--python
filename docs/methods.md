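# Methods

This note documents the models, estimators, parameter choices, and
numerical conventions used throughout `fingercode`, including the
design decisions taken where more than one defensible choice existed.

## Synthetic data model

The generator emulates multi-session recordings during cued individual
finger movements of either hand. Per session it draws a fresh
population of units (sessions never share units, matching how
pseudo-population analyses treat different days' neurons as distinct).
For unit *i* the mean rate of condition (hand *h*, finger *f*) is

    mu_i(h, f) = max(0, b_i + H_i(h) + F_i(f) + lambda * G_i(h, f))

- `b_i ~ Gamma(shape 2, mean baseline_rate)` — positive, right-skewed
  baselines, the shape of cortical firing-rate distributions;
- `H_i, F_i ~ N(0, sd^2)` i.i.d. per unit — hand and finger main
  effects with configurable SDs;
- `G_i ~ N(0, 1 Hz^2)` scaled by `lambda` (Hz) — a per-condition
  interaction. At `lambda = 0` the condition-mean matrix is exactly
  additive (perfectly factorized); growing `lambda` destroys
  factorization while leaving within-condition decodability intact.
  Rectification at zero is the only nonlinearity; at the default
  10 Hz baseline it is rarely active.

Trial noise is Poisson on spike counts: `count ~ Poisson(mu * gain *
window_s)`, rate = count / window. The spike-time generator uses a
piecewise-constant Poisson process across the trial phases
(ITI → cue → delay → go), with per-phase gain multipliers. During the
ITI the rate is the baseline only (no condition offsets): before the
cue appears the condition is unknowable, so pre-cue activity cannot
carry condition information — this is what makes the sliding-window
decode time course fall to chance before cue onset, as it must.
The No-Go condition fires at baseline in every phase; it is the
reference for the Dunnett contrasts.

Defaults mirror the ten-finger study conditions: 10 sessions,
110 units/session, 10 trials per condition, both hands, 0.5 s windows.
A `contralateral_delay()` preset (4 sessions, 118 units, right hand,
No-Go, 20 trials/condition) covers the single-hand task. Effect SDs
default to 2 Hz, chosen so that per-unit effect sizes against Poisson
rate variance in 0.5 s windows (~20 Hz^2 at 10 Hz) span the
small-to-large eta^2 range rather than saturating.

What the generator does *not* emulate: trial-to-trial overdispersion
(real units are often super-Poisson), noise correlations between units,
temporal dynamics within a phase, adjacent-finger tuning correlations,
and electrode/sorting artifacts. Consequences: decoding accuracies on
synthetic data are optimistic for a given unit count, and error
anatomies show no preference for adjacent fingers (the generator's
finger tuning is exchangeable). Passing tests therefore validate the
*estimators*, not quantitative predictions about cortex.

## Analysis windows and rates

Canonical epochs are 500 ms: move = [go+0.2, go+0.7), plan =
[delay+0.2, delay+0.7), cue = [cue+0.2, cue+0.7), ITI = last 500 ms of
the ITI phase (ending at cue onset). Windows are half-open
[start, end), so abutting windows partition spikes without double
counting. Rates are counts divided by window duration.

PSTHs convolve per-trial spike trains with a Gaussian kernel
(default sigma 50 ms) truncated at ±4 sigma and renormalized, on a
10 ms grid (finer grids are superfluous at sigma = 50 ms); the CI is
the pointwise normal-approximation 95% interval across trials. Edges
are biased low by kernel truncation; no data is fabricated beyond
trial bounds.

Unit screens: decoding discards units whose *training-fold* mean rate
is below 1 Hz (recomputed per fold — the test fold never touches the
screen); selectivity statistics use a looser 0.5 Hz screen over the
whole recording.

## Selectivity statistics

- ANOVA: classical one-way fixed effects, vectorized across units.
  Degenerate all-constant units report F = 0, p = 1, eta^2 = 0 rather
  than raising, so population summaries stay computable for silent
  units; perfectly separated groups report p = 0, eta^2 = 1.
- BH-FDR: step-up with explicit support for m larger than the number
  of tabulated p-values; the experiment-wide family is all units
  passing the rate screen, pooled across sessions (m = N convention).
  Calls: selective if q < 0.05; large effect if eta^2 > 0.14.
- Dunnett many-to-one test: adjusted p-values from a seeded
  100,000-draw Monte Carlo null of the max-|t| statistic (shared
  control, pooled chi^2 variance), cached per (k groups, df). This is
  a balanced-design approximation (the tasks are balanced); it
  vectorizes across thousands of units, reduces to the two-sided t
  test at k = 1, and agrees with the exact multivariate-t
  implementation to ~0.01 in p (cross-checked in the tests).
- Hedges' g: J-corrected standardized mean difference,
  J = 1 − 3/(4·df − 1), with a nonparametric bootstrap percentile 95%
  CI (default 5000 resamples; 1000 in the per-unit table for speed).
- The "mean number of significant fingers" summary is reported both
  conditioned on ANOVA-selective units and unconditioned, since either
  convention is defensible.

## Decoding

Diagonal LDA: class means, one pooled within-class variance vector
shared across classes (denominator n − C), empirical priors, a 1e-6
Hz^2 variance floor for silent-but-retained units. Prediction is the
argmax of log prior − ½ Σ (x − mu)²/sigma²; exact ties resolve to the
lowest class index and are flagged. The model is exactly a
shared-variance Gaussian naive Bayes, and the tests hold it to exact
label agreement with an independent brute-force oracle.

Cross-validation: stratified K-fold (default 8), trials assigned to
folds round-robin in within-class trial order — deterministic, no
shuffling. Sessions are pooled by summing correct trials; the
across-session SD of accuracy is weighted by session trial counts.
Accuracy CIs on curves are normal-approximation 95% intervals over the
pooled fold × session accuracy list (the fold/session decomposition is
not separately modeled); neuron-dropping intervals are 2.5/97.5
percentiles over 40 unit-resamples.

Learning curves truncate each training fold to the first n trials per
class in fold order (deterministic); fractions leaving fewer than two
training trials per class are skipped with a warning, since the pooled
variance is undefined below that. Pseudo-populations pair the j-th
trial of each condition across sessions and trim to the cross-session
minimum trial count.

## Crossnobis geometry

Distances follow the cross-validated Mahalanobis estimator with both
folds' noise covariances averaged (see README for the formula). Noise
covariance: within-fold residuals (trials minus their own
fold-condition mean), empirical covariance with df = trials −
conditions, shrunk toward its diagonal with the Schafer–Strimmer
analytic intensity. Two numerical guards matter in practice:

- the covariance diagonal is floored at 1% of the mean unit variance —
  a unit silent within a fold otherwise contributes a ~0 variance whose
  inverse dominates every distance;
- the fold count is capped so each condition keeps at least 2 trials
  per fold. A fold of singleton conditions has zero residual degrees of
  freedom and no covariance estimate at all; with 10 trials/condition
  and K = 8, six of eight folds would be singletons and the RDM
  diverges. The cap (K_eff = min(K, floor(min condition count / 2)))
  preserves the default K = 8 whenever trials allow it.

Session-average RDMs are unweighted means. The matching contrast is
mean(non-matching cross-hand d²) − mean(matching d²) with a bootstrap
95% CI over session × pair entries (5 matching and 20 non-matching
pairs per session for 5 finger types × 2 hands).

MDS embeds sqrt(max(d², 0)) — negative squared distances, legitimate
under the unbiased estimator, are clipped to zero before the root —
using metric MDS with a classical-MDS initialization (deterministic).
Generalized Procrustes alignment iterates rotation/reflection/
translation and optional isotropic scaling against the evolving mean
shape (tolerance 1e-9, max 100 iterations); per-condition dispersion is
the across-session standard error, undefined below 3 sessions.

## CCGP and the permutation test

Hand CCGP: five leave-one-finger-type-out splits, left-vs-right
classifiers; finger-type CCGP: train on one hand, test on the other,
both directions; correct/total pooled over splits. The matched
within-condition bound runs standard stratified CV on the dimension's
labels with training folds subsampled (class-stratified, seeded) to the
CCGP training-set size; K = 8 is required so the training folds can
hold the matched size. Null distribution: hand and finger-type labels
shuffled jointly across trials within each session *before*
pseudo-population pairing (destroying both factor structures while
preserving marginal counts), full CCGP recomputed per shuffle, with
the one-sided add-one p-value p = (1 + #{null ≥ obs})/(N + 1), never
zero. All random streams (subsampling, bootstraps, permutations) are
independently named children of the master seed.

## Problem sizes in the validation battery

The test suite validates estimator properties at deliberately small
scale: 500 replicates for crossnobis unbiasedness (20 units, 40
trials/condition — the same setup `scripts/acceptance.py` reruns), 20
replicates for factorization and matching-contrast recovery (200
pseudo-units via 2 sessions × 100 units), a 4-point lambda grid
(0, 2, 4, 8 Hz against 2 Hz main effects, spanning sub- to
super-dominant interactions), 1,000 all-null simulations for FDR
control, and 10,000 null families for Dunnett familywise error (fast
because the Monte Carlo critical value is computed once and shared).
These sizes were chosen to bound Monte Carlo error well below each
test's decision threshold.

## Known limitations

- Poisson-only noise; no overdispersion or noise-correlation options.
- The Dunnett approximation assumes balanced (or near-balanced) group
  sizes; heavily unbalanced designs should use an exact implementation.
- The within-condition bound requires the matched training size to fit
  inside a CV training fold; with few trials and small K it refuses
  rather than silently under-matching.
- MDS embeddings are defined only up to rotation/reflection; only
  aligned (post-Procrustes) coordinates are comparable across sessions.
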