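# Methods

This note documents the models, the fitting machinery, the synthetic-data
generator, and the numerical and design choices behind `banditfit`, in
enough detail to reproduce or audit any number the package emits.

## Task environment

The restless two-armed bandit presents two options whose hidden reward
probabilities drift independently. The drift is implemented as a Gaussian
random walk with reflecting boundaries: each trial adds a zero-mean
Gaussian step (`step_sd`, default 0.05 probability units) and folds the
result back into `[low, high]` (default `[0.1, 0.9]`). Defaults are 220
trials, binary 1-unit rewards, and a start point drawn uniformly within
the bounds unless fixed. The original study describes the walk only
qualitatively; these defaults preserve its qualitative structure — slow
drifts, occasional reversals of which bandit is better, no absorbing
extremes — and every constant is configurable. Reflection (rather than
clipping or resampling) keeps increments mean-zero in the interior;
consequently step autocorrelation is zero away from the bounds (a
tested property) and slightly negative at them.

All subjects of a cohort share one environment (one pair of walks), as in
the original design. Bandits are labelled 0/1 internally; the trial-table
reader accepts 1/2 labels with a flag, because published worked examples
use 1/2.

## Model families

Both families output action propensities `m_a(t)`, passed through a
softmax with inverse temperature `beta > 0` (`beta = 0` is permitted in
simulation as the pure-chance policy; fitted models use the log
transform, which keeps `beta` strictly positive).

**Rescorla–Wagner.** `Q` initialised at 0.5 for both actions;
`Q_chosen += alpha * (R - Q_chosen)`. Optional terms: choice kernel `b`
added to the propensity of the previously chosen action; forgetting
`phi` relaxing the unchosen `Q` towards 0.5 each trial.

**Bayesian observer.** Beliefs are beta distributions with pseudo-counts
initialised at `gamma = eps = 1` (uniform prior). After an outcome `R` on
chosen bandit `c` with learning rate `omega`:

    gamma_c <- (1 - omega) gamma_c + omega + R
    eps_c   <- (1 - omega) eps_c   + omega + (1 - R)

and for the unchosen bandit with forgetting rate `lambda`, both counts
decay as `x <- (1 - lambda) x + lambda`. The two-parameter variant ties
`lambda = omega`. Counts therefore live in `[1, 1 + 1/omega]`: the upper
bound is the fixed point of the chosen-bandit update, and forgetting only
moves counts towards 1. Expected value and variance are the beta mean and
variance. One published statement puts the *initial* variance at 0.143;
the beta(1,1) variance implied by the variance formula (and by the
worked example's own numbers) is 1/12 ≈ 0.083, and the standard formula
is what the package implements.

Optional propensity terms, all inactive on trial 1 and on the first valid
trial after a missed trial (no previous choice exists; the source is
silent on this corner and this is the conservative reading):

* choice kernel `b` as in the RW family;
* variance term `upsilon * V_a`, applied to the previously chosen
  (`variance="chosen"`) or previously unchosen (`"unchosen"`) bandit;
* confidence term `kappa * Crel(t-1)` applied to the previously unchosen
  bandit, with `Crel = 2 P(theta_chosen > theta_unchosen) - 1`.

**State convention for V and Crel.** The published description is
ambiguous: the results text reads "current variance", while the worked
example computes confidence from the beliefs "at choice on the previous
trial", and its printed unchosen-option variance (0.05) matches only the
previous-trial state (the current-state value is ≈0.061). Both terms
therefore default to the belief state as of the previous trial's choice
(`variance_state="previous"`), which reproduces the worked example
exactly; `variance_state="current"` is available as a configuration
switch and changes the likelihood (a test asserts this).

**Missed trials** trigger no update of either bandit and contribute no
likelihood; after a miss the history-dependent terms restart. Misses are
read from data but never generated by the simulator (agents always
respond).

**Prediction error** `delta = R - Q_chosen` is computed and exported for
both families — for the observer as the discrepancy between the outcome
and the belief mean — because model-derived RPE regressors are a standard
downstream product even when the generating model does not learn from
RPEs.

## The beta-comparison integral

`P(theta_A > theta_B)` for two beta beliefs is the workhorse of the
confidence term (once per trial inside every likelihood evaluation of a
confidence model). Two implementations exist deliberately:

* `confidence()` — the reference scalar API: adaptive quadrature
  (`scipy.integrate.quad`) of `f_1(y) F_0(y)` on [0, 1], absolute
  tolerance 1e-6, raising on failure.
* `prob_greater()` — the vectorised rule used inside likelihoods: a
  Gauss–Legendre rule (48 nodes, or 96 when total pseudo-counts exceed
  18) applied to the antisymmetrised integrand
  `(f_A F_B - f_B F_A)`, whose quadrature equals `2P - 1` by integration
  by parts. The beta CDFs at the nodes are obtained spectrally — a
  precomputed Legendre antiderivative matrix applied to the density
  values — rather than by incomplete-beta evaluations, which is ~6x
  faster and equally accurate. The antisymmetric form guarantees
  `P(A>B) + P(B>A) = 1` to machine precision, making the likelihood
  exactly invariant to relabelling the bandits.

Because beta densities with non-integer exponents have branch points at
the interval ends, fixed-order convergence is algebraic, not geometric:
worst-case absolute error is ~1e-4 for pseudo-counts up to ~25 and
~3e-5 in the regime the update rules actually reach, which is negligible
against the likelihood scale (`beta * kappa * error` per trial). Above a
total count of 200 (reachable only transiently during optimisation at
extreme rate values) both beliefs are effectively Gaussian and a
moment-matched normal approximation is used. Tests pin the vectorised
rule to the adaptive quadrature and to a Monte-Carlo oracle.

## Fitting

Parameters are optimised on an unconstrained scale: log for `beta`,
logit for `alpha`, `phi`, `omega`, `lambda`, identity for `b`,
`upsilon`, `kappa`. The inverse log transform is clamped at `exp(50)` so
optimiser excursions cannot overflow; this is far beyond any behaviourally
distinguishable inverse temperature.

*Subject level.* MAP estimation minimises the negative log joint
(likelihood plus Gaussian prior) with L-BFGS-B from the prior mean, an
optional warm start, and `n_restarts` draws around the prior mean. Draw
sd is capped at 2 on the transformed scale: the initial "flat" prior
(variance 100) is deliberately vague, and sampling restarts from its full
width would start optimisation at numerically absurd parameter values.
The Laplace covariance is the inverse of a central finite-difference
Hessian (step 1e-4 on the transformed scale); a non-positive-definite
Hessian is jittered to the nearest positive-definite matrix and flagged.

*Group level.* EM with an independent Gaussian prior per parameter:
E-step fits every subject (restarts in the first iteration, warm starts
from the previous MAP afterwards); M-step moment-matches,
`mu <- mean(x_i)`, `sigma^2 <- mean(x_i^2 + v_i) - mu^2` with `v_i` the
Laplace variances — the standard update that is exactly unbiased in the
conjugate-Gaussian case. Iteration stops when the largest absolute change
in the prior means drops below `tol` (default 1e-3) or at `max_iter`
(default 50). Group variances are floored at 1e-8 and flagged if hit.
The per-iteration objective (negative sum of Laplace evidences) is
recorded; it is non-increasing up to optimiser tolerance and the tests
assert that. Because likelihood contours correlate parameters (e.g.
`beta` with `alpha`), shrinkage towards the group mean holds in
aggregate per parameter rather than coordinatewise per subject, and the
shrinkage test is formulated accordingly.

A trajectory cache keyed on the data and the rate parameters makes
optimiser steps that only move `beta`, `b`, `upsilon` or `kappa` reuse
the belief trajectory and confidence vector, which is what makes the
grid fits affordable on one core.

## Model comparison

Group evidence per model is estimated by Monte Carlo: for each subject,
the log of the average likelihood over `n_samples` draws (default 1000)
from the fitted group prior, log-sum-exp stabilised, summed over
subjects. A cross-check against the sum of Laplace evidences agrees
within 1% on test cohorts. `iBIC = -2 log Z + 2 k ln N` with `N` the
total count of valid trials and `2k` counting the group mean and
variance per subject-level parameter — the only penalty convention
consistent with the published comparison table (its 5-parameter row
implies a penalty of `10 ln N`). Pseudo-R² is `1 - NLL/(N ln 2)`, the
improvement over the chance policy P = 0.5. Published likelihood values
themselves are inputs, not outputs: absolute likelihoods of the human
cohort cannot be recomputed without the (undeposited) data.

## Synthetic cohorts and calibration

Cohort generation draws each agent's transformed parameters from
independent Gaussians. Defaults for the winning five-parameter observer
are calibrated to the reported fitted-parameter summary of the original
57-subject cohort: the transformed mean is the reported median and the
sd is the reported half-interquartile range divided by 0.6745 (log beta:
2.508 ± 0.687; logit omega: −0.372 ± 1.036; logit lambda: −1.374 ±
0.616; upsilon: −1.069 ± 0.865; kappa: 0.260 ± 0.153). Parameters
without published summaries (RW `alpha`, `b`, `phi`) use values a
practitioner would call typical for this task class (alpha ≈ 0.3, mild
perseveration b ≈ 0.2, phi ≈ 0.2, with moderate spread). Default cohort
size is 30, mirroring the study's per-group sample size.

What the generator emulates: the drifting two-bandit environment, shared
across a cohort; heterogeneous agents with realistic parameter spread;
binary rewards. What it does not: response times, missed trials,
within-session non-stationarity of parameters, and any correlation
between parameters across subjects (the generator draws independently).
Passing recovery tests therefore demonstrate that the pipeline recovers
what the model family can express under the study's design — not that
human data satisfy the model.

## Recovery properties and their limits

With 30 agents × 220 trials under the calibrated winning model, the
hierarchical fit recovers `beta`, `upsilon`, `kappa` strongly
(true-vs-recovered Pearson r ≈ 0.88–0.97 across cohort draws) and the
update rates more weakly (omega r ≈ 0.61–0.91 across draws, lambda r ≈ 0.55–0.58).
The rate attenuation is an identifiability property of the design, not
an estimation defect: the per-subject Laplace sd of logit lambda
(≈ 0.54) is as large as the generative group spread (0.564), capping the
attainable correlation near 0.7 even for an ideal estimator, and the
hierarchical estimates already roughly double the unpooled maximum-
likelihood correlations (omega 0.61 vs 0.42, lambda 0.55 vs 0.24 on a
reference cohort). 220 trials with a few dozen switches simply carry
limited information about how fast the unchosen option's belief decays.

Model recovery uses a reduced four-model grid spanning both families
(`rw`, `rw_kernel`, `bayes`, `bayes_full`) at 8 subjects per replicate
with a shortened EM schedule — sizes chosen so the whole recovery study
runs on one core in minutes while leaving the generating model's
evidence margin over the runner-up at dozens of iBIC points.

## Numerical and edge-case summary

* Softmax via max-subtraction; equal propensities give exactly 0.5.
* Likelihood of an empty (all-missed) sequence is 0 with a warning.
* Exact ties in the behavioural metrics (true-probability ties,
  model-value ties at a switch) count 0.5 — deterministic and unbiased;
  ties are measure-zero under drifting walks.
* Switch counting compares nearest valid choices across misses; the
  adaptive-switch rate is undefined (NaN) for subjects with no switches.
* All randomness flows through explicit integer seeds (`numpy`
  `default_rng` / `SeedSequence`); identical seeds give byte-identical
  simulations, fits and files.
* The published worked example's relative confidence (0.12) is the
  difference of the two printed 2-decimal confidences; the unrounded
  value is 0.1258, and the package reports the comparison at printed
  precision.
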