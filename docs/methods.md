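# Methods

This note documents the models, priors, algorithms and numerical choices
implemented in `shootddm`, and what the synthetic-data validation does and
does not establish.

## The decision model

A trial of the shoot/don't-shoot task is modelled as a one-dimensional
diffusion with unit diffusion coefficient: evidence starts at
`z = beta * alpha` between absorbing boundaries at `0` ("Don't Shoot") and
`alpha` ("Shoot") and drifts at rate `delta` (evidence units per second;
positive toward "Shoot").  The observed response time is the boundary
crossing time plus a non-decision time, `rt = t_d + ndt`.  The four
parameters per subject and condition are:

| parameter | meaning | unit | subject-level bounds |
|---|---|---|---|
| `beta`  | relative start point (bias toward "Shoot" if > .5) | fraction of `alpha` | [.1, .9] |
| `alpha` | threshold separation (speed-accuracy trade-off) | evidence units | (.05, 5] |
| `delta` | drift rate (evidence quality and direction) | evidence / s | [-9, 9] |
| `ndt`   | non-decision time (encoding + motor) | s (ms at I/O) | [0, 1] |

The diffusion coefficient is a free scaling convention; fixing it at 1
with time in seconds puts `alpha` near 1.0-1.4 and `|delta|` near 2 for
this task, which is the parameter regime all defaults assume.  Packages
that fix the diffusion coefficient at 0.1 report all evidence-scale
parameters ten times smaller.

### First-passage density

The lower-boundary density is evaluated through the standard small-time /
large-time series pair, choosing whichever representation needs fewer
terms for the requested truncation error (default `tol = 1e-7`); the
upper boundary follows by the reflection `(beta, delta) -> (1-beta,
-delta)`.  The choice probability has the closed form
`P(upper) = expm1(-2 v a w) / expm1(-2 v a)` (with the `v < 0` branch
mirrored to keep exponents non-positive), and the survivor function
`P(T > t)` is computed from the large-time series integrated term by term,
truncated when terms fall below 1e-12 (at most 1000 terms; for
`t / alpha^2 < 1e-4` the absorbed mass is treated as zero).

### Trial simulator

Trials are simulated by Euler-Maruyama with a default step of 0.25 ms
plus a Brownian-bridge crossing test within each step: after every step
the bridge probability of having touched either boundary,
`exp(-2 (a - x0)(a - x1) / dt)` and `exp(-2 x0 x1 / dt)`, is evaluated and
a crossing sampled accordingly, with the crossing time drawn uniformly
within the step.  The bridge test removes the `O(sqrt(dt))` upward bias
of the naive scheme in choice and censoring probabilities; the remaining
within-step timing error is bounded by the step size.  Simulated choice
frequencies and censoring rates agree with the analytic values within
Monte-Carlo error at n = 20,000 (see the acceptance battery).

### Deadline censoring

Studies that do not record responses beyond the deadline contribute, for
each censored trial, the survivor mass
`1 - F_upper(w) - F_lower(w)` with `w = window - ndt` to the likelihood.
Observed trials contribute the first-passage density at `rt - ndt`; a
response faster than the non-decision time has probability zero (no
contaminant mixture is used).  A deliberately censoring-blind fit (drop
censored trials, keep the same model otherwise) is available to
demonstrate the resulting inflation of drift magnitudes.

## The hierarchy

For each parameter family `theta` in {beta, alpha, delta, ndt} and design
cell `i`, subject `j` has

    theta_{i,j} ~ Normal(mu_i, 1/tau)   truncated to the family bounds,

with one precision `tau` per family (shared across cells, which is what
makes the standardized contrast `d = (mu_A - mu_B) * sqrt(tau)` well
defined).  Group means have uniform hyperpriors over the family bounds
and precisions have Gamma(0.001, 0.001) hyperpriors (shape, rate) — the
standard vague precision prior, chosen because one fixed informative rate
cannot be scale-appropriate simultaneously for drift (group SD ~ 0.6) and
for the start point (group SD ~ 0.06); both constants are overridable in
`PriorConfig`.

Parameter variation follows the task's identifiability structure: start
point and threshold separation may vary over race, context, blur and
study but never over object type (a start point is only identified when
both stimulus classes project to opposite boundaries within a cell);
drift and non-decision time may additionally vary by object.
Between-subject factors enter through subject-to-level assignment in the
trial index; a subject simply has no cells at the other levels.

Subject-level NDT is additionally bounded above by the subject's fastest
observed response.  This constraint is enforced by the likelihood (the
density is zero at `rt <= ndt`) rather than by the prior truncation:
putting it into the truncated-normal prior makes the group-level NDT mean
degenerate (subject values sit against their data-dependent caps and the
truncation normalizer rewards arbitrarily large means), whereas the
likelihood-enforced version has the identical support and recovers
planted NDT means without bias.

## Sampling

The joint posterior is sampled by adaptive random-walk
Metropolis-within-Gibbs, compiled with numba:

* subject-level parameters are updated coordinate-wise against a
  per-trial log-likelihood cache (only the trials a coordinate touches
  are re-evaluated, and only at the proposal);
* group means and precisions (log scale) have prior-only conditionals;
* each cell additionally receives a joint translation move that shifts
  the group mean and all its subject values by one scalar.  This move
  travels along the location ridge that coordinate updates traverse
  slowly and is what keeps split-Rhat of the group means near 1 at a few
  hundred warmup sweeps.

Proposal scales adapt toward a 0.44 acceptance rate in batches of 50
sweeps during warmup only.  Chains are initialized from overdispersed
draws in the plausible region (start point .35-.7, threshold .6-2, drift
±2.5, NDT between 100 ms and 80% of the fastest response), re-drawn until
the posterior is finite; by default 4 chains with 1,000 warmup and 1,000
kept sweeps, though the validation suites use 2 chains and 400-600 sweeps,
which already give split-Rhat <= 1.05 for all group-level means at the
problem sizes used there.  Identical seeds give bit-identical draws.

The signal-detection baseline and any user-supplied log density use a
plain (numpy) adaptive coordinate sampler with optional joint-translation
blocks; the conjugate-normal closed form and the probit closed form serve
as its oracles in the tests.

## Summaries

* **HDI**: shortest contiguous interval containing `ceil(mass * n)` of the
  sorted draws; ties resolve to the earlier interval.
* **Contrasts**: draw-wise cell differences of the group means; the
  standardized effect `d = (mu_A - mu_B) * sqrt(tau)` is computed
  draw-wise as well.  Marginal contrasts average matched cell pairs that
  differ only in the contrasted factor.
* **DIC**: deviance uses the data likelihood only (priors excluded);
  `DIC = D(theta_bar) + 2 p_D`, `p_D = mean deviance - deviance at the
  posterior mean of the subject-level parameters`; if that mean were ever
  outside the support the highest-likelihood draw is substituted.
* **Posterior predictive checks**: full datasets are re-simulated under
  sampled subject-level parameters and the design's own deadlines
  (censoring applied only for studies whose data are censored), and
  compared per drift-cell on shoot proportion, mean correct RT and RT
  deciles against central 95% predictive intervals.

## The signal-detection baseline

Equal-variance SDT with the criterion measured from the midpoint:
`P(hit) = Phi(d'/2 - c)`, `P(false alarm) = Phi(-d'/2 - c)`, binomial
likelihood over per-subject-per-condition counts, hierarchical normal
priors on subject `d'` and `c` with N(0, 3^2) group-mean priors and
Gamma(0.001, 0.001) precisions.  With this sign convention a *negative*
criterion is liberal (a lower bar for "Shoot").  Censored trials are
excluded from the counts by default (`censored_as_error=True` counts them
as misses / correct rejections instead).  Contrasts reuse the same
machinery as the diffusion path.

## Synthetic data and validation

The generator draws subject parameters from truncated normals around
configurable group means and simulates every trial with the subject's
cell-specific parameters.  Defaults (a `TruthConfig`): start point .55
(the payoff matrix rewards shooting), drift +2 / -2 for gun / non-gun,
NDT 300 / 330 ms, threshold separation 1.1 generically and 1.36 / 1.04 /
1.10 / 0.99 in the four study presets (descending with tighter response
windows).  Group SDs — beta .059, alpha .15, delta .58, NDT 45 ms — are
set from the study-level standardized-effect magnitudes reported for this
task (a mean/d pair fixes the group SD, e.g. 0.62/1.07 ~ 0.58 for drift).
Planted condition effects are additive shifts on group-mean cells;
the selective-influence suite uses beta +.05, delta +.5, alpha +.1 on the
race factor, again at the scale of reported effects.

Study presets mirror the four designs: 56x100 at 850 ms and 116x80 at
630 ms with drop-censoring (context between subjects in the second),
38x320 at 750 ms with context and blur within, 108x320 at 630 ms with
context within; the last two record late responses instead of censoring
them.  `censor_mode` distinguishes dropping choice/rt ("drop"), flagging
late trials while keeping their outcomes ("flag"), and recording
everything ("none").  The task's point payoffs (+10 hit, +5 correct
rejection, -20 false alarm, -40 miss) are carried as preset metadata
only.  Ground truth (group means, precisions, subject draws) is returned
as a JSON sidecar keyed by seed.

Validation suites:

* **Selective influence**: replicate datasets with an effect planted in
  one (or two) parameter families; a family is *identified* when the 95%
  HDI of its group-level race contrast, marginalized over the other
  factors, excludes zero.  Run at 20 datasets per setting, 25 subjects x
  80 trials, no deadline.
* **Parameter recovery**: group-mean bias and 95%-HDI coverage plus
  subject-level posterior-mean correlations at a scaled largest-study
  design (40 subjects x 160 trials, race x context x object, 24 group
  means).
* **Censoring direction**: aware vs blind fits of the same drop-censored
  dataset; blind must inflate every drift magnitude.
* **DIC recovery**: data with object-varying NDT (30 ms gap) must prefer
  the object-varying parameterization.

Problem sizes throughout are scaled-down versions of the four designs,
chosen so the whole battery runs on a single CPU in well under an hour;
they are stated alongside every reported rate.

### What the synthetic validation does not show

The generator emulates the *statistical* structure of the task, not its
psychology: stimulus-level variability (specific targets and objects are
repeated in the real task), trial-order and feedback effects of the point
scheme, response-time contaminants (anticipations, lapses), and
trial-to-trial parameter variability are all absent.  Passing recovery
therefore certifies the estimation machinery under the model's own
assumptions, not the adequacy of those assumptions for any real dataset.
Real analyses should lean on the posterior predictive checks, and the
validator's minimum-RT filter (default off) exists because real data
contain anticipatory responses the model assigns zero probability.

## Known limitations

* No trial-by-trial variability in drift, start point or NDT: the
  designs this package targets (many subjects, few trials per cell) do
  not support estimating it.
* A single precision per parameter family assumes homogeneous
  between-subject spread across cells.
* As in any hierarchical model with weakly identified variance
  components, interval calibration for the start-point and threshold
  contrasts degrades at small subject counts (a few dozen): their 95%
  HDIs can exclude a true null somewhat more often than 5%, while drift
  and NDT contrasts stay close to nominal.
* The coordinate sampler's precision draws mix more slowly than the
  means (split-Rhat for `tau` can sit above 1.1 at small subject counts);
  group-mean inferences are robust to this, but precision-based
  quantities (standardized `d`) carry the extra Monte-Carlo noise.
* DIC is reported because it is the conventional criterion for these
  hierarchical fits; it shares the known optimism of plug-in deviance
  criteria and is used here only for coarse model ordering.
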