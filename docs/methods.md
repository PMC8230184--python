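# Methods

## Model

The package implements the standard two-boundary diffusion decision
model.  Within a trial, evidence X(t) starts at z·a and evolves as
dX = v·dt + s·dW with diffusion coefficient fixed at s = 1 (the modern
scaling convention; all drift, threshold and variability values are
interpreted on that scale).  Absorption at a produces a "same"
response, absorption at 0 a "different" response; response time is the
first-passage time plus the non-decision time t0.  Across-trial
variability: drift is Gaussian with SD sv, the start point uniform with
relative width sz.  Drift criterion and non-decision-time variability
are fixed at zero (scaling constraint) and rejected if set otherwise.
The start point z and its variability sz are fractions of a, so a
single start-point parameter remains meaningful when a differs between
updating modes.

Response coding: each design cell carries one drift *magnitude* toward
the correct response.  The signed drift passed to the likelihood is
+magnitude in "same" cells and −magnitude in "different" cells, so a
single z expresses response bias toward "same".

### Likelihood

The first-passage density is evaluated with the classical
small-time/large-time series, choosing per evaluation whichever
representation needs fewer terms for a target truncation error of
1e-8.  Gaussian drift variability is marginalized analytically (the
drift factor of the density is a Gaussian integral with closed form);
start-point variability is marginalized by fixed-order Gauss–Legendre
quadrature (order 11).  Densities are floored at 1e-10 before taking
logs so stray outlier RTs cannot produce infinite deviance.  The
defective CDF and RT quantiles are obtained by trapezoidal integration
of the density on a 4096-point grid whose horizon is chosen from the
slowest series mode so that the truncated tail mass is negligible
(normalization holds to ~1e-6 in practice; the tests require 1e-4).

Absorption probabilities use the closed form for biased diffusion,
with Gauss–Hermite (order 41) marginalization over sv and the same
Gauss–Legendre rule over sz.

### Simulator

`simulate_choice_rt` is deliberately an independent route to the same
distribution: Euler–Maruyama with an exact diffusion-bridge correction
for undetected within-step boundary crossings (crossing probability
exp(−2(a−x₁)(a−x₂)/dt), evaluated only when it exceeds ~1e-9).  The
bridge correction removes the leading O(√dt) crossing bias; at the
default dt = 1e-4 (and at the dt = 2e-4 used in the cross-check tests)
the simulator matches the series density to KS < 0.01 at n = 1e5.
Posterior-predictive simulation uses dt = 5e-4, where the residual
discretization bias is far below posterior and sampling variability.

## Task annotation

Design cells cross updating (red frame → reference, blue → comparison),
switching (frame color change from the previous trial within a block)
and match (probe vs. the referent *before* any update; the referent is
then replaced on red frames only).  The block-initial trial is always
red-framed, provides the first referent, requires no response and is
excluded.  Trial 2 of a block is annotatable: its switch status is
defined relative to the forced red first trial.  This convention is a
declared choice; the alternative (treating trial 2 as unclassifiable)
would discard ~0.8% of trials.

## Cost measures

Six contrasts are computed per subject from per-cell summaries, then
averaged across subjects (subject as the unit of analysis).  Updating
and comparison costs use no-switch trials only; substitution is the
updating × match double difference over all switch levels.  RT costs
are slow-minus-fast differences of mean *correct* RT; whether error
trials belong in the cell mean is not settled usage, and the
correct-trials-only choice is declared here (error RTs still enter the
0.1/0.5/0.9 error quantile summaries).  Accuracy costs are reported on
the easy-minus-hard orientation so positive always means worse
performance in the costly condition.  The RT filter keeps responded
trials with RT in [150 ms, 3 s], bounds inclusive — only strictly
faster/slower responses are outliers.

## Priors

Independent truncated normals on each parameter's support (defaults,
all configurable): v ~ N(2, 3) on (0, 10); a ~ N(1.5, 1) on (0.1, 5);
z ~ N(0.5, 0.2) on (0.05, 0.95); t0 ~ N(0.3, 0.2) on (0.05, 1) seconds;
sv ~ N(1, 1) on (0, 5); sz ~ N(0.2, 0.2) on (0, 0.9).  The joint
constraint z ± sz/2 ∈ (0, 1) is enforced by the posterior support.
Hierarchical hyper-SDs get half-normal(1) priors; hyper-means reuse the
subject-level priors.

## Sampling

Subject-level parameters are sampled with differential-evolution MCMC:
K = 3d interacting chains by default, crossover step γ = 2.38/√(2d)
with small uniform jitter and 10% γ = 1 mode-jumping steps, and a 5%
per-iteration migration step during burn-in only.  Chains are seeded
from moment-based (EZ-style) per-cell estimates of v, a and t0, which
cuts the burn-in needed by an order of magnitude relative to prior
draws.  Default run length is 500 burn-in + 1000 retained iterations.

In the hierarchical sampler the subject-level DE updates alternate with
group-level updates.  The group level does not use DE: because the
truncated-normal population model admits near-conjugate conditionals,
each (hyper-mean, hyper-SD) pair is updated by Metropolis-within-Gibbs
with independence proposals from the untruncated conjugate conditionals
(normal for the mean, inverse-gamma for the variance), corrected by
exact MH ratios for the truncation constants and the half-normal
hyper-SD prior.  This mixes far better than a DE step on the
2d-dimensional group vector: on a 6-subject test problem the median
split-R̂ of the hyper-means drops from ~2.9 to ~1.07 at identical cost.

Hierarchical models of this kind have a funnel geometry: when a
hyper-SD drifts low, subject proposals away from the group mean are
rejected, the apparent between-subject spread shrinks further, and the
chain can stick in an over-shrunk state.  To break this feedback the
sampler adds an interweaving-style *scale move* every third iteration:
per parameter, a log-normal factor c jointly rescales all subject
deviations and the hyper-SD (θ_s → μ + c(θ_s − μ), σ → cσ).  Z-scores
are invariant, so the move slides along the funnel axis; it is accepted
by exact Metropolis–Hastings with the c^(S+1) Jacobian.  In testing
this removed hyper-SD collapse entirely at ~30% extra likelihood cost.
Split-R̂ is reported per parameter (via ArviZ) and downstream analyses
refuse posteriors with any R̂ > 1.1 unless explicitly overridden;
interacting DE chains make R̂ a conservative, approximate diagnostic.

DIC uses the Spiegelhalter form pD = D̄ − D(θ̄) with θ̄ the posterior
mean (falling back to the highest-posterior draw if θ̄ leaves the
support); the hierarchical DIC applies the same form to subject-summed
deviance.  MAP estimates are the retained draw with the highest log
posterior and feed the individual-difference correlations, which use
the non-hierarchical fits to avoid shrinkage-induced dependence.  An
outlying cost value (|z| > 3, configurable) is excluded pairwise from
correlations and logged.

## Synthetic data

The generator reproduces the task design: equiprobable stimuli and
frame colors, red block-initial trials without responses, 512 trials in
4 blocks per subject by default.  Subjects are drawn from truncated
normal population distributions.  The default group plants the
qualitative effect pattern this task is known for, at mid-range values
chosen once as plausible for a practiced young-adult sample: drift
magnitude baseline 3.0 with deficits of 0.5 (reference), 0.9
(mismatch) and 0.3 (switch); non-decision time baseline 300 ms with
costs of 50/20/20 ms; thresholds 1.30 (reference) vs 1.15 (comparison);
z = 0.5, sz = 0.12, sv = 0.8; hyper-SDs 0.4 (v), 0.12 (a), 0.04 (z),
40 ms (t0), 0.25 (sv), 0.04 (sz).  These produce overall accuracy near
90% and mean RTs in the 600–800 ms range — the regime typical of this
paradigm — and are fixture-generating defaults, never empirical
estimates.  Optional contamination adds uniform fast guesses (< 150 ms)
and slow stragglers (3–6 s) at a configurable rate (default 1%) to
exercise the RT filter.

What the generator does *not* emulate: sequential carry-over effects
(priming, task-set inertia, Gratton-type adjustments), response-key
effects, practice/fatigue drifts, and the two-session structure of
multi-session studies.  Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to the misspecifications real data
contain.

## Problem sizes and numerical choices

The test-suite and the acceptance script scale the studies to desk
size, chosen as the package's own defaults for validation work: the
recovery/effect study uses 20 subjects × 512 trials with 63 chains
(3d) and 300 + 130 iterations; null-group calibration uses 10
replicates of 6 subjects × 128 trials; DIC comparison 6 subjects;
posterior predictive checks 100 replicates per subject (the
conventional figure).  Under these conditions pooled subject-level
drift recovery reaches r ≥ 0.9, t0 recovers without material bias, and
roughly 90–96% of subject-level v/a/t0 estimates fall within 2
posterior SDs of truth; median hyper-mean R̂ is ~1.1 at this run
length (a few stragglers higher), so validation analyses that consume
these scaled-down fits pass the explicit override rather than the
strict R̂ ≤ 1.1 gate.  Degenerate cases are defined explicitly: a contrast of
a parameter with itself reports p = 0.5 and Z = 0; Bayesian p is
floored at 0.5/n_draws (no exact zeros); empty cells yield missing
summary markers rather than errors.

## Known limitations

- The Wiener series density assumes st0 = 0; no provision is made for
  uniform non-decision-time variability.
- R̂ on interacting DE chains is approximate; for publication-grade
  inference, run longer chains and verify with independent restarts.
- The hierarchical population model assumes independent truncated
  normals per parameter; correlations between parameters across
  subjects are not modeled.
- Model selection refits each variant independently; no bridge
  sampling or marginal-likelihood alternatives are provided.
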