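# Methods

## Task model

A session is `n_trials = 200` choices between bandits A and B.  Each bandit
has a per-block probability triple over outcomes (−1, 0, +1); blocks are
half-open windows of `block_length = 40` trials (`block = trial // 40`), so
a 200-trial session has 5 blocks.  The packaged default schedule gives the
"good" bandit (0.1, 0.3, 0.6) and the "bad" bandit (0.6, 0.3, 0.1), with
the identities swapping every block so the better option changes over time
while all three outcomes stay observable in every block.  The original
task's exact nominal probabilities are not published; the default is a
stand-in and every consumer accepts an explicit schedule (YAML-configurable
in the pipeline).

## Observation models

Values start at V = (0, 0) — the utility-neutral prior — and only the
chosen bandit's value is updated:

    V_c ← V_c + α (u_t − V_c),  α ∈ [0, 1]

Choice follows a softmax with inverse temperature τ ≥ 0 as a multiplicative
gain (τ = 0 gives uniform choice), computed with max-subtraction so τ·V up
to at least 700 cannot overflow.

The **delta model** uses u = r.  The **reference model** maps outcomes
through the piecewise-linear utility

    u(r) = (r − η)/(η + 1)  for r ≤ η,    u(r) = (r − η)/(1 − η)  for r ≥ η

with η ∈ (−1, 1).  This form realises the intended semantics exactly: it is
anchored at u(−1) = −1, u(η) = 0, u(+1) = +1, is continuous and strictly
increasing in r, makes the sign of the neutral outcome's utility flip with
the sign of η, and places sad and happy at non-equidistant subjective
distances from neutral whenever η ≠ 0.  Other forms with the same anchors
(e.g. sigmoidal) could be substituted behind the same function signature.
Because u ∈ [−1, 1] and the update is a convex combination, values stay in
[−1, 1] on every trajectory.

Both likelihoods replay a recorded session: at each trial the probability of
the recorded choice is taken from the current softmax, then the value is
updated with the recorded outcome's utility.  A brute-force enumeration
oracle over all 2^n choice paths (n ≤ 10) verifies the sequential
implementation to 1e-10 in the tests, and the reference model with η = 0
equals the delta model to machine precision.

## Hierarchical model

Subject s in condition c ∈ {0 = soothe, 1 = keep_happy} has link-scale
parameters

    x_ps = μ_p + β_p c + σ_p z_ps,   z_ps ~ N(0, 1),   p ∈ {α, τ, η}

with α = Φ(x), τ = exp(x), η = 2Φ(x) − 1.  The probit links allow posterior
mass to pile up near α = 1, which these data produce in the happy-baseline
condition.  Hyperpriors: N(0, 1) on μ_p and β_p, half-N(0, 1) on σ_p
(sampled as log σ with the Jacobian).  The condition coefficient β_p enters
all three parameters jointly; natural-scale condition contrasts are formed
per draw as linkinv(μ + β) − linkinv(μ), summarised by the median, 95% HDI
and P(diff > 0) (reported as 0.5 with a degeneracy flag if the difference is
identically zero).  Boundary natural values are clamped at ±8 on the link
scale with a warning.

### Sampler

Adaptive Metropolis-within-Gibbs over the non-centered parameterization,
with per-iteration blocks:

1. per parameter family, a location proposal on (μ_p, β_p) and a separate
   scale proposal on log σ_p (each needs one full-data pass);
2. per subject, a joint random-walk proposal on its z row (one
   subject-data pass);
3. per family, two likelihood-free *interweaving* moves that update the
   population location and scale at fixed natural-scale subject parameters
   (z transforms deterministically, with the (σ_old/σ_new)^n Jacobian).
   These are the centered-parameterization complements of block 1 and are
   what keeps the population SDs mixing when subject parameters are weakly
   identified.

Step sizes adapt toward ~0.3 acceptance by Robbins–Monro during burn-in and
are frozen afterwards.  Chains start from a crude per-subject grid estimate
with per-chain jitter, so split-Rhat is informative.  The whole sweep is
numba-compiled; a 60-subject × 200-trial fit at the default settings takes
well under a minute on one CPU.

Defaults are a desk-scale run: 4 chains × 2,500 iterations, 500 burn-in,
thin 2 (heavier settings, e.g. 11,500/1,500/10, are plain arguments).
Retained draws are exactly `chains × (iterations − burn_in)/thin`.
Correctness is validated three ways in the tests: a conjugate normal–normal
oracle for the generic sampler, simulation-based calibration on
single-subject fits, and agreement of the compiled hierarchical sampler
with the generic sampler on the same joint density.

### Diagnostics

Split-Rhat (chains halved before the between/within comparison; NaN for
zero-variance chains, flagged at ≥ 1.05) and a Geyer initial-positive-pair
ESS, both cross-checked against arviz in the tests.  HDIs are the shortest
contiguous interval containing ⌈0.95 n⌉ sorted draws.

## Model comparison

Marginal likelihoods are estimated on the unconstrained scale (proper
priors, Jacobians included, so no post-hoc correction) by the iterative
optimal-bridge estimator with a moment-matched multivariate-normal
proposal; the proposal is fitted on half the posterior draws and the bridge
identity evaluated on the other half to avoid reuse bias.  Tolerance 1e-10,
max 1,000 iterations, both configurable; non-convergence and regularized
proposal covariances are flagged, and the flag propagates into the Bayes
factor.  On conjugate models the estimator is accurate to ~1e-3 nats; two
independent seeds differ by far less than 0.1.  Because the estimator
integrates over the full parameter space, the reference model's extra
dimensions are charged automatically: on data generated with η = 0 the
log BF_ref,delta is near or below zero (Occam penalty), while data
generated with η = −0.64 at 50 subjects yields log BF ≈ +50.

## Synthetic cohorts

The generator is the fitted model run forwards: subject parameters drawn
from the population on the link scale, choices from the softmax, outcomes
from the schedule.  Cohort defaults mirror the study conditions: 60
subjects per condition, 200 trials, link-scale SDs 0.3, population medians
set through `PopulationParams.from_natural_medians` (the links are
monotone, so the natural median is the link-inverse of the link mean).
Questionnaire totals (age, SMFQ, STAI state/trait, SAPAS, BIS-11, EPDS) are
truncated normals within instrument ranges with means near the published
student-sample descriptives; covariate effects are injected on the link
scale per SD of the z-scored score, matching the linear-predictor form of
the condition effect.  Degenerate agents (always press A) exercise the
exclusion filter deterministically.

What the generator does *not* emulate: item-level questionnaire structure
and reliability, response times, positional or perseverative choice biases,
session-to-session variability.  Passing recovery tests therefore show that
the inference machinery is correct and well calibrated for data that follow
the model, not that real participants do.

## Exclusions and association analyses

Exclusion rules, in precedence order: repeated session; incomplete session
(fewer than the expected 200 trials); same bandit chosen on strictly more
than 75% of trials (exactly 75% is retained).  The filter is idempotent and
order-independent.

Association regressions are two-stage: subject-level posterior medians of
(α, τ, η) on the natural scale are regressed, one mental-health measure at
a time, with age (and condition in two-condition designs) as covariates.
Predictors are z-scored so coefficients are per SD — the scale on which
effects like −0.18 on a [0, 1] learning rate are interpretable.  The
regression is conjugate normal–inverse-gamma (coefficients N(0, 10²σ²),
σ² ~ IG(10⁻³, 10⁻³)) sampled exactly, so results are deterministic under a
seed; complete cases per regression with n reported; no multiple-testing
correction, mirroring per-model credible intervals, with the number of
models run available on request.  If item-level EPDS columns are present, a
variant with anxiety items 3–6 dropped is added.  The stimulus-rating
analysis models the post-task rating on condition (soothe reference) by
default, with post-minus-pre differences as an option (subjects missing a
phase are dropped and counted).

## Problem sizes and numerical choices

Recovery runs use 60 subjects × 200 trials with 4 × 2,500 iterations —
enough for split-Rhat < 1.1 on population parameters and ESS in the
hundreds.  At this cohort size the population reference point is the least
identified quantity: its posterior SD is roughly 0.1 on the natural scale
(the published fits at comparable n show similarly wide HDIs), so recovered
medians scatter by about that much around the generative value across
cohort replicates, while learning-rate and inverse-temperature medians
recover within a few hundredths.  Probability triples must sum to 1 within
1e-12; link round-trips are exact to 1e-10 on the interiors; softmax uses
max-subtraction; τ's link value is capped at 30 before exponentiation
inside the sampler to avoid overflow during early adaptation.

## Known limitations

- The utility's exact published functional form is not available; the
  anchor form above is this package's choice and is stated wherever
  outputs depend on it.
- No choice-kernel/perseveration or separate gain/loss learning rates —
  deliberately restricted to the two-model space under study.
- Bridge-sampling accuracy degrades if the posterior is far from
  unimodal-Gaussian on the unconstrained scale; convergence metadata and
  flags are attached to every estimate.
- The joint hierarchical entry of mental-health covariates (rather than
  two-stage regression on medians) is not implemented.
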