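# banditref

Hierarchical Bayesian reinforcement-learning modelling of an infant-feedback
two-armed bandit task.

## The problem

How do people learn which of two actions best soothes (or keeps happy) a
baby, when the feedback is a crying, neutral or happy infant face?  And does
the infant's *baseline* emotional state change how that feedback is valued?
This package implements the full analysis pipeline for that question, aimed
at computational-psychiatry researchers who want to fit, compare and
validate the models on their own task data — or on synthetic cohorts, since
every stage is testable end-to-end by parameter recovery.

Participants play 200 trials of a two-armed bandit.  Each bandit shows one
of three outcomes, coded r ∈ {−1, 0, +1} (crying, neutral, happy), with
outcome probabilities that switch every 40 trials.  Two conditions differ
only in the baseline face: *soothe* (crying baseline) vs *keep_happy*
(happy baseline).

## The models

Both observation models learn action values with the Rescorla–Wagner rule
and choose through a softmax:

```
V(a) ← V(a) + α (u − V(a)),        P(A) = exp(τ V_A) / (exp(τ V_A) + exp(τ V_B))
```

- **delta model**: utility is the nominal outcome, u = r.
- **reference model**: outcomes pass through a piecewise-linear utility
  anchored at u(−1) = −1, u(η) = 0, u(+1) = +1, where η ∈ (−1, 1) is the
  *reference point* — the emotional intensity experienced as subjectively
  neutral.  η < 0 makes the neutral face feel positive (as after a crying
  baseline); η > 0 makes it feel negative.  η = 0 recovers the delta model
  exactly.

Subject-level parameters (α, τ, η) follow condition-dependent population
distributions on a link scale (probit for α and η, log for τ), fitted by
adaptive MCMC with a non-centered parameterization and interweaved
location/scale moves (numba-compiled).  Models are compared by
bridge-sampling marginal likelihoods (Bayes factor BF_ref,delta), and
subject-level posterior medians are regressed on mental-health scores
(SMFQ, STAI, SAPAS, BIS-11, EPDS) with conjugate Bayesian regressions.

## Worked example

```python
import numpy as np
from banditref import (CohortConfig, PopulationParams, generate_cohort,
                       fit_hierarchical, hdi, condition_contrast)

pop = PopulationParams.from_natural_medians(alpha=0.92, tau=1.20, eta=-0.64,
                                            sigma=0.3)
cohort = generate_cohort(CohortConfig(n_subjects_per_condition=60,
                                      conditions=("soothe",),
                                      population=pop, seed=42))
fit = fit_hierarchical(cohort.datasets, model="reference", seed=1)
for p in ("alpha", "tau", "eta"):
    d = fit.population_natural(p, "soothe")
    h = hdi(d)
    print(f"{p}: median {np.median(d):.3f}  95% HDI ({h.lower:.3f}, {h.upper:.3f})")
```

prints (population natural-scale summaries; generative truth 0.92 / 1.20 / −0.64):

```
alpha: median 0.928  95% HDI (0.877, 0.976)
tau: median 1.140  95% HDI (1.056, 1.232)
eta: median -0.691  95% HDI (-0.948, -0.468)
```

i.e. the hierarchical fit recovers the generating population learning rate,
inverse temperature and reference point of a 60-subject cohort, with the
reference point the most uncertain of the three (its posterior width is a
genuine property of this cohort size, not of the sampler).

The same pipeline runs from the shell:

```
banditref simulate --n-per-condition 30 --seed 1 --out runs/demo
banditref fit --trials runs/demo/trials.csv --model reference --out runs/demo/draws.csv
banditref run-all --config pipeline.yaml
```

## Layout

- `src/banditref/task.py` — bandit structure, reward schedules, trials I/O
- `src/banditref/models.py` — utilities, RW updates, softmax, likelihoods
- `src/banditref/cohort.py` — synthetic cohorts with covariate effects
- `src/banditref/inference.py` — hierarchical MCMC, diagnostics, HDI, contrasts
- `src/banditref/comparison.py` — bridge sampling and Bayes factors
- `src/banditref/associations.py` — exclusions, regressions, rating analysis
- `src/banditref/pipeline.py`, `cli.py` — orchestration and the `banditref` CLI

See `docs/methods.md` for the modelling details and design choices.
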