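"""Synthetic cohorts of simulated bandit-task participants.

Each simulated subject plays the task with the same reference-point learner
used for fitting, with subject-level (alpha, tau, eta) drawn from a
condition-dependent population distribution on the link scale.  Optional
covariate effects tilt individual parameters linearly (per SD of the
z-scored covariate, on the link scale), and optional degenerate agents
press the same bandit on every trial to exercise the exclusion filter.

Questionnaire totals (SMFQ, STAI state/trait, SAPAS, BIS-11, EPDS) are
drawn from truncated normals within each instrument's score range; their
psychometric structure is not modelled — only their linear link to the
learning parameters matters downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .inference import PARAM_NAMES, PopulationParams, link_inverse
from .models import ModelParams, _utility_scalar
from .task import (
    BANDITS,
    CONDITIONS,
    RewardSchedule,
    SubjectDataset,
    TrialRecord,
    default_schedule,
    sample_outcome,
)

__all__ = [
    "CovariateSpec",
    "DEFAULT_COVARIATES",
    "CohortConfig",
    "CohortResult",
    "sample_subject_parameters",
    "simulate_subject",
    "generate_cohort",
    "write_covariates",
    "read_covariates",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: a truncated-normal score distribution plus its
    link-scale effects (per SD) on named learning parameters."""

    name: str
    mean: float
    sd: float
    lower: float
    upper: float
    effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.effects:
            if p not in PARAM_NAMES:
                raise ValueError(f"effect targets unknown parameter {p!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


def _default_covariates() -> list[CovariateSpec]:
    # score distributions loosely follow the student-sample descriptives
    return [
        CovariateSpec("age", 19.8, 2.7, 18, 50),
        CovariateSpec("smfq", 7.0, 4.5, 0, 26),
        CovariateSpec("stai_s", 39.0, 10.0, 20, 80),
        CovariateSpec("stai_t", 46.0, 10.0, 20, 80),
        CovariateSpec("sapas", 3.0, 1.5, 0, 8),
        CovariateSpec("bis", 64.0, 8.0, 30, 120),
        CovariateSpec("epds", 13.0, 4.0, 0, 30),
    ]


DEFAULT_COVARIATES = _default_covariates()


@dataclass
class CohortConfig:
    n_subjects_per_condition: int = 60
    conditions: tuple = CONDITIONS
    schedule: RewardSchedule | None = None
    population: PopulationParams | None = None
    covariates: list[CovariateSpec] = field(default_factory=_default_covariates)
    n_degenerate_agents: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_condition < 1:
            raise ValueError("n_subjects_per_condition must be >= 1")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
        if self.schedule is None:
            self.schedule = default_schedule()
        if self.population is None:
            self.population = PopulationParams(
                mu={"alpha": 0.5, "tau": 0.2, "eta": 0.0},
                sigma={p: 0.3 for p in PARAM_NAMES},
            )

    def hash(self) -> str:
        payload = {
            "n": self.n_subjects_per_condition,
            "conditions": list(self.conditions),
            "schedule": {
                "n_trials": self.schedule.n_trials,
                "block_length": self.schedule.block_length,
                "probs": self.schedule.probs.tolist(),
            },
            "population": {
                "mu": self.population.mu,
                "sigma": self.population.sigma,
                "beta_cond": self.population.beta_cond,
            },
            "covariates": [asdict(c) for c in self.covariates],
            "n_degenerate": self.n_degenerate_agents,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def sample_subject_parameters(
    population: PopulationParams,
    condition: str,
    covariate_effects: float | dict | None,
    rng: np.random.Generator,
) -> ModelParams:
    """Draw one subject's (alpha, tau, eta) from the population.

    The link-scale predictor is mean + condition coefficient x condition
    code + covariate contribution + sigma x N(0,1), then mapped to the
    natural scale, so ranges are guaranteed.  ``covariate_effects`` maps a
    parameter name to its summed link-scale covariate contribution for this
    subject (or None for none).
    """
    c = CONDITIONS.index(condition)
    shift = covariate_effects or {}
    x = []
    for p in PARAM_NAMES:
        loc = population.mu[p] + population.beta_cond[p] * c + shift.get(p, 0.0)
        x.append(loc + population.sigma[p] * rng.standard_normal())
    a, t, e = link_inverse(*x)
    e = min(max(e, -1 + 1e-12), 1 - 1e-12)
    return ModelParams(alpha=a, tau=t, eta=e)


def simulate_subject(
    params: ModelParams,
    schedule: RewardSchedule,
    condition: str,
    rng: np.random.Generator,
    subject_id: str = "sim",
    fixed_choice: str | None = None,
) -> SubjectDataset:
    """Simulate one session: softmax choices, scheduled outcomes,
    reference-point value updates.  ``fixed_choice`` produces a degenerate
    agent that ignores its values and always presses the same bandit.
    """
    v = [0.0, 0.0]
    trials = []
    for t in range(schedule.n_trials):
        if fixed_choice is not None:
            c = BANDITS.index(fixed_choice)
        else:
            d = params.tau * (v[0] - v[1])
            p_a = 1.0 / (1.0 + np.exp(-d)) if d > -700 else 0.0
            c = 0 if rng.random() < p_a else 1
        outcome = sample_outcome(schedule, t, BANDITS[c], rng)
        u = _utility_scalar(float(outcome), params.eta)
        v[c] += params.alpha * (u - v[c])
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                condition=condition,
                trial_index=t,
                block_index=schedule.block_of(t),
                choice=BANDITS[c],
                outcome=outcome,
            )
        )
    return SubjectDataset(subject_id, condition, trials)


@dataclass
class CohortResult:
    datasets: list[SubjectDataset]
    covariates: pd.DataFrame
    provenance: dict

    def __iter__(self):
        return iter((self.datasets, self.covariates))


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Generate a full synthetic cohort (trial data + covariate table).

    Deterministic under ``config.seed``; the provenance dict records the
    seed and a hash of the full configuration.  Degenerate always-same-
    bandit agents are appended after the regular subjects (alternating
    conditions, fixed bandit A) and carry NaN generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    n_per = config.n_subjects_per_condition
    subjects = []  # (subject_id, condition, fixed_choice)
    for cond in config.conditions:
        for i in range(n_per):
            subjects.append((f"{cond}_{i:03d}", cond, None))
    for i in range(config.n_degenerate_agents):
        cond = config.conditions[i % len(config.conditions)]
        subjects.append((f"degenerate_{i:03d}", cond, "A"))

    n_total = len(subjects)
    cov_values = {spec.name: spec.sample(n_total, rng) for spec in config.covariates}
    cov_z = {}
    for name, vals in cov_values.items():
        sd = vals.std(ddof=0)
        cov_z[name] = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)

    datasets = []
    rows = []
    for idx, (sid, cond, fixed) in enumerate(subjects):
        shift = {p: 0.0 for p in PARAM_NAMES}
        for spec in config.covariates:
            for p, eff in spec.effects.items():
                shift[p] += eff * cov_z[spec.name][idx]
        params = sample_subject_parameters(config.population, cond, shift, rng)
        datasets.append(
            simulate_subject(
                params, config.schedule, cond, rng, subject_id=sid, fixed_choice=fixed
            )
        )
        row = {"subject_id": sid, "condition": cond}
        row.update({name: cov_values[name][idx] for name in cov_values})
        if fixed is None:
            row.update(
                true_alpha=params.alpha, true_tau=params.tau, true_eta=params.eta
            )
        else:
            row.update(true_alpha=np.nan, true_tau=np.nan, true_eta=np.nan)
        rows.append(row)

    covariates = pd.DataFrame(rows)
    provenance = {"seed": config.seed, "config_hash": config.hash(), "n_subjects": n_total}
    return CohortResult(datasets, covariates, provenance)


def write_covariates(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError(f"covariates file {path} is missing 'subject_id'")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate covariate row for subject {dup}")
    return df
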