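"""Cognitive observation models for the two-armed infant-feedback bandit.

Two nested models describe trial-by-trial choice:

* **delta model** — Rescorla–Wagner value learning on the nominal outcomes
  (−1 sad, 0 neutral, +1 happy) with a softmax choice rule.
* **reference model** — the same learner, but outcomes are first passed
  through a piecewise-linear utility with a reference point ``eta``: the
  emotional intensity that is subjectively experienced as neutral.  The
  utility is anchored at u(−1) = −1, u(eta) = 0 and u(+1) = +1, so a
  negative reference point makes the nominal-neutral outcome feel positive
  and vice versa.  Setting eta = 0 recovers the delta model exactly.

All functions here are pure and deterministic; the sequential likelihood is
compiled with numba so hierarchical fits stay cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "ModelParams",
    "LearnerState",
    "utility",
    "rw_update",
    "choice_probabilities",
    "subject_log_likelihood",
    "enumerate_path_probabilities",
]

MODELS = ("delta", "reference")


@dataclass(frozen=True)
class ModelParams:
    """Subject-level parameters.

    alpha : learning rate in [0, 1]
    tau   : softmax inverse temperature, >= 0 (0 = random choice)
    eta   : reference point in (−1, 1); fixed at 0 for the delta model
    """

    alpha: float
    tau: float
    eta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.tau < 0.0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if not -1.0 < self.eta < 1.0:
            raise ValueError(f"eta must be in (-1, 1), got {self.eta}")


@dataclass
class LearnerState:
    """Current value estimates (V_A, V_B); initialised at (0, 0)."""

    v_a: float = 0.0
    v_b: float = 0.0


@njit(cache=True)
def _utility_scalar(r: float, eta: float) -> float:
    if r <= eta:
        return (r - eta) / (eta + 1.0)
    return (r - eta) / (1.0 - eta)


def utility(outcome, eta: float):
    """Map a nominal outcome in {−1, 0, +1} to subjective utility in [−1, 1].

    Piecewise linear with anchors u(−1) = −1, u(eta) = 0, u(+1) = +1;
    continuous and strictly increasing in the outcome.
    """
    if not -1.0 < eta < 1.0:
        raise ValueError(f"eta must be in (-1, 1), got {eta}")
    r = np.asarray(outcome, dtype=float)
    out = np.where(r <= eta, (r - eta) / (eta + 1.0), (r - eta) / (1.0 - eta))
    if np.ndim(outcome) == 0:
        return float(out)
    return out


def rw_update(state: LearnerState, choice: str, u: float, alpha: float) -> LearnerState:
    """Rescorla–Wagner update: V_chosen += alpha * (u − V_chosen)."""
    if choice == "A":
        return LearnerState(state.v_a + alpha * (u - state.v_a), state.v_b)
    if choice == "B":
        return LearnerState(state.v_a, state.v_b + alpha * (u - state.v_b))
    raise ValueError(f"choice must be 'A' or 'B', got {choice!r}")


def choice_probabilities(state: LearnerState, tau: float) -> tuple[float, float]:
    """Softmax choice probabilities (p_A, p_B) with inverse temperature tau.

    Computed with max-subtraction so large tau*V never overflows.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    x_a, x_b = tau * state.v_a, tau * state.v_b
    m = max(x_a, x_b)
    e_a, e_b = math.exp(x_a - m), math.exp(x_b - m)
    z = e_a + e_b
    return e_a / z, e_b / z


@njit(cache=True)
def _loglik_core(
    choices: np.ndarray, outcomes: np.ndarray, alpha: float, tau: float, eta: float, use_eta: bool
) -> float:
    """Sequential log-likelihood of recorded choices (0 = A, 1 = B)."""
    v_a = 0.0
    v_b = 0.0
    ll = 0.0
    for t in range(choices.shape[0]):
        x_a = tau * v_a
        x_b = tau * v_b
        m = x_a if x_a > x_b else x_b
        log_z = m + math.log(math.exp(x_a - m) + math.exp(x_b - m))
        if choices[t] == 0:
            ll += x_a - log_z
        else:
            ll += x_b - log_z
        r = float(outcomes[t])
        u = _utility_scalar(r, eta) if use_eta else r
        if choices[t] == 0:
            v_a += alpha * (u - v_a)
        else:
            v_b += alpha * (u - v_b)
    return ll


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept a SubjectDataset or a (choices, outcomes) pair of arrays."""
    if isinstance(dataset, tuple):
        choices, outcomes = dataset
    else:
        choices, outcomes = dataset.choice_array(), dataset.outcome_array()
    return np.asarray(choices, dtype=np.int64), np.asarray(outcomes, dtype=np.int64)


def subject_log_likelihood(dataset, params: ModelParams, model: str = "reference") -> float:
    """Log-likelihood (nats) of one subject's choice sequence under a model.

    Replays the dataset: at each trial the probability of the recorded
    choice is taken from the current softmax, then values are updated with
    the recorded outcome's utility.  ``model='delta'`` uses the identity
    utility (eta forced to 0), so the two models agree exactly at eta = 0.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    choices, outcomes = _as_arrays(dataset)
    if choices.size == 0:
        raise ValueError("empty dataset has no likelihood")
    use_eta = model == "reference"
    eta = params.eta if use_eta else 0.0
    return float(_loglik_core(choices, outcomes, params.alpha, params.tau, eta, use_eta))


def enumerate_path_probabilities(
    outcomes_by_path, params: ModelParams, model: str = "reference"
) -> dict[tuple[int, ...], float]:
    """Brute-force distribution over all 2^n choice sequences (test oracle).

    ``outcomes_by_path`` is either a fixed outcome sequence (array-like,
    applied regardless of choice) or a callable ``(path) -> outcome list``
    conditioning outcomes on the choice path.  Refuses n > 10.
    """
    if callable(outcomes_by_path):
        probe = outcomes_by_path(())
        n = len(probe)
        get_outcomes = outcomes_by_path
    else:
        fixed = np.asarray(outcomes_by_path, dtype=np.int64)
        n = fixed.shape[0]

        def get_outcomes(path):
            return fixed

    if n > 10:
        raise ValueError(f"enumeration limited to n <= 10 trials, got {n}")

    out: dict[tuple[int, ...], float] = {}
    for bits in range(2**n):
        path = tuple((bits >> t) & 1 for t in range(n))
        outcomes = np.asarray(get_outcomes(path), dtype=np.int64)
        ll = subject_log_likelihood((np.asarray(path, dtype=np.int64), outcomes), params, model)
        out[path] = math.exp(ll)
    return out
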