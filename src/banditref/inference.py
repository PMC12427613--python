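"""Hierarchical Bayesian inference for the bandit learning models.

Subject-level parameters are drawn from condition-dependent population
distributions on an unconstrained ("link") scale:

    alpha = Phi(x),  tau = exp(x),  eta = 2 Phi(x) - 1

with, for each parameter p and subject s in condition c in {0, 1},

    link_p(theta_ps) = mu_p + beta_p * c + sigma_p * z_ps,   z_ps ~ N(0, 1)

(non-centered parameterization).  Hyperpriors are Normal(0, 1) on the
population means mu_p and condition coefficients beta_p, and half-Normal(0, 1)
on the population SDs sigma_p.  The condition coefficient beta_p measures the
link-scale shift of the population mean in the ``keep_happy`` condition
relative to the ``soothe`` reference.

Sampling uses adaptive Metropolis-within-Gibbs: one proposal block per
population-parameter family and one per subject, with per-block step sizes
tuned by Robbins–Monro during burn-in and frozen afterwards.  The whole
chain sweep is compiled with numba.  Posterior correctness is validated
against a conjugate closed form and by simulation-based calibration in the
test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import ndtr, ndtri

from .models import _loglik_core
from .task import CONDITIONS, SubjectDataset, default_schedule

__all__ = [
    "PARAM_NAMES",
    "LINK_CLAMP",
    "PopulationParams",
    "PosteriorSamples",
    "Diagnostics",
    "HdiInterval",
    "ConditionContrast",
    "link_forward",
    "link_inverse",
    "hierarchical_log_posterior",
    "run_mcmc",
    "fit_hierarchical",
    "split_rhat",
    "effective_sample_size",
    "hdi",
    "condition_contrast",
    "sbc_ranks",
]

PARAM_NAMES = ("alpha", "tau", "eta")
LINK_CLAMP = 8.0  # boundary natural values map to +/- this on the link scale
RHAT_WARN = 1.05


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------

def link_forward(alpha: float, tau: float, eta: float) -> tuple[float, float, float]:
    """Map natural-scale (alpha, tau, eta) to the unconstrained link scale.

    alpha via the probit (inverse standard-normal CDF), tau via log, eta via
    the probit of (eta+1)/2.  Boundary values (alpha in {0, 1}, tau = 0,
    |eta| = 1) would map to infinity and are clamped at +/-LINK_CLAMP with a
    warning.
    """
    def _probit(p):
        x = ndtri(p)
        if not np.isfinite(x) or abs(x) > LINK_CLAMP:
            warnings.warn("boundary value clamped on the link scale", stacklevel=3)
            return math.copysign(LINK_CLAMP, x if x != 0 else p - 0.5)
        return float(x)

    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if tau < 0.0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    if not -1.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [-1, 1], got {eta}")
    x_a = _probit(alpha)
    if tau == 0.0:
        warnings.warn("boundary value clamped on the link scale", stacklevel=2)
        x_t = -LINK_CLAMP
    else:
        x_t = min(max(math.log(tau), -LINK_CLAMP), LINK_CLAMP)
    x_e = _probit((eta + 1.0) / 2.0)
    return x_a, x_t, x_e


def link_inverse(x_alpha: float, x_tau: float, x_eta: float) -> tuple[float, float, float]:
    """Inverse of :func:`link_forward` (exact on the interiors)."""
    return float(ndtr(x_alpha)), float(np.exp(x_tau)), float(2.0 * ndtr(x_eta) - 1.0)


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameters on the link scale.

    ``mu``, ``sigma`` and ``beta_cond`` each map parameter name ->
    link-scale value; ``beta_cond`` is the keep_happy-minus-soothe shift of
    the population mean and is 0 when only one condition is modelled.
    """

    mu: dict
    sigma: dict
    beta_cond: dict = field(default_factory=lambda: {p: 0.0 for p in PARAM_NAMES})

    def __post_init__(self) -> None:
        for p in PARAM_NAMES:
            if p not in self.mu or p not in self.sigma:
                raise ValueError(f"population parameters must include {p!r}")
            if self.sigma[p] < 0:
                raise ValueError(f"sigma[{p!r}] must be >= 0")

    @classmethod
    def from_natural_medians(
        cls,
        alpha: float,
        tau: float,
        eta: float,
        sigma: float = 0.3,
        beta_cond: dict | None = None,
    ) -> "PopulationParams":
        """Population whose natural-scale medians equal the given values.

        The links are monotone, so the natural median is the link-inverse of
        the link-scale mean regardless of sigma.
        """
        x_a, x_t, x_e = link_forward(alpha, tau, eta)
        return cls(
            mu={"alpha": x_a, "tau": x_t, "eta": x_e},
            sigma={p: float(sigma) for p in PARAM_NAMES},
            beta_cond=beta_cond or {p: 0.0 for p in PARAM_NAMES},
        )

    def natural_medians(self, condition_code: int = 0) -> dict:
        x = [
            self.mu[p] + self.beta_cond[p] * condition_code for p in PARAM_NAMES
        ]
        a, t, e = link_inverse(*x)
        return {"alpha": a, "tau": t, "eta": e}


# ---------------------------------------------------------------------------
# Data packing and joint log posterior
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_LOG_HALF_NORMAL = 0.5 * math.log(2.0 / math.pi)


def _pack(datasets: list[SubjectDataset]):
    n = len(datasets)
    offsets = np.zeros(n + 1, dtype=np.int64)
    for i, d in enumerate(datasets):
        offsets[i + 1] = offsets[i] + len(d)
    choices = np.concatenate([d.choice_array() for d in datasets])
    outcomes = np.concatenate([d.outcome_array() for d in datasets])
    cond = np.array(
        [CONDITIONS.index(d.condition) for d in datasets], dtype=np.float64
    )
    return choices, outcomes, offsets, cond


@njit(cache=True)
def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _subject_natural(mu, beta, lsig, z_row, c, use_eta):
    xa = mu[0] + beta[0] * c + math.exp(lsig[0]) * z_row[0]
    xt = mu[1] + beta[1] * c + math.exp(lsig[1]) * z_row[1]
    if xt > 30.0:
        xt = 30.0
    alpha = _phi(xa)
    tau = math.exp(xt)
    eta = 0.0
    if use_eta:
        xe = mu[2] + beta[2] * c + math.exp(lsig[2]) * z_row[2]
        eta = 2.0 * _phi(xe) - 1.0
        if eta <= -1.0:
            eta = -1.0 + 1e-12
        elif eta >= 1.0:
            eta = 1.0 - 1e-12
    return alpha, tau, eta


@njit(cache=True)
def _all_logliks(mu, beta, lsig, z, cond, choices, outcomes, offsets, use_eta, out):
    n = offsets.shape[0] - 1
    for s in range(n):
        a, t, e = _subject_natural(mu, beta, lsig, z[s], cond[s], use_eta)
        out[s] = _loglik_core(
            choices[offsets[s] : offsets[s + 1]],
            outcomes[offsets[s] : offsets[s + 1]],
            a,
            t,
            e,
            use_eta,
        )


def _pop_log_prior(mu, beta, lsig, two_cond: bool) -> float:
    lp = float(np.sum(-0.5 * mu**2 - _LOG_SQRT_2PI))
    if two_cond:
        lp += float(np.sum(-0.5 * beta**2 - _LOG_SQRT_2PI))
    sigma = np.exp(lsig)
    # half-Normal(0,1) on sigma plus the log-Jacobian of sigma = exp(lsig)
    lp += float(np.sum(_LOG_HALF_NORMAL - 0.5 * sigma**2 + lsig))
    return lp


def _unpack_vector(vec: np.ndarray, n_subjects: int, n_params: int, two_cond: bool):
    k = 0
    mu = vec[k : k + n_params]
    k += n_params
    if two_cond:
        beta = vec[k : k + n_params]
        k += n_params
    else:
        beta = np.zeros(n_params)
    lsig = vec[k : k + n_params]
    k += n_params
    z = vec[k : k + n_subjects * n_params].reshape(n_subjects, n_params)
    return mu, beta, lsig, z


def _vector_dim(n_subjects: int, n_params: int, two_cond: bool) -> int:
    return n_params * (3 if two_cond else 2) + n_subjects * n_params


def hierarchical_log_posterior(
    datasets: list[SubjectDataset],
    vector: np.ndarray,
    model: str = "reference",
    loglik_fn=None,
) -> float:
    """Joint log density of the hierarchical model at an unconstrained state.

    The state vector is [mu (P), beta (P, only with two conditions),
    log sigma (P), z (n_subjects x P, row-major)] where P = 3 for the
    reference model and 2 for the delta model.  The density is fully
    normalized over the unconstrained space (priors proper, Jacobians
    included), as required for marginal-likelihood estimation.

    ``loglik_fn(dataset_index, alpha, tau, eta) -> float`` may replace the
    bandit likelihood (used by the conjugate validation tests).  Returns
    ``-inf`` for non-finite states.
    """
    use_eta = model == "reference"
    n_params = 3 if use_eta else 2
    n = len(datasets)
    conds = {d.condition for d in datasets}
    two_cond = len(conds) == 2
    vec = np.asarray(vector, dtype=float)
    if vec.shape != (_vector_dim(n, n_params, two_cond),):
        raise ValueError(
            f"expected state vector of length {_vector_dim(n, n_params, two_cond)}, "
            f"got {vec.shape}"
        )
    if not np.all(np.isfinite(vec)):
        return -math.inf
    mu, beta, lsig, z = _unpack_vector(vec, n, n_params, two_cond)
    mu3 = np.zeros(3)
    beta3 = np.zeros(3)
    lsig3 = np.zeros(3)
    mu3[:n_params] = mu
    beta3[:n_params] = beta
    lsig3[:n_params] = lsig

    lp = _pop_log_prior(mu, beta, lsig, two_cond)
    lp += float(np.sum(-0.5 * z**2 - _LOG_SQRT_2PI))
    if n == 0:
        return lp

    if loglik_fn is None:
        choices, outcomes, offsets, cond = _pack(datasets)
        ll = np.empty(n)
        z3 = np.zeros((n, 3))
        z3[:, :n_params] = z
        _all_logliks(mu3, beta3, lsig3, z3, cond, choices, outcomes, offsets, use_eta, ll)
        lp += float(ll.sum())
    else:
        for s, d in enumerate(datasets):
            c = float(CONDITIONS.index(d.condition))
            z_row = np.zeros(3)
            z_row[:n_params] = z[s]
            a, t, e = _subject_natural(mu3, beta3, lsig3, z_row, c, use_eta)
            lp += float(loglik_fn(s, a, t, e))
    if not np.isfinite(lp):
        return -math.inf
    return lp


@njit(cache=True)
def _joint_log_posterior_batch(
    states, choices, outcomes, offsets, cond, use_eta, two_cond, out
):
    """Fully-normalized joint log density for a batch of state vectors."""
    n_params = 3 if use_eta else 2
    n = offsets.shape[0] - 1
    log_sqrt_2pi = 0.5 * math.log(2.0 * math.pi)
    log_half_normal = 0.5 * math.log(2.0 / math.pi)
    mu3 = np.zeros(3)
    beta3 = np.zeros(3)
    lsig3 = np.zeros(3)
    z_row = np.zeros(3)
    for i in range(states.shape[0]):
        vec = states[i]
        k = 0
        lp = 0.0
        for p in range(n_params):
            mu3[p] = vec[k]
            lp += -0.5 * mu3[p] * mu3[p] - log_sqrt_2pi
            k += 1
        if two_cond:
            for p in range(n_params):
                beta3[p] = vec[k]
                lp += -0.5 * beta3[p] * beta3[p] - log_sqrt_2pi
                k += 1
        else:
            for p in range(n_params):
                beta3[p] = 0.0
        for p in range(n_params):
            lsig3[p] = vec[k]
            sig = math.exp(lsig3[p])
            lp += log_half_normal - 0.5 * sig * sig + lsig3[p]
            k += 1
        for s in range(n):
            for p in range(n_params):
                z_row[p] = vec[k + p]
                lp += -0.5 * z_row[p] * z_row[p] - log_sqrt_2pi
            k += n_params
            a, t, e = _subject_natural(mu3, beta3, lsig3, z_row, cond[s], use_eta)
            lp += _loglik_core(
                choices[offsets[s] : offsets[s + 1]],
                outcomes[offsets[s] : offsets[s + 1]],
                a,
                t,
                e,
                use_eta,
            )
        out[i] = lp


class HierarchicalLogPosterior:
    """Callable joint log posterior with a fast batched path.

    Built once per dataset collection; ``__call__`` evaluates one state
    vector, ``batch`` evaluates a (N, dim) array of states (numba path).
    """

    def __init__(self, datasets: list[SubjectDataset], model: str = "reference"):
        self.model = model
        self.use_eta = model == "reference"
        self.n_params = 3 if self.use_eta else 2
        self.choices, self.outcomes, self.offsets, self.cond = _pack(datasets)
        self.two_cond = len(np.unique(self.cond)) == 2
        self.n_subjects = len(datasets)
        self.dim = _vector_dim(self.n_subjects, self.n_params, self.two_cond)

    def batch(self, states: np.ndarray) -> np.ndarray:
        states = np.ascontiguousarray(np.atleast_2d(states), dtype=np.float64)
        if states.shape[1] != self.dim:
            raise ValueError(f"expected state dimension {self.dim}, got {states.shape[1]}")
        out = np.empty(states.shape[0])
        finite = np.all(np.isfinite(states), axis=1)
        _joint_log_posterior_batch(
            states,
            self.choices,
            self.outcomes,
            self.offsets,
            self.cond,
            self.use_eta,
            self.two_cond,
            out,
        )
        out[~finite] = -np.inf
        out[~np.isfinite(out)] = -np.inf
        return out

    def __call__(self, vector: np.ndarray) -> float:
        return float(self.batch(np.asarray(vector, dtype=float)[None, :])[0])


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

@njit(cache=True)
def _hier_chain(
    choices,
    outcomes,
    offsets,
    cond,
    use_eta,
    two_cond,
    n_iter,
    burn_in,
    thin,
    seed,
    mu0,
    beta0,
    lsig0,
    z0,
):
    """One adaptive Metropolis-within-Gibbs chain; returns thinned states.

    Blocks: for each parameter family p, a joint proposal on
    (mu_p, beta_p, log sigma_p); then for each subject a joint proposal on
    its z row.  Step sizes adapt toward ~0.3 acceptance during burn-in only.
    """
    np.random.seed(seed)
    n_params = 3 if use_eta else 2
    n = offsets.shape[0] - 1
    mu = mu0.copy()
    beta = beta0.copy()
    lsig = lsig0.copy()
    z = z0.copy()

    mu3 = np.zeros(3)
    beta3 = np.zeros(3)
    lsig3 = np.zeros(3)
    z3 = np.zeros((n, 3))
    for p in range(n_params):
        mu3[p] = mu[p]
        beta3[p] = beta[p]
        lsig3[p] = lsig[p]
        for s in range(n):
            z3[s, p] = z[s, p]

    ll = np.empty(n)
    _all_logliks(mu3, beta3, lsig3, z3, cond, choices, outcomes, offsets, use_eta, ll)
    new_ll = np.empty(n)

    log_step_pop = np.full(n_params, math.log(0.08))
    log_step_pop_scale = np.full(n_params, math.log(0.3))
    log_step_rep = np.full(n_params, math.log(0.15))
    log_step_scale = np.full(n_params, math.log(0.3))
    log_step_z = np.full(n, math.log(0.3))
    target = 0.3
    z_prop = np.empty(n)

    n_pop_cols = n_params * (3 if two_cond else 2)
    dim = n_pop_cols + n * n_params
    n_keep = (n_iter - burn_in + thin - 1) // thin
    out = np.empty((n_keep, dim))
    kept = 0

    for it in range(n_iter):
        gamma = 0.0
        if it < burn_in:
            gamma = min(0.25, 2.0 / math.sqrt(1.0 + it))

        # -- population blocks (non-centered; each needs a data pass) -----
        for p in range(n_params):
            # location sub-block: (mu_p, beta_p)
            step = math.exp(log_step_pop[p])
            dmu = np.random.normal(0.0, step)
            dbeta = np.random.normal(0.0, step) if two_cond else 0.0
            mu_new = mu3[p] + dmu
            beta_new = beta3[p] + dbeta
            d_prior = -0.5 * (mu_new * mu_new - mu3[p] * mu3[p])
            if two_cond:
                d_prior += -0.5 * (beta_new * beta_new - beta3[p] * beta3[p])
            old_mu = mu3[p]
            old_beta = beta3[p]
            mu3[p] = mu_new
            beta3[p] = beta_new
            _all_logliks(
                mu3, beta3, lsig3, z3, cond, choices, outcomes, offsets, use_eta, new_ll
            )
            delta = d_prior
            for s in range(n):
                delta += new_ll[s] - ll[s]
            aprob = 1.0 if delta >= 0 else math.exp(delta)
            if np.random.random() < aprob:
                for s in range(n):
                    ll[s] = new_ll[s]
            else:
                mu3[p] = old_mu
                beta3[p] = old_beta
            if gamma > 0.0:
                log_step_pop[p] += gamma * (aprob - target)

            # scale sub-block: log sigma_p alone (z fixed)
            step = math.exp(log_step_pop_scale[p])
            dlsig = np.random.normal(0.0, step)
            lsig_new = lsig3[p] + dlsig
            sig_old = math.exp(lsig3[p])
            sig_new = math.exp(lsig_new)
            d_prior = (-0.5 * (sig_new * sig_new - sig_old * sig_old)
                       + (lsig_new - lsig3[p]))
            old_lsig = lsig3[p]
            lsig3[p] = lsig_new
            _all_logliks(
                mu3, beta3, lsig3, z3, cond, choices, outcomes, offsets, use_eta, new_ll
            )
            delta = d_prior
            for s in range(n):
                delta += new_ll[s] - ll[s]
            aprob = 1.0 if delta >= 0 else math.exp(delta)
            if np.random.random() < aprob:
                for s in range(n):
                    ll[s] = new_ll[s]
            else:
                lsig3[p] = old_lsig
            if gamma > 0.0:
                log_step_pop_scale[p] += gamma * (aprob - target)

        # -- subject blocks ----------------------------------------------
        for s in range(n):
            step = math.exp(log_step_z[s])
            z_old0 = z3[s, 0]
            z_old1 = z3[s, 1]
            z_old2 = z3[s, 2]
            d_prior = 0.0
            for p in range(n_params):
                znew = z3[s, p] + np.random.normal(0.0, step)
                d_prior += -0.5 * (znew * znew - z3[s, p] * z3[s, p])
                z3[s, p] = znew
            a, t, e = _subject_natural(mu3, beta3, lsig3, z3[s], cond[s], use_eta)
            ll_new = _loglik_core(
                choices[offsets[s] : offsets[s + 1]],
                outcomes[offsets[s] : offsets[s + 1]],
                a,
                t,
                e,
                use_eta,
            )
            delta = d_prior + ll_new - ll[s]
            aprob = 1.0 if delta >= 0 else math.exp(delta)
            if np.random.random() < aprob:
                ll[s] = ll_new
            else:
                z3[s, 0] = z_old0
                z3[s, 1] = z_old1
                z3[s, 2] = z_old2
            if gamma > 0.0:
                log_step_z[s] += gamma * (aprob - target)

        # -- interweaving moves: update population location / scale at
        # fixed natural-scale subject parameters (z transforms
        # deterministically, so the likelihood is unchanged and no data
        # pass is needed).  Two separate moves per family so the scale can
        # take large steps even when the mean is tightly identified. ------
        for p in range(n_params):
            # location move: (mu_p, beta_p) shift, z absorbs it
            step = math.exp(log_step_rep[p])
            dmu = np.random.normal(0.0, step)
            dbeta = np.random.normal(0.0, step) if two_cond else 0.0
            mu_new = mu3[p] + dmu
            beta_new = beta3[p] + dbeta
            sig = math.exp(lsig3[p])
            delta = -0.5 * (mu_new * mu_new - mu3[p] * mu3[p])
            if two_cond:
                delta += -0.5 * (beta_new * beta_new - beta3[p] * beta3[p])
            for s in range(n):
                zn = z3[s, p] - (dmu + dbeta * cond[s]) / sig
                z_prop[s] = zn
                delta += -0.5 * (zn * zn - z3[s, p] * z3[s, p])
            aprob = 1.0 if delta >= 0 else math.exp(delta)
            if np.random.random() < aprob:
                mu3[p] = mu_new
                beta3[p] = beta_new
                for s in range(n):
                    z3[s, p] = z_prop[s]
            if gamma > 0.0:
                log_step_rep[p] += gamma * (aprob - target)

            # scale move: log sigma_p rescales, z absorbs it
            step = math.exp(log_step_scale[p])
            dlsig = np.random.normal(0.0, step)
            lsig_new = lsig3[p] + dlsig
            sig_old = math.exp(lsig3[p])
            sig_new = math.exp(lsig_new)
            ratio = sig_old / sig_new
            delta = (-0.5 * (sig_new * sig_new - sig_old * sig_old)
                     + (lsig_new - lsig3[p]))
            for s in range(n):
                zn = z3[s, p] * ratio
                z_prop[s] = zn
                delta += -0.5 * (zn * zn - z3[s, p] * z3[s, p])
            delta += n * (lsig3[p] - lsig_new)  # Jacobian of the z map
            aprob = 1.0 if delta >= 0 else math.exp(delta)
            if np.random.random() < aprob:
                lsig3[p] = lsig_new
                for s in range(n):
                    z3[s, p] = z_prop[s]
            if gamma > 0.0:
                log_step_scale[p] += gamma * (aprob - target)

        # -- storage ------------------------------------------------------
        if it >= burn_in and (it - burn_in) % thin == 0:
            k = 0
            for p in range(n_params):
                out[kept, k] = mu3[p]
                k += 1
            if two_cond:
                for p in range(n_params):
                    out[kept, k] = beta3[p]
                    k += 1
            for p in range(n_params):
                out[kept, k] = lsig3[p]
                k += 1
            for s in range(n):
                for p in range(n_params):
                    out[kept, k] = z3[s, p]
                    k += 1
            kept += 1

    return out


# ---------------------------------------------------------------------------
# Posterior containers and diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HdiInterval:
    lower: float
    upper: float
    mass: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower


def hdi(draws, mass: float = 0.95) -> HdiInterval:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 draws for an HDI, got {n}")
    k = int(math.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return HdiInterval(float(x[i]), float(x[i + k - 1]), mass)


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, iterations); each chain is split in half
    before comparing within- and between-chain variance.  Returns NaN for
    degenerate (zero-variance) chains.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains of >= 4 draws")
    n_half = x.shape[1] // 2
    halves = np.concatenate([x[:, :n_half], x[:, n_half : 2 * n_half]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    w = float(halves.var(axis=1, ddof=1).mean())
    b = n * float(chain_means.var(ddof=1))
    if w <= 0.0:
        return math.nan
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def effective_sample_size(draws: np.ndarray) -> float:
    """Effective sample size across chains (Geyer initial-positive pairs)."""
    x = np.asarray(draws, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 4:
        raise ValueError("need >= 4 draws per chain")
    centered = x - x.mean(axis=1, keepdims=True)
    # autocovariance per chain via FFT
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)
    w = acov[:, 0].mean() * n / (n - 1)
    chain_means = x.mean(axis=1)
    b_over_n = chain_means.var(ddof=1) if m > 1 else 0.0
    var_plus = w * (n - 1) / n + b_over_n
    if var_plus <= 0:
        return math.nan
    rho = 1.0 - (w - mean_acov) / var_plus
    # Geyer: sum consecutive pairs while their sum stays positive
    tau_sum = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau_sum += pair
        t += 2
    ess = m * n / (1.0 + 2.0 * tau_sum)
    return float(min(ess, m * n))


@dataclass
class Diagnostics:
    rhat: dict
    ess: dict
    converged: bool
    flagged: list

    @classmethod
    def from_draws(cls, draws: np.ndarray, names: list[str]) -> "Diagnostics":
        rhat = {}
        ess = {}
        flagged = []
        for j, name in enumerate(names):
            r = split_rhat(draws[:, :, j])
            rhat[name] = r
            ess[name] = effective_sample_size(draws[:, :, j])
            if math.isnan(r) or r >= RHAT_WARN:
                flagged.append(name)
        return cls(rhat=rhat, ess=ess, converged=not flagged, flagged=flagged)


class PosteriorSamples:
    """MCMC draws indexed by (chain, iteration, parameter name).

    ``draws`` has shape (n_chains, n_kept, dim); ``names`` labels the last
    axis.  For hierarchical fits the metadata records the model, the subject
    ids and condition codes so natural-scale summaries can be derived.
    """

    def __init__(self, draws: np.ndarray, names: list[str], meta: dict | None = None):
        self.draws = np.asarray(draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[2] != len(names):
            raise ValueError("draws must have shape (chains, iterations, len(names))")
        self.names = list(names)
        self.meta = dict(meta or {})
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chains, iterations)."""
        return self.draws[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).ravel()

    def stacked(self) -> np.ndarray:
        """All draws pooled across chains, shape (chains*iterations, dim)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def diagnostics(self) -> Diagnostics:
        return Diagnostics.from_draws(self.draws, self.names)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy draws: columns chain, iteration, parameter, value."""
        chains, iters, dim = self.draws.shape
        rec = {
            "chain": np.repeat(np.arange(chains), iters * dim),
            "iteration": np.tile(np.repeat(np.arange(iters), dim), chains),
            "parameter": np.tile(np.array(self.names, dtype=object), chains * iters),
            "value": self.draws.ravel(),
        }
        return pd.DataFrame(rec)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: dict | None = None) -> "PosteriorSamples":
        names = list(df[df["chain"] == df["chain"].iloc[0]].loc[
            lambda d: d["iteration"] == d["iteration"].iloc[0], "parameter"
        ])
        chains = df["chain"].nunique()
        iters = df["iteration"].nunique()
        draws = df["value"].to_numpy().reshape(chains, iters, len(names))
        return cls(draws, names, meta)

    # -- hierarchical-fit conveniences ------------------------------------

    def _require_hier(self):
        if "model" not in self.meta:
            raise ValueError("not a hierarchical fit result")

    def population_natural(self, parameter: str, condition: str = "soothe") -> np.ndarray:
        """Per-draw natural-scale population median for one condition."""
        self._require_hier()
        p = PARAM_NAMES.index(parameter)
        if self.meta["model"] == "delta" and parameter == "eta":
            raise ValueError("delta model has no eta parameter")
        c = CONDITIONS.index(condition)
        x = self.flat(f"mu_{parameter}")
        if not self.meta["two_cond"]:
            present = {CONDITIONS[code] for code in self.meta["condition_codes"]}
            if condition not in present:
                raise ValueError(
                    f"single-condition fit covers {sorted(present)}, not {condition!r}"
                )
        elif c == 1:
            x = x + self.flat(f"beta_{parameter}")
        if parameter == "alpha":
            return ndtr(x)
        if parameter == "tau":
            return np.exp(x)
        return 2.0 * ndtr(x) - 1.0

    def subject_natural_medians(self) -> pd.DataFrame:
        """Posterior median (alpha, tau, eta) per subject, natural scale."""
        self._require_hier()
        use_eta = self.meta["model"] == "reference"
        params = PARAM_NAMES if use_eta else PARAM_NAMES[:2]
        cond_codes = self.meta["condition_codes"]
        rows = {}
        for p in params:
            mu = self.flat(f"mu_{p}")
            beta = self.flat(f"beta_{p}") if self.meta["two_cond"] else 0.0
            sig = np.exp(self.flat(f"log_sigma_{p}"))
            nat = []
            for s, sid in enumerate(self.meta["subject_ids"]):
                x = mu + (beta * cond_codes[s] if self.meta["two_cond"] else 0.0) \
                    + sig * self.flat(f"z_{p}[{s}]")
                if p == "alpha":
                    v = ndtr(x)
                elif p == "tau":
                    v = np.exp(x)
                else:
                    v = 2.0 * ndtr(x) - 1.0
                nat.append(float(np.median(v)))
            rows[p] = nat
        df = pd.DataFrame(rows)
        df.insert(0, "subject_id", list(self.meta["subject_ids"]))
        if not use_eta:
            df["eta"] = 0.0
        return df

    def summary(self) -> pd.DataFrame:
        """Median, 95% HDI, split-Rhat and ESS per stored parameter."""
        diag = self.diagnostics()
        rows = []
        for name in self.names:
            flat = self.flat(name)
            interval = hdi(flat)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(flat)),
                    "hdi_lower": interval.lower,
                    "hdi_upper": interval.upper,
                    "rhat": diag.rhat[name],
                    "ess": diag.ess[name],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Generic adaptive random-walk sampler (oracle validation, SBC, small models)
# ---------------------------------------------------------------------------

def run_mcmc(
    log_density,
    x0,
    chains: int = 4,
    iterations: int = 11500,
    burn_in: int = 1500,
    thin: int = 10,
    seed: int = 0,
    names: list[str] | None = None,
) -> PosteriorSamples:
    """Adaptive componentwise Metropolis sampler for an arbitrary density.

    ``log_density`` maps a 1-D state vector to a joint log density (may
    return -inf).  Per-component step sizes adapt toward ~0.44 acceptance
    during burn-in and are frozen afterwards.  Retains exactly
    ``chains * (iterations - burn_in) / thin`` draws (ceiling division).
    Deterministic under ``seed``.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    dim = x0.size
    if names is None:
        names = [f"x{i}" for i in range(dim)]
    rng = np.random.default_rng(seed)
    n_keep = (iterations - burn_in + thin - 1) // thin
    draws = np.empty((chains, n_keep, dim))
    for c in range(chains):
        x = x0 + rng.normal(0.0, 0.5, dim)
        lp = log_density(x)
        tries = 0
        while not np.isfinite(lp) and tries < 100:
            x = x0 + rng.normal(0.0, 0.1, dim)
            lp = log_density(x)
            tries += 1
        if not np.isfinite(lp):
            raise ValueError("could not find a finite-density starting point")
        log_step = np.full(dim, math.log(0.5))
        kept = 0
        for it in range(iterations):
            gamma = min(0.25, 2.0 / math.sqrt(1.0 + it)) if it < burn_in else 0.0
            for j in range(dim):
                prop = x.copy()
                prop[j] += rng.normal(0.0, math.exp(log_step[j]))
                lp_prop = log_density(prop)
                delta = lp_prop - lp
                aprob = 1.0 if delta >= 0 else (math.exp(delta) if np.isfinite(delta) else 0.0)
                if rng.random() < aprob:
                    x, lp = prop, lp_prop
                if gamma > 0.0:
                    log_step[j] += gamma * (aprob - 0.44)
            if it >= burn_in and (it - burn_in) % thin == 0:
                draws[c, kept] = x
                kept += 1
    return PosteriorSamples(draws, names)


# ---------------------------------------------------------------------------
# Hierarchical fit driver
# ---------------------------------------------------------------------------

_ALPHA_GRID = np.array([0.05, 0.2, 0.4, 0.6, 0.8, 0.92, 0.98])
_TAU_GRID = np.array([0.2, 0.5, 0.9, 1.4, 2.2, 3.5])
_ETA_GRID = np.array([-0.8, -0.5, -0.2, 0.0, 0.2, 0.5, 0.8])


def _crude_subject_estimates(datasets, use_eta: bool) -> np.ndarray:
    """Grid-search MLE per subject, on the link scale; used only for
    initialisation so chains start near the posterior bulk."""
    etas = _ETA_GRID if use_eta else np.array([0.0])
    out = np.zeros((len(datasets), 3))
    for s, d in enumerate(datasets):
        choices, outcomes = d.choice_array(), d.outcome_array()
        best = -np.inf
        best_combo = (0.5, 1.0, 0.0)
        for a in _ALPHA_GRID:
            for t in _TAU_GRID:
                for e in etas:
                    ll = _loglik_core(choices, outcomes, a, t, e, use_eta)
                    if ll > best:
                        best = ll
                        best_combo = (a, t, e)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[s] = link_forward(*best_combo)
    return out


def fit_hierarchical(
    datasets: list[SubjectDataset],
    model: str = "reference",
    chains: int = 4,
    iterations: int = 2500,
    burn_in: int = 500,
    thin: int = 2,
    seed: int = 0,
) -> PosteriorSamples:
    """Fit the hierarchical bandit model by adaptive MCMC.

    Default sampler settings are a desk-scale run (4 chains x 2,500
    iterations, 500 burn-in, thin 2); heavier settings can be passed for
    fidelity runs.  Chains are initialised from a crude per-subject grid
    estimate with per-chain jitter, so split-Rhat is informative.  The
    result carries metadata for natural-scale population summaries,
    condition contrasts and per-subject medians; call ``.diagnostics()``
    for split-Rhat/ESS (parameters with Rhat >= 1.05 are flagged).
    """
    if model not in ("delta", "reference"):
        raise ValueError(f"model must be 'delta' or 'reference', got {model!r}")
    if chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    if not datasets:
        raise ValueError("no datasets to fit")
    use_eta = model == "reference"
    n_params = 3 if use_eta else 2
    choices, outcomes, offsets, cond = _pack(datasets)
    two_cond = len(np.unique(cond)) == 2
    n = len(datasets)

    theta_hat = _crude_subject_estimates(datasets, use_eta)  # (n, 3) link scale
    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=chains)

    names = [f"mu_{p}" for p in PARAM_NAMES[:n_params]]
    if two_cond:
        names += [f"beta_{p}" for p in PARAM_NAMES[:n_params]]
    names += [f"log_sigma_{p}" for p in PARAM_NAMES[:n_params]]
    for s in range(n):
        names += [f"z_{p}[{s}]" for p in PARAM_NAMES[:n_params]]

    all_draws = []
    for c in range(chains):
        mask0 = cond == 0
        mu0 = theta_hat[mask0, :n_params].mean(axis=0) if mask0.any() else np.zeros(n_params)
        if two_cond:
            beta0 = theta_hat[~mask0, :n_params].mean(axis=0) - mu0
        else:
            beta0 = np.zeros(n_params)
        sd0 = np.clip(theta_hat[:, :n_params].std(axis=0), 0.2, 1.0)
        # overdispersed starts: jitter the population block per chain
        mu0 = mu0 + rng.normal(0.0, 0.15, n_params)
        beta0 = beta0 + (rng.normal(0.0, 0.15, n_params) if two_cond else 0.0)
        lsig0 = np.log(sd0) + rng.normal(0.0, 0.1, n_params)
        resid = theta_hat[:, :n_params] - mu0 - np.outer(cond, beta0)
        z0 = np.clip(resid / np.exp(lsig0), -2.5, 2.5) + rng.normal(0.0, 0.05, (n, n_params))
        draws = _hier_chain(
            choices,
            outcomes,
            offsets,
            cond,
            use_eta,
            two_cond,
            int(iterations),
            int(burn_in),
            int(thin),
            int(chain_seeds[c]),
            np.ascontiguousarray(mu0),
            np.ascontiguousarray(beta0),
            np.ascontiguousarray(lsig0),
            np.ascontiguousarray(z0),
        )
        all_draws.append(draws)

    meta = {
        "model": model,
        "two_cond": bool(two_cond),
        "subject_ids": [d.subject_id for d in datasets],
        "condition_codes": cond.astype(int).tolist(),
        "n_params": n_params,
        "chains": chains,
        "iterations": iterations,
        "burn_in": burn_in,
        "thin": thin,
        "seed": seed,
    }
    return PosteriorSamples(np.stack(all_draws), names, meta)


# ---------------------------------------------------------------------------
# Condition contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionContrast:
    """Posterior of the keep_happy-minus-soothe natural-scale population
    difference for one parameter."""

    parameter: str
    median: float
    interval: HdiInterval
    p_positive: float
    degenerate: bool
    draws: np.ndarray


def condition_contrast(samples: PosteriorSamples, parameter: str) -> ConditionContrast:
    """Natural-scale population difference between conditions.

    Per draw, the population medians of both conditions are formed by
    link-inverting mu and mu + beta; the contrast is their difference
    (keep_happy minus soothe), summarised by its median, 95% HDI and the
    posterior probability of being positive.  If the difference is exactly
    zero on every draw, P(>0) is reported as 0.5 with ``degenerate=True``.
    """
    if not samples.meta.get("two_cond", False):
        raise ValueError("condition contrast requires a two-condition fit")
    d = (
        samples.population_natural(parameter, "keep_happy")
        - samples.population_natural(parameter, "soothe")
    )
    degenerate = bool(np.all(d == 0.0))
    p_pos = 0.5 if degenerate else float(np.mean(d > 0))
    return ConditionContrast(
        parameter=parameter,
        median=float(np.median(d)),
        interval=hdi(d),
        p_positive=p_pos,
        degenerate=degenerate,
        draws=d,
    )


# ---------------------------------------------------------------------------
# Simulation-based calibration (single-subject scale)
# ---------------------------------------------------------------------------

def sbc_ranks(
    n_replicates: int = 20,
    n_trials: int = 80,
    iterations: int = 1200,
    burn_in: int = 400,
    thin: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Simulation-based calibration of the sampler on single-subject fits.

    For each replicate, draw (alpha, tau, eta) link-scale values from the
    standard-normal prior, simulate one subject on the default schedule,
    sample the posterior with the same prior, and record the rank of the
    true value among the retained draws (per parameter).  If the sampler
    targets the correct posterior the ranks are uniform.

    Returns an integer array of shape (n_replicates, 3); ranks lie in
    [0, n_kept] where n_kept = (iterations - burn_in) / thin.
    """
    from .cohort import simulate_subject  # late import; cohort depends on us
    from .models import ModelParams

    schedule = default_schedule(n_trials=n_trials, block_length=n_trials)
    rng = np.random.default_rng(seed)
    ranks = np.zeros((n_replicates, 3), dtype=int)
    for i in range(n_replicates):
        x_true = rng.normal(0.0, 1.0, 3)
        a, t, e = link_inverse(*x_true)
        ds = simulate_subject(
            ModelParams(a, t, e), schedule, condition="soothe",
            rng=rng, subject_id=f"sbc{i}",
        )
        choices, outcomes = ds.choice_array(), ds.outcome_array()

        def logpost(x):
            if np.any(np.abs(x) > 12):
                return -np.inf
            aa, tt, ee = link_inverse(*x)
            ee = min(max(ee, -1 + 1e-12), 1 - 1e-12)
            ll = _loglik_core(choices, outcomes, aa, min(tt, 1e6), ee, True)
            return ll - 0.5 * float(np.sum(x**2))

        fit = run_mcmc(
            logpost,
            x_true,
            chains=1,
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            seed=int(rng.integers(2**31 - 1)),
        )
        pooled = fit.stacked()
        for p in range(3):
            ranks[i, p] = int(np.sum(pooled[:, p] < x_true[p]))
    return ranks
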