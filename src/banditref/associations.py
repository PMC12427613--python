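"""Exclusion rules and covariate analyses on fitted parameters.

Mirrors the paper-style analysis stage of the pipeline:

* participants are excluded if they pressed the same bandit on **more
  than** 75% of trials (strict inequality: exactly 75% is retained), did
  not complete the session, or repeated the session;
* each subject's posterior-median (alpha, tau, eta) is regressed on one
  mental-health score at a time with Bayesian linear regression, adjusting
  for age (and condition in two-condition designs); predictors are
  z-scored so coefficients are per SD;
* pre/post stimulus ratings are compared between conditions.

The regressions use the conjugate normal–inverse-gamma family with weakly
informative scales and exact posterior sampling, so results are
deterministic under a seed and carry trivially converged Rhat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .inference import split_rhat
from .task import CONDITIONS, SubjectDataset

__all__ = [
    "ExclusionReport",
    "RegressionResult",
    "AssociationResult",
    "apply_exclusions",
    "fit_bayesian_regression",
    "associate_parameters",
    "rating_difference_analysis",
    "score_epds",
    "STUDY1_MEASURES",
    "STUDY2_MEASURES",
]

STUDY1_MEASURES = ("smfq", "stai_s", "stai_t", "sapas", "bis")
STUDY2_MEASURES = ("sapas", "epds")
EPDS_ANXIETY_ITEMS = (3, 4, 5, 6)


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    """Per-subject exclusion bookkeeping; ``table`` has one row per input
    dataset with columns subject_id, n_trials_completed,
    max_same_bandit_fraction, excluded, reason."""

    table: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    def reason_counts(self) -> dict:
        return self.table.loc[self.table["excluded"], "reason"].value_counts().to_dict()


def apply_exclusions(
    datasets: list[SubjectDataset],
    expected_trials: int = 200,
    threshold: float = 0.75,
) -> tuple[list[SubjectDataset], ExclusionReport]:
    """Apply the task's exclusion rules and report per-subject outcomes.

    Rules, in precedence order: a second session from the same subject is a
    ``repeat_session``; fewer than ``expected_trials`` completed trials is
    ``incomplete``; a same-bandit fraction strictly greater than
    ``threshold`` is ``same_bandit_gt_75pct``.  Exactly 75% is retained.
    """
    seen: set[str] = set()
    rows = []
    retained = []
    for d in datasets:
        frac = d.same_bandit_fraction()
        if d.subject_id in seen:
            reason = "repeat_session"
        elif len(d) < expected_trials:
            reason = "incomplete"
        elif frac > threshold:
            reason = "same_bandit_gt_75pct"
        else:
            reason = "none"
        seen.add(d.subject_id)
        rows.append(
            {
                "subject_id": d.subject_id,
                "n_trials_completed": len(d),
                "max_same_bandit_fraction": frac,
                "excluded": reason != "none",
                "reason": reason,
            }
        )
        if reason == "none":
            retained.append(d)
    return retained, ExclusionReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Bayesian linear regression (conjugate normal--inverse-gamma)
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Posterior coefficient summaries; ``coefficients`` has one row per
    predictor (plus intercept) with median, 2.5/97.5% CrI bounds, rhat."""

    coefficients: pd.DataFrame
    sigma_median: float
    n: int
    draws: pd.DataFrame

    def coefficient(self, name: str) -> pd.Series:
        return self.coefficients.set_index("predictor").loc[name]


def fit_bayesian_regression(
    outcome,
    predictors: pd.DataFrame,
    prior_scale: float = 10.0,
    n_draws: int = 4000,
    seed: int = 0,
) -> RegressionResult:
    """Bayesian linear regression with weakly informative priors.

    Conjugate model: coefficients ~ N(0, sigma^2 * prior_scale^2) given the
    residual variance, sigma^2 ~ Inv-Gamma(0.001, 0.001) (vague).  The posterior is
    sampled exactly (sigma^2 from its inverse-gamma marginal, coefficients
    from the conditional normal), so the run is deterministic under
    ``seed`` and chains are exact draws.  An intercept is always included;
    pass z-scored predictors for per-SD coefficients.
    """
    y = np.asarray(outcome, dtype=float)
    X_df = pd.DataFrame(predictors)
    n = y.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, got {n}")
    if X_df.shape[0] != n:
        raise ValueError("outcome and predictors have different lengths")
    for col in X_df.columns:
        if float(np.std(X_df[col].to_numpy(dtype=float))) == 0.0:
            raise ValueError(f"predictor {col!r} is constant")
    names = ["intercept"] + list(X_df.columns)
    X = np.column_stack([np.ones(n), X_df.to_numpy(dtype=float)])
    k = X.shape[1]

    a0, b0 = 1e-3, 1e-3
    prior_prec = np.eye(k) / prior_scale**2
    prec_n = prior_prec + X.T @ X
    chol = cho_factor(prec_n, lower=True)
    mean_n = cho_solve(chol, X.T @ y)
    a_n = a0 + n / 2.0
    b_n = b0 + 0.5 * float(y @ y - mean_n @ prec_n @ mean_n)

    rng = np.random.default_rng(seed)
    sigma2 = b_n / rng.gamma(a_n, 1.0, size=n_draws)
    z = rng.standard_normal((n_draws, k))
    # solve L^T u = z  =>  u ~ N(0, prec_n^{-1})
    L = np.linalg.cholesky(prec_n)
    u = np.linalg.solve(L.T, z.T).T
    betas = mean_n + u * np.sqrt(sigma2)[:, None]

    n_chains = 4
    per_chain = n_draws // n_chains
    rows = []
    for j, name in enumerate(names):
        col = betas[: n_chains * per_chain, j].reshape(n_chains, per_chain)
        lo, med, hi = np.quantile(betas[:, j], [0.025, 0.5, 0.975])
        rows.append(
            {
                "predictor": name,
                "median": float(med),
                "cri_lower": float(lo),
                "cri_upper": float(hi),
                "rhat": split_rhat(col),
            }
        )
    draws = pd.DataFrame(betas, columns=names)
    draws["sigma"] = np.sqrt(sigma2)
    return RegressionResult(
        coefficients=pd.DataFrame(rows),
        sigma_median=float(np.median(np.sqrt(sigma2))),
        n=n,
        draws=draws,
    )


# ---------------------------------------------------------------------------
# Parameter--covariate associations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    parameter: str
    predictor: str
    median: float
    cri_lower: float
    cri_upper: float
    rhat: float
    n: int

    def contains_zero(self) -> bool:
        return self.cri_lower <= 0.0 <= self.cri_upper


def score_epds(items: pd.DataFrame, drop_anxiety: bool = False) -> pd.Series:
    """Total EPDS score from item-level columns ``epds_item1..10``.

    With ``drop_anxiety=True`` items 3–6 are omitted from the total.
    """
    cols = [f"epds_item{i}" for i in range(1, 11)]
    missing = [c for c in cols if c not in items.columns]
    if missing:
        raise ValueError(f"missing EPDS item columns {missing}")
    use = [
        c
        for i, c in enumerate(cols, start=1)
        if not (drop_anxiety and i in EPDS_ANXIETY_ITEMS)
    ]
    return items[use].sum(axis=1)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def associate_parameters(
    parameter_medians: pd.DataFrame,
    covariates: pd.DataFrame,
    design: str = "study1",
    measures: tuple | None = None,
    seed: int = 0,
) -> list[AssociationResult]:
    """One Bayesian regression per (parameter, mental-health measure) pair.

    ``parameter_medians`` has columns subject_id, alpha, tau, eta (posterior
    medians, natural scale); ``covariates`` carries age, condition and the
    questionnaire totals.  The study1 design adjusts for age and condition
    (soothe = reference); study2 adjusts for age only.  Complete-case per
    regression, with the per-model n in each result.  If item-level EPDS
    columns are present, an ``epds_noanx`` variant (anxiety items 3–6
    dropped) is added to the study2 battery.
    """
    if design not in ("study1", "study2"):
        raise ValueError(f"design must be 'study1' or 'study2', got {design!r}")
    if covariates["subject_id"].duplicated().any():
        dup = covariates.loc[covariates["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicated covariate rows (subject {dup})")
    orphans = set(parameter_medians["subject_id"]) - set(covariates["subject_id"])
    if orphans:
        raise ValueError(f"no covariates for subjects: {sorted(orphans)}")

    merged = parameter_medians.merge(covariates, on="subject_id", how="left")
    if measures is None:
        measures = STUDY1_MEASURES if design == "study1" else STUDY2_MEASURES
        if design == "study2" and "epds_item1" in covariates.columns:
            merged["epds_noanx"] = score_epds(merged, drop_anxiety=True).to_numpy()
            measures = measures + ("epds_noanx",)

    params = [p for p in ("alpha", "tau", "eta") if p in parameter_medians.columns]
    results = []
    run = 0
    for param in params:
        for measure in measures:
            if measure not in merged.columns:
                continue
            cols = [param, measure, "age"]
            if design == "study1":
                cols.append("condition")
            sub = merged[["subject_id"] + cols].dropna()
            X = pd.DataFrame(
                {measure: _zscore(sub[measure].to_numpy(dtype=float)),
                 "age": _zscore(sub["age"].to_numpy(dtype=float))}
            )
            if design == "study1":
                X["condition"] = [CONDITIONS.index(c) for c in sub["condition"]]
            fit = fit_bayesian_regression(
                sub[param].to_numpy(dtype=float), X, seed=seed + run
            )
            run += 1
            coef = fit.coefficient(measure)
            results.append(
                AssociationResult(
                    parameter=param,
                    predictor=measure,
                    median=float(coef["median"]),
                    cri_lower=float(coef["cri_lower"]),
                    cri_upper=float(coef["cri_upper"]),
                    rhat=float(coef["rhat"]),
                    n=fit.n,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Pre/post stimulus-rating analysis
# ---------------------------------------------------------------------------

def rating_difference_analysis(
    ratings: pd.DataFrame,
    outcome: str = "post",
    seed: int = 0,
) -> pd.DataFrame:
    """Condition effect on stimulus ratings, per (stimulus, scale) cell.

    ``ratings`` is long format with columns subject_id, condition, phase
    (pre/post), stimulus (negative/neutral/happy), scale (emotion/
    temperament), rating (0–100).  The default models the post-task rating
    on condition (soothe = reference); ``outcome='difference'`` models
    post − pre instead, dropping (and counting) subjects missing a phase.
    Returns one row per cell: posterior mean difference, 95% CrI, rhat, n.
    """
    if outcome not in ("post", "difference"):
        raise ValueError(f"outcome must be 'post' or 'difference', got {outcome!r}")
    required = {"subject_id", "condition", "phase", "stimulus", "scale", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing columns {sorted(missing)}")
    out_rows = []
    run = 0
    for (stimulus, scale), cell in ratings.groupby(["stimulus", "scale"], sort=True):
        wide = cell.pivot_table(
            index=["subject_id", "condition"], columns="phase", values="rating"
        ).reset_index()
        n_dropped = 0
        if outcome == "post":
            wide = wide.dropna(subset=["post"])
            y = wide["post"].to_numpy(dtype=float)
        else:
            complete = wide.dropna(subset=["pre", "post"])
            n_dropped = len(wide) - len(complete)
            wide = complete
            y = (wide["post"] - wide["pre"]).to_numpy(dtype=float)
        if len(wide) == 0:
            raise ValueError(f"no usable ratings for ({stimulus}, {scale})")
        X = pd.DataFrame({"condition": [CONDITIONS.index(c) for c in wide["condition"]]})
        fit = fit_bayesian_regression(y, X, seed=seed + run)
        run += 1
        cond_draws = fit.draws["condition"].to_numpy()
        coef = fit.coefficient("condition")
        out_rows.append(
            {
                "stimulus": stimulus,
                "scale": scale,
                "mean_difference": float(np.mean(cond_draws)),
                "cri_lower": float(coef["cri_lower"]),
                "cri_upper": float(coef["cri_upper"]),
                "rhat": float(coef["rhat"]),
                "n": fit.n,
                "n_dropped": n_dropped,
            }
        )
    return pd.DataFrame(out_rows)
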