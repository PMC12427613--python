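"""End-to-end pipeline: simulate -> exclude -> fit -> compare -> associate.

A single YAML/dict config drives every stage; each stage derives its own
seed deterministically from the master seed, writes its artifact under the
run directory, and logs one line with the seed and an input hash, so a
rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import cohort as cohort_mod
from . import comparison as comp
from . import inference as inf
from . import task as task_mod

__all__ = ["PipelineConfig", "run_pipeline", "recovery_report"]

logger = logging.getLogger("banditref")

_DEFAULT_SAMPLER = {"chains": 4, "iterations": 2500, "burn_in": 500, "thin": 2}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``cohort`` describes the synthetic cohort (or ``trials``/``covariates``
    point at existing CSVs); ``sampler`` holds MCMC settings; ``models``
    lists which observation models to fit.  All stage seeds derive from
    ``seed``.
    """

    out_dir: str
    seed: int = 0
    trials: str | None = None
    covariates: str | None = None
    cohort: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)
    models: tuple = ("reference", "delta")
    compare: bool = True
    association_design: str = "study1"
    expected_trials: int | None = None
    save_subject_draws: bool = False

    def __post_init__(self) -> None:
        if not self.out_dir:
            raise ValueError("config must set out_dir")
        for m in self.models:
            if m not in ("reference", "delta"):
                raise ValueError(f"unknown model {m!r}")
        if self.association_design not in ("study1", "study2"):
            raise ValueError(f"unknown design {self.association_design!r}")
        merged = dict(_DEFAULT_SAMPLER)
        merged.update(self.sampler)
        self.sampler = merged
        if (self.trials is None) != (self.covariates is None):
            raise ValueError("provide both trials and covariates paths, or neither")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def stage_seeds(self) -> dict:
        ints = np.random.SeedSequence(self.seed).generate_state(6) % (2**31 - 1)
        stages = ["simulate", "fit_reference", "fit_delta", "compare", "associate", "extra"]
        return {s: int(v) for s, v in zip(stages, ints)}


def _cohort_from_config(cfg: dict, seed: int) -> cohort_mod.CohortConfig:
    cfg = dict(cfg)
    pop_cfg = cfg.pop("population", None)
    population = None
    if pop_cfg is not None:
        if "natural_medians" in pop_cfg:
            nm = pop_cfg["natural_medians"]
            population = inf.PopulationParams.from_natural_medians(
                nm["alpha"], nm["tau"], nm["eta"],
                sigma=pop_cfg.get("sigma", 0.3),
                beta_cond=pop_cfg.get("beta_cond"),
            )
        else:
            population = inf.PopulationParams(**pop_cfg)
    schedule_cfg = cfg.pop("schedule", None)
    schedule = None
    if schedule_cfg is not None:
        if "block_probs" in schedule_cfg:
            schedule = task_mod.build_reward_schedule(
                schedule_cfg["n_trials"],
                schedule_cfg["block_length"],
                schedule_cfg["block_probs"],
            )
        else:
            schedule = task_mod.default_schedule(**schedule_cfg)
    if "conditions" in cfg:
        cfg["conditions"] = tuple(cfg["conditions"])
    return cohort_mod.CohortConfig(
        population=population, schedule=schedule, seed=seed, **cfg
    )


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _log_stage(stage: str, seed: int, artifact: Path) -> None:
    logger.info(
        "stage=%s seed=%d artifact=%s hash=%s",
        stage, seed, artifact.name, _file_hash(artifact),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the summary dict.

    Artifacts under ``config.out_dir``: trials.csv, covariates.csv,
    exclusions.csv, posterior_<model>.csv (population-level draws, tidy),
    comparison.json, associations.csv and summary.json, plus run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = config.stage_seeds()
    summary: dict = {"seed": config.seed, "stages": []}

    try:
        # -- data ---------------------------------------------------------
        if config.trials is not None:
            datasets = task_mod.read_trials(config.trials)
            covariates = cohort_mod.read_covariates(config.covariates)
            summary["data"] = {"source": "files", "trials": str(config.trials)}
        else:
            cohort_cfg = _cohort_from_config(config.cohort, seeds["simulate"])
            result = cohort_mod.generate_cohort(cohort_cfg)
            datasets, covariates = result.datasets, result.covariates
            summary["data"] = {"source": "synthetic", **result.provenance}
        task_mod.write_trials(datasets, out / "trials.csv")
        cohort_mod.write_covariates(covariates, out / "covariates.csv")
        _log_stage("simulate", seeds["simulate"], out / "trials.csv")
        summary["stages"].append("simulate")

        # -- exclusions ---------------------------------------------------
        expected = config.expected_trials
        if expected is None:
            expected = max(len(d) for d in datasets)
        retained, report = assoc.apply_exclusions(datasets, expected_trials=expected)
        report.table.to_csv(out / "exclusions.csv", index=False)
        _log_stage("exclude", config.seed, out / "exclusions.csv")
        summary["exclusions"] = {
            "n_input": len(datasets),
            "n_retained": len(retained),
            "reasons": report.reason_counts(),
        }
        summary["stages"].append("exclude")

        # -- hierarchical fits -------------------------------------------
        fits = {}
        for model in config.models:
            fit = inf.fit_hierarchical(
                retained, model=model, seed=seeds[f"fit_{model}"], **config.sampler
            )
            fits[model] = fit
            pop_names = [n for n in fit.names if not n.startswith("z_")]
            tidy = fit.to_dataframe()
            if not config.save_subject_draws:
                tidy = tidy[tidy["parameter"].isin(pop_names)]
            tidy.to_csv(out / f"posterior_{model}.csv", index=False)
            _log_stage(f"fit_{model}", seeds[f"fit_{model}"], out / f"posterior_{model}.csv")
            diag = fit.diagnostics()
            pop_summary = {}
            conditions = ["soothe"] + (["keep_happy"] if fit.meta["two_cond"] else [])
            for p in ("alpha", "tau", "eta")[: fit.meta["n_params"]]:
                for cond in conditions:
                    draws = fit.population_natural(p, cond)
                    interval = inf.hdi(draws)
                    pop_summary[f"{p}_{cond}"] = {
                        "median": float(np.median(draws)),
                        "hdi_lower": interval.lower,
                        "hdi_upper": interval.upper,
                    }
            contrasts = {}
            if fit.meta["two_cond"]:
                for p in ("alpha", "tau", "eta")[: fit.meta["n_params"]]:
                    c = inf.condition_contrast(fit, p)
                    contrasts[p] = {
                        "median": c.median,
                        "hdi_lower": c.interval.lower,
                        "hdi_upper": c.interval.upper,
                        "p_positive": c.p_positive,
                    }
            summary[f"fit_{model}"] = {
                "converged": diag.converged,
                "flagged": diag.flagged[:10],
                "max_rhat_population": max(diag.rhat[n] for n in pop_names),
                "population": pop_summary,
                "contrasts": contrasts,
            }
            summary["stages"].append(f"fit_{model}")

        # -- model comparison --------------------------------------------
        if config.compare and {"reference", "delta"} <= set(fits):
            cmp_result = comp.compare_models(
                fits["reference"], fits["delta"], retained, seed=seeds["compare"]
            )
            (out / "comparison.json").write_text(json.dumps(cmp_result, indent=2))
            _log_stage("compare", seeds["compare"], out / "comparison.json")
            summary["comparison"] = {
                k: cmp_result[k]
                for k in ("logml_reference", "logml_delta", "log_bf_ref_delta",
                          "log10_bf_ref_delta")
            }
            summary["stages"].append("compare")

        # -- associations -------------------------------------------------
        primary = "reference" if "reference" in fits else config.models[0]
        medians = fits[primary].subject_natural_medians()
        cov_retained = covariates[
            covariates["subject_id"].isin(medians["subject_id"])
        ].reset_index(drop=True)
        results = assoc.associate_parameters(
            medians,
            cov_retained,
            design=config.association_design,
            seed=seeds["associate"],
        )
        assoc_df = pd.DataFrame([r.__dict__ for r in results])
        assoc_df.to_csv(out / "associations.csv", index=False)
        _log_stage("associate", seeds["associate"], out / "associations.csv")
        summary["associations"] = assoc_df.to_dict(orient="records")
        summary["stages"].append("associate")

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def recovery_report(
    fit: inf.PosteriorSamples,
    population: inf.PopulationParams,
    conditions: tuple = ("soothe",),
) -> pd.DataFrame:
    """Compare a fit's population posteriors against generative truth.

    One row per (parameter, condition): generative natural-scale median,
    posterior median, 95% HDI bounds, and whether the HDI covers truth.
    """
    if population is None:
        raise ValueError("generative population truth is required")
    rows = []
    n_params = fit.meta["n_params"]
    for p in ("alpha", "tau", "eta")[:n_params]:
        for cond in conditions:
            code = task_mod.CONDITIONS.index(cond)
            truth = population.natural_medians(code)[p]
            draws = fit.population_natural(p, cond)
            interval = inf.hdi(draws)
            rows.append(
                {
                    "parameter": p,
                    "condition": cond,
                    "truth": truth,
                    "posterior_median": float(np.median(draws)),
                    "hdi_lower": interval.lower,
                    "hdi_upper": interval.upper,
                    "covered": bool(interval.lower <= truth <= interval.upper),
                    "abs_error": abs(float(np.median(draws)) - truth),
                }
            )
    return pd.DataFrame(rows)
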