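import numpy as np
import pandas as pd
import pytest

from banditref.associations import (
    apply_exclusions,
    associate_parameters,
    fit_bayesian_regression,
    rating_difference_analysis,
    score_epds,
)
from conftest import make_dataset


def _dataset_with_fraction(n_same, n_total, subject_id="s0"):
    choices = [0] * n_same + [1] * (n_total - n_same)
    outcomes = [1] * n_total
    return make_dataset(choices, outcomes, subject_id=subject_id)


class TestExclusions:
    def test_exactly_75_percent_is_retained(self):
        retained, report = apply_exclusions([_dataset_with_fraction(150, 200)])
        assert len(retained) == 1
        assert report.table.iloc[0]["reason"] == "none"

    def test_above_75_percent_is_excluded(self):
        retained, report = apply_exclusions([_dataset_with_fraction(151, 200)])
        assert retained == []
        assert report.table.iloc[0]["reason"] == "same_bandit_gt_75pct"

    def test_incomplete_session_excluded(self):
        retained, report = apply_exclusions([_dataset_with_fraction(30, 62)])
        assert retained == []
        assert report.table.iloc[0]["reason"] == "incomplete"

    def test_repeat_session_excluded(self):
        first = _dataset_with_fraction(100, 200, "s1")
        second = _dataset_with_fraction(110, 200, "s1")
        retained, report = apply_exclusions([first, second])
        assert len(retained) == 1
        assert report.table.iloc[1]["reason"] == "repeat_session"

    def test_idempotent(self):
        data = [
            _dataset_with_fraction(150, 200, "a"),
            _dataset_with_fraction(180, 200, "b"),
            _dataset_with_fraction(100, 200, "c"),
        ]
        once, _ = apply_exclusions(data)
        twice, report = apply_exclusions(once)
        assert [d.subject_id for d in twice] == [d.subject_id for d in once]
        assert report.n_excluded == 0

    def test_order_independent(self):
        data = [
            _dataset_with_fraction(150, 200, "a"),
            _dataset_with_fraction(180, 200, "b"),
            _dataset_with_fraction(100, 200, "c"),
        ]
        kept_fwd, _ = apply_exclusions(data)
        kept_rev, _ = apply_exclusions(data[::-1])
        assert {d.subject_id for d in kept_fwd} == {d.subject_id for d in kept_rev}


class TestBayesianRegression:
    def test_strong_signal_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        x = (x - x.mean()) / x.std()
        y = 2.0 * x + rng.normal(0, 0.01, 200)
        fit = fit_bayesian_regression(y, pd.DataFrame({"x": x}), seed=1)
        assert fit.coefficient("x")["median"] == pytest.approx(2.0, abs=0.02)

    def test_null_predictor_calibration(self):
        rng = np.random.default_rng(2)
        covered = 0
        for rep in range(20):
            x = rng.standard_normal(200)
            y = rng.standard_normal(200)
            fit = fit_bayesian_regression(y, pd.DataFrame({"x": x}), seed=rep)
            c = fit.coefficient("x")
            covered += c["cri_lower"] <= 0.0 <= c["cri_upper"]
        assert covered >= 18  # ~95% coverage over 20 replicates

    def test_zero_variance_outcome(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        fit = fit_bayesian_regression(np.zeros(50), pd.DataFrame({"x": x}), seed=4)
        assert abs(fit.coefficient("x")["median"]) < 0.01
        assert fit.sigma_median < 0.1

    def test_per_sd_coefficient_is_scale_equivariant(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(150)
        y = 0.7 * x + rng.normal(0, 0.3, 150)
        raw = fit_bayesian_regression(y, pd.DataFrame({"x": x}), seed=6)
        doubled = fit_bayesian_regression(y, pd.DataFrame({"x": 2 * x}), seed=6)
        # near-equivariant: only the weak shrinkage prior breaks exact halving
        assert doubled.coefficient("x")["median"] == pytest.approx(
            raw.coefficient("x")["median"] / 2, rel=1e-3
        )
        z = (x - x.mean()) / x.std()
        z2 = (2 * x - (2 * x).mean()) / (2 * x).std()
        per_sd = fit_bayesian_regression(y, pd.DataFrame({"x": z}), seed=6)
        per_sd2 = fit_bayesian_regression(y, pd.DataFrame({"x": z2}), seed=6)
        assert per_sd.coefficient("x")["median"] == pytest.approx(
            per_sd2.coefficient("x")["median"], rel=1e-6
        )

    def test_constant_predictor_named_in_error(self):
        with pytest.raises(ValueError, match="flat_col"):
            fit_bayesian_regression(
                np.arange(20.0), pd.DataFrame({"flat_col": np.ones(20)})
            )

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_bayesian_regression(np.arange(5.0), pd.DataFrame({"x": np.arange(5.0)}))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        a = fit_bayesian_regression(y, pd.DataFrame({"x": x}), seed=8)
        b = fit_bayesian_regression(y, pd.DataFrame({"x": x}), seed=8)
        assert a.coefficients.equals(b.coefficients)


def _covariate_frame(n, rng, condition=True):
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age": rng.normal(20, 3, n),
            "smfq": rng.normal(7, 4, n).clip(0, 26),
            "stai_s": rng.normal(39, 10, n).clip(20, 80),
            "stai_t": rng.normal(46, 10, n).clip(20, 80),
            "sapas": rng.normal(3, 1.5, n).clip(0, 8),
            "bis": rng.normal(64, 8, n).clip(30, 120),
            "epds": rng.normal(13, 4, n).clip(0, 30),
        }
    )
    if condition:
        df["condition"] = np.where(np.arange(n) % 2 == 0, "soothe", "keep_happy")
    else:
        df["condition"] = "soothe"
    return df


class TestAssociateParameters:
    def test_null_effects_mostly_cover_zero(self):
        rng = np.random.default_rng(10)
        n = 120
        cov = _covariate_frame(n, rng)
        medians = pd.DataFrame(
            {
                "subject_id": cov["subject_id"],
                "alpha": rng.uniform(0.3, 0.9, n),
                "tau": rng.uniform(0.5, 2.5, n),
                "eta": rng.uniform(-0.5, 0.5, n),
            }
        )
        results = associate_parameters(medians, cov, design="study1", seed=11)
        assert len(results) == 15  # 3 parameters x 5 measures
        n_cover = sum(r.contains_zero() for r in results)
        assert n_cover >= 12

    def test_injected_effect_recovered_with_sign_and_size(self):
        rng = np.random.default_rng(12)
        n = 91
        cov = _covariate_frame(n, rng, condition=False)
        z = (cov["sapas"] - cov["sapas"].mean()) / cov["sapas"].std(ddof=0)
        medians = pd.DataFrame(
            {
                "subject_id": cov["subject_id"],
                "alpha": np.clip(0.6 - 0.18 * z + rng.normal(0, 0.05, n), 0.02, 0.98),
                "tau": rng.uniform(0.5, 2.5, n),
                "eta": rng.uniform(-0.5, 0.5, n),
            }
        )
        results = associate_parameters(medians, cov, design="study2", seed=13)
        alpha_sapas = next(
            r for r in results if r.parameter == "alpha" and r.predictor == "sapas"
        )
        assert alpha_sapas.median == pytest.approx(-0.18, abs=0.08)
        assert alpha_sapas.n == n

    def test_complete_case_n_reported(self):
        rng = np.random.default_rng(14)
        cov = _covariate_frame(40, rng)
        cov.loc[:4, "sapas"] = np.nan
        medians = pd.DataFrame(
            {
                "subject_id": cov["subject_id"],
                "alpha": rng.uniform(0.2, 0.9, 40),
                "tau": rng.uniform(0.5, 2, 40),
                "eta": rng.uniform(-0.5, 0.5, 40),
            }
        )
        results = associate_parameters(medians, cov, design="study1", seed=15)
        sapas = [r for r in results if r.predictor == "sapas"]
        assert all(r.n == 35 for r in sapas)
        others = [r for r in results if r.predictor != "sapas"]
        assert all(r.n == 40 for r in others)

    def test_duplicated_covariates_rejected(self):
        rng = np.random.default_rng(16)
        cov = _covariate_frame(20, rng)
        dup = pd.concat([cov, cov.iloc[:1]], ignore_index=True)
        medians = pd.DataFrame(
            {"subject_id": cov["subject_id"], "alpha": rng.uniform(size=20),
             "tau": np.ones(20), "eta": np.zeros(20)}
        )
        with pytest.raises(ValueError, match="duplicated"):
            associate_parameters(medians, dup, seed=17)

    def test_orphan_subjects_listed(self):
        rng = np.random.default_rng(18)
        cov = _covariate_frame(20, rng)
        medians = pd.DataFrame(
            {"subject_id": ["ghost1", "ghost2"], "alpha": [0.5, 0.6],
             "tau": [1.0, 1.0], "eta": [0.0, 0.0]}
        )
        with pytest.raises(ValueError, match="ghost1"):
            associate_parameters(medians, cov, seed=19)


class TestEpdsScoring:
    def test_anxiety_items_dropped(self):
        items = pd.DataFrame(
            {f"epds_item{i}": [1] * 3 for i in range(1, 11)}
        )
        assert (score_epds(items) == 10).all()
        assert (score_epds(items, drop_anxiety=True) == 6).all()

    def test_missing_items_rejected(self):
        with pytest.raises(ValueError, match="epds_item"):
            score_epds(pd.DataFrame({"epds_item1": [1]}))


def _ratings_frame(rng, n=60, shift=0.0):
    rows = []
    for i in range(n):
        cond = "soothe" if i % 2 == 0 else "keep_happy"
        for stim in ("negative", "neutral", "happy"):
            for scale in ("emotion", "temperament"):
                base = {"negative": 20, "neutral": 50, "happy": 80}[stim]
                for phase in ("pre", "post"):
                    r = base + rng.normal(0, 5)
                    if (phase == "post" and cond == "keep_happy"
                            and stim == "happy" and scale == "temperament"):
                        r += shift
                    rows.append(
                        {"subject_id": f"s{i}", "condition": cond, "phase": phase,
                         "stimulus": stim, "scale": scale,
                         "rating": float(np.clip(r, 0, 100))}
                    )
    return pd.DataFrame(rows)


class TestRatingAnalysis:
    def test_no_effect_differences_near_zero(self):
        rng = np.random.default_rng(20)
        out = rating_difference_analysis(_ratings_frame(rng), seed=21)
        assert len(out) == 6
        # 95% intervals: allow one chance exclusion across the six cells
        covers = ((out["cri_lower"] <= 0) & (out["cri_upper"] >= 0)).sum()
        assert covers >= 5
        assert out["mean_difference"].abs().max() < 4.0

    def test_injected_shift_recovered(self):
        rng = np.random.default_rng(22)
        out = rating_difference_analysis(_ratings_frame(rng, shift=5.0), seed=23)
        cell = out[(out["stimulus"] == "happy") & (out["scale"] == "temperament")]
        assert cell["mean_difference"].iloc[0] == pytest.approx(5.0, abs=2.5)

    def test_difference_outcome_drops_incomplete_subjects(self):
        rng = np.random.default_rng(24)
        df = _ratings_frame(rng, n=30)
        df = df[~((df["subject_id"] == "s0") & (df["phase"] == "pre"))]
        out = rating_difference_analysis(df, outcome="difference", seed=25)
        assert (out["n_dropped"] == 1).all()
        assert (out["n"] == 29).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            rating_difference_analysis(pd.DataFrame({"subject_id": []}))
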