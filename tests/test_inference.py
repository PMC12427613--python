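import math
import warnings

import numpy as np
import pytest
from scipy.stats import chisquare

import banditref.inference as inf
from banditref.cohort import CohortConfig, generate_cohort
from banditref.inference import (
    Diagnostics,
    PopulationParams,
    PosteriorSamples,
    condition_contrast,
    effective_sample_size,
    fit_hierarchical,
    hdi,
    hierarchical_log_posterior,
    link_forward,
    link_inverse,
    run_mcmc,
    sbc_ranks,
    split_rhat,
)


class TestLinks:
    def test_symmetry_points(self):
        assert link_forward(0.5, 1.0, 0.0) == pytest.approx((0.0, 0.0, 0.0))
        assert link_inverse(0.0, 0.0, 0.0) == pytest.approx((0.5, 1.0, 0.0))

    def test_round_trip_on_random_triples(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(1000):
            a, t, e = rng.uniform(0.01, 0.99), rng.uniform(0.05, 20), rng.uniform(-0.95, 0.95)
            back = link_inverse(*link_forward(a, t, e))
            worst = max(worst, abs(back[0] - a), abs(back[1] - t), abs(back[2] - e))
        assert worst < 1e-10

    def test_boundary_values_clamp_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            x, _, _ = link_forward(1.0, 1.0, 0.0)
        assert x == inf.LINK_CLAMP
        with pytest.warns(UserWarning, match="clamped"):
            _, xt, _ = link_forward(0.5, 0.0, 0.0)
        assert xt == -inf.LINK_CLAMP

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            link_forward(1.2, 1.0, 0.0)


class TestHdi:
    def test_uniform_width(self):
        rng = np.random.default_rng(1)
        interval = hdi(rng.uniform(0, 1, 100_000))
        assert interval.width == pytest.approx(0.95, abs=0.01)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(2)
        interval = hdi(rng.standard_normal(100_000))
        assert interval.lower == pytest.approx(-1.96, abs=0.03)
        assert interval.upper == pytest.approx(1.96, abs=0.03)

    def test_point_mass_zero_width(self):
        interval = hdi(np.full(50, 3.14))
        assert interval.width == 0.0

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="20"):
            hdi(np.arange(10))

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 1.0, 20_000)
        ours = hdi(x)
        theirs = az.hdi(x, hdi_prob=0.95)
        assert ours.lower == pytest.approx(theirs[0], abs=0.02)
        assert ours.upper == pytest.approx(theirs[1], abs=0.02)


class TestSplitRhat:
    def test_white_noise_near_one(self):
        rng = np.random.default_rng(4)
        r = split_rhat(rng.standard_normal((2, 1000)))
        assert 0.99 <= r <= 1.01

    def test_separated_chains_detected(self):
        rng = np.random.default_rng(5)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert split_rhat(chains) > 2.0

    def test_within_chain_trend_detected(self):
        # split-chain construction catches a drifting single-mode chain
        rng = np.random.default_rng(6)
        drift = np.linspace(0, 5, 800) + rng.normal(0, 0.1, 800)
        chains = np.stack([drift, drift + rng.normal(0, 0.1, 800)])
        assert split_rhat(chains) > 1.05

    def test_degenerate_chains_nan(self):
        assert math.isnan(split_rhat(np.ones((2, 100))))

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(7)
        x = np.cumsum(rng.standard_normal((4, 400)), axis=1) * 0.05
        x += rng.standard_normal((4, 400))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = float(az.rhat(x, method="split"))
        assert split_rhat(x) == pytest.approx(theirs, abs=0.01)


def test_effective_sample_size_iid_close_to_n():
    rng = np.random.default_rng(8)
    ess = effective_sample_size(rng.standard_normal((4, 500)))
    assert 1200 < ess <= 2000


def test_effective_sample_size_correlated_is_smaller():
    rng = np.random.default_rng(9)
    x = rng.standard_normal((4, 1000))
    for t in range(1, 1000):
        x[:, t] = 0.95 * x[:, t - 1] + math.sqrt(1 - 0.95**2) * x[:, t]
    assert effective_sample_size(x) < 400


class TestHierarchicalLogPosterior:
    def test_zero_subjects_is_hyperprior_only(self):
        vec = np.array([0.3, -0.2, 0.1, 0.0, 0.0, 0.0])  # mu (3), log sigma (3)
        lp = hierarchical_log_posterior([], vec, model="reference")
        c = 0.5 * math.log(2 * math.pi)
        expected = sum(-0.5 * m**2 - c for m in (0.3, -0.2, 0.1))
        expected += 3 * (0.5 * math.log(2 / math.pi) - 0.5)  # sigma=1, lsig=0
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_likelihood_stub_decomposition(self, small_cohort):
        datasets = small_cohort.datasets[:1]
        n_params = 3
        dim = 2 * n_params + n_params
        vec = np.zeros(dim)
        lp_null = hierarchical_log_posterior(
            datasets, vec, loglik_fn=lambda s, a, t, e: 0.0
        )
        lp_const = hierarchical_log_posterior(
            datasets, vec, loglik_fn=lambda s, a, t, e: -7.5
        )
        assert lp_const - lp_null == pytest.approx(-7.5, abs=1e-10)

    def test_sigma_to_zero_pins_subject_at_population_mean(self, small_cohort):
        datasets = small_cohort.datasets[:1]
        seen = {}

        def record(s, a, t, e):
            seen.update(alpha=a, tau=t, eta=e)
            return 0.0

        vec = np.zeros(9)
        vec[3:6] = -20.0  # log sigma -> sigma ~ 0
        vec[6:] = 1.7  # z should have no effect
        hierarchical_log_posterior(datasets, vec, loglik_fn=record)
        assert seen["alpha"] == pytest.approx(0.5, abs=1e-8)
        assert seen["tau"] == pytest.approx(1.0, abs=1e-8)
        assert seen["eta"] == pytest.approx(0.0, abs=1e-8)

    def test_wrong_dimension_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="length"):
            hierarchical_log_posterior(small_cohort.datasets[:2], np.zeros(4))

    def test_batched_path_agrees_with_scalar(self, small_cohort):
        datasets = small_cohort.datasets[:3]
        log_post = inf.HierarchicalLogPosterior(datasets, model="reference")
        rng = np.random.default_rng(10)
        states = rng.normal(0, 0.5, (8, log_post.dim))
        batch = log_post.batch(states)
        loop = [hierarchical_log_posterior(datasets, s) for s in states]
        assert np.allclose(batch, loop, atol=1e-8)


class TestRunMcmc:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.y = rng.normal(0.8, 1.0, 10)
        n = len(self.y)
        self.post_mean = self.y.sum() / (n + 1)
        self.post_sd = 1.0 / math.sqrt(n + 1)

        def logpost(x):
            th = x[0]
            return -0.5 * np.sum((self.y - th) ** 2) - 0.5 * th * th

        self.logpost = logpost

    def test_conjugate_normal_posterior_recovered(self):
        fit = run_mcmc(self.logpost, [0.0], chains=4, iterations=1500,
                       burn_in=500, thin=1, seed=12)
        draws = fit.flat("x0")
        ess = effective_sample_size(fit.get("x0"))
        mcse = draws.std() / math.sqrt(ess)
        assert abs(draws.mean() - self.post_mean) < 3 * mcse + 1e-9
        assert draws.std() == pytest.approx(self.post_sd, rel=0.15)

    def test_same_seed_identical(self):
        a = run_mcmc(self.logpost, [0.0], chains=2, iterations=300, burn_in=100,
                     thin=2, seed=13)
        b = run_mcmc(self.logpost, [0.0], chains=2, iterations=300, burn_in=100,
                     thin=2, seed=13)
        assert np.array_equal(a.draws, b.draws)

    def test_thinning_bookkeeping_exact(self):
        fit = run_mcmc(self.logpost, [0.0], chains=3, iterations=1100, burn_in=100,
                       thin=10, seed=14)
        assert fit.draws.shape == (3, 100, 1)


def test_simulation_based_calibration_ranks_uniform():
    """If the sampler targets the right posterior, the rank of the true
    parameter among posterior draws is uniform across prior replicates."""
    ranks = sbc_ranks(n_replicates=20, n_trials=60, iterations=1200,
                      burn_in=400, thin=4, seed=15)
    n_kept = 200
    edges = np.array([0, 0.25, 0.5, 0.75, 1.0]) * n_kept
    counts = np.histogram(ranks.ravel(), bins=edges)[0]
    stat = chisquare(counts)
    assert stat.pvalue > 0.01


@pytest.fixture(scope="module")
def small_fit(small_cohort):
    return fit_hierarchical(
        small_cohort.datasets, model="reference",
        chains=2, iterations=400, burn_in=100, thin=2, seed=16,
    )


class TestFitHierarchical:
    def test_retained_draw_count_exact(self, small_fit):
        assert small_fit.draws.shape[:2] == (2, 150)

    def test_natural_summaries_respect_ranges(self, small_fit):
        for cond in ("soothe", "keep_happy"):
            a = small_fit.population_natural("alpha", cond)
            t = small_fit.population_natural("tau", cond)
            e = small_fit.population_natural("eta", cond)
            assert np.all((a >= 0) & (a <= 1))
            assert np.all(t >= 0)
            assert np.all((e > -1) & (e < 1))

    def test_subject_medians_table(self, small_fit, small_cohort):
        medians = small_fit.subject_natural_medians()
        assert len(medians) == len(small_cohort.datasets)
        assert medians["alpha"].between(0, 1).all()

    def test_deterministic_under_seed(self, small_cohort):
        kw = dict(model="delta", chains=2, iterations=200, burn_in=50, thin=2)
        a = fit_hierarchical(small_cohort.datasets[:4], seed=17, **kw)
        b = fit_hierarchical(small_cohort.datasets[:4], seed=17, **kw)
        assert np.array_equal(a.draws, b.draws)

    def test_delta_model_has_no_eta(self, small_cohort):
        fit = fit_hierarchical(small_cohort.datasets[:4], model="delta",
                               chains=2, iterations=200, burn_in=50, thin=2, seed=18)
        assert "mu_eta" not in fit.names
        with pytest.raises(ValueError):
            fit.population_natural("eta", "soothe")

    def test_diagnostics_structure(self, small_fit):
        diag = small_fit.diagnostics()
        assert isinstance(diag, Diagnostics)
        assert set(diag.rhat) == set(small_fit.names)

    def test_requires_two_chains(self, small_cohort):
        with pytest.raises(ValueError, match="chains"):
            fit_hierarchical(small_cohort.datasets[:2], chains=1)


class TestConditionContrast:
    def _fake_fit(self, mu, beta, n_draws=400):
        names, cols = [], []
        for p, m in mu.items():
            names.append(f"mu_{p}")
            cols.append(np.full(n_draws, m))
        for p, b in beta.items():
            names.append(f"beta_{p}")
            cols.append(np.asarray(b) * np.ones(n_draws) if np.ndim(b) == 0 else b)
        draws = np.stack(cols, axis=1)[None].repeat(2, axis=0)
        meta = {"model": "reference", "two_cond": True, "n_params": 3,
                "subject_ids": [], "condition_codes": []}
        return PosteriorSamples(draws, names, meta)

    def test_zero_coefficient_is_degenerate_half(self):
        fit = self._fake_fit({"alpha": 0.5, "tau": 0.0, "eta": 0.0},
                             {"alpha": 0.0, "tau": 0.0, "eta": 0.0})
        c = condition_contrast(fit, "alpha")
        assert c.median == 0.0
        assert c.p_positive == 0.5
        assert c.degenerate

    def test_all_positive_differences(self):
        rng = np.random.default_rng(19)
        fit = self._fake_fit({"alpha": 0.0, "tau": 0.0, "eta": 0.0},
                             {"eta": rng.uniform(0.5, 1.0, 400),
                              "alpha": 0.0, "tau": 0.0})
        c = condition_contrast(fit, "eta")
        assert c.p_positive == 1.0
        assert c.median > 0
        assert not c.degenerate

    def test_single_condition_fit_rejected(self, small_cohort):
        soothe_only = [d for d in small_cohort.datasets if d.condition == "soothe"]
        fit = fit_hierarchical(soothe_only[:4], chains=2, iterations=100,
                               burn_in=50, thin=1, seed=20)
        with pytest.raises(ValueError, match="two-condition"):
            condition_contrast(fit, "alpha")


def test_population_params_validation():
    with pytest.raises(ValueError, match="sigma"):
        PopulationParams(mu={p: 0 for p in inf.PARAM_NAMES},
                         sigma={"alpha": -1, "tau": 1, "eta": 1})
    pop = PopulationParams.from_natural_medians(0.92, 1.2, -0.64)
    med = pop.natural_medians(0)
    assert med["alpha"] == pytest.approx(0.92, abs=1e-9)
    assert med["eta"] == pytest.approx(-0.64, abs=1e-9)
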