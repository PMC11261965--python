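"""Variational posterior: conjugate-toy accuracy, support containment, rounds."""

import numpy as np
import pytest
from scipy import stats

from bmpinfer import (
    BmpOnestepSBI,
    PriorSpec,
    ValidationError,
    fit_posterior,
    make_synthetic_study,
)


def gaussian_loglik(xs, sd):
    def fn(thetas):
        th = thetas[:, 0]
        return -0.5 * np.sum((xs[None, :] - th[:, None]) ** 2, axis=1) / sd**2
    return fn


class TestFitPosterior:
    def test_conjugate_gaussian_toy(self):
        # x_i ~ N(theta, sd^2) with an effectively flat prior on a wide box:
        # posterior is N(xbar, sd^2 / n)
        rng = np.random.default_rng(1)
        true, sd, n = 3.0, 0.5, 40
        xs = rng.normal(true, sd, n)
        prior = PriorSpec(low=1e-2, high=1e2, dimension=1)
        post = fit_posterior(gaussian_loglik(xs, sd), prior,
                             config={"n_elbo_draws": 256}, seed=0)
        draws = post.sample(20_000, seed=5)[:, 0]
        xbar, psd = xs.mean(), sd / np.sqrt(n)
        assert draws.mean() == pytest.approx(xbar, rel=0.05)
        assert draws.std() == pytest.approx(psd, rel=0.05)

    def test_flat_likelihood_recovers_prior(self):
        prior = PriorSpec(dimension=1)
        post = fit_posterior(lambda thetas: np.zeros(thetas.shape[0]), prior,
                             config={"n_elbo_draws": 1024}, seed=1)
        draws = np.log10(post.sample(2000, seed=2)[:, 0])
        ref = np.random.default_rng(3).uniform(-4, 2, 2000)
        assert stats.ks_2samp(draws, ref).pvalue > 0.01

    def test_samples_always_inside_prior_box(self):
        rng = np.random.default_rng(2)
        xs = rng.normal(1.0, 0.2, 10)
        prior = PriorSpec(dimension=1)
        post = fit_posterior(gaussian_loglik(xs, 0.2), prior, seed=3)
        draws = post.sample(10_000, seed=4)
        assert np.all((draws >= 1e-4) & (draws <= 1e2))

    def test_log_density_finite_at_own_samples(self):
        rng = np.random.default_rng(5)
        xs = rng.normal(2.0, 0.3, 15)
        prior = PriorSpec(dimension=1)
        post = fit_posterior(gaussian_loglik(xs, 0.3), prior, seed=6)
        draws = post.sample(200, seed=7)
        assert np.all(np.isfinite(post.log_density(draws)))
        assert np.all(np.isfinite(post.log_density_log10(np.log10(draws))))

    def test_elbo_trace_non_decreasing_up_to_tolerance(self):
        rng = np.random.default_rng(8)
        xs = rng.normal(0.5, 0.1, 20)
        prior = PriorSpec(dimension=1)
        post = fit_posterior(gaussian_loglik(xs, 0.1), prior, seed=9)
        trace = np.asarray(post.elbo_trace)
        assert trace.size >= 2
        drops = np.diff(trace)
        tol = 1e-3 * max(1.0, np.abs(trace[-1]))
        assert np.all(drops >= -tol)

    def test_log_density_change_of_variables(self):
        # linear-scale density must equal log10-scale density minus the
        # theta*ln10 Jacobian
        rng = np.random.default_rng(10)
        xs = rng.normal(1.5, 0.4, 10)
        prior = PriorSpec(dimension=2)
        post = fit_posterior(
            lambda t: -0.5 * np.sum((t - 1.5) ** 2, axis=1), prior, seed=11
        )
        theta = post.sample(50, seed=12)
        lhs = post.log_density(theta)
        rhs = post.log_density_log10(np.log10(theta)) - np.sum(
            np.log(theta * np.log(10.0)), axis=1
        )
        assert np.allclose(lhs, rhs, rtol=1e-10)


@pytest.fixture(scope="module")
def quick_fit():
    theta_star, data, prior = make_synthetic_study(seed=42, n_experiments=12)
    model = BmpOnestepSBI(data, noise_sd=0.05)
    results = model.fit(n_rounds=2, seed=0, sims_per_round=128,
                        n_predictive=50, surrogate={"max_iter": 120})
    return theta_star, model, results


class TestRunRounds:
    def test_history_one_record_per_round(self, quick_fit):
        _, _, results = quick_fit
        assert len(results.history) == 2
        df = results.history.to_frame()
        assert list(df["round"]) == [1, 2]
        assert np.all(df["median_distance"] >= 0)
        assert np.all((df["ppc"] >= 0) & (df["ppc"] <= 100))

    def test_posterior_samples_in_support(self, quick_fit):
        _, _, results = quick_fit
        draws = results.sample_posterior(2000, seed=1)
        assert np.all((draws >= 1e-4) & (draws <= 1e2))

    def test_summary_mentions_rounds_and_parameters(self, quick_fit):
        _, _, results = quick_fit
        text = results.summary()
        assert "median distance" in text
        assert "K[0,0,0]" in text and "eps[0,0,0]" in text

    def test_invalid_round_count(self):
        _, data, prior = make_synthetic_study(seed=1, n_experiments=4)
        model = BmpOnestepSBI(data)
        with pytest.raises(ValidationError):
            model.fit(n_rounds=0)


class TestParameterRecovery:
    def test_posterior_predicts_better_than_prior(self):
        """After a few rounds the posterior predictive should sit closer to
        the observations than the prior predictive in most replicates.

        This is the recoverable form of parameter recovery for this model:
        the equilibrium constant and its efficiency share a ridge (only
        their product is identified below saturation), so pointwise density
        at theta* is not a meaningful target, while predictive closeness is.
        """
        from bmpinfer import median_distance, posterior_predictive_sims, sample_prior

        wins = 0
        n_rep = 5
        for rep in range(n_rep):
            theta_star, data, prior = make_synthetic_study(
                seed=500 + rep, n_experiments=24
            )
            model = BmpOnestepSBI(data, noise_sd=0.05)
            results = model.fit(n_rounds=3, seed=rep, sims_per_round=256,
                                n_predictive=20, surrogate={"max_iter": 200})
            md_post = results.median_distance(n_draws=100, seed=77)
            prior_draws = sample_prior(prior, 2000, 77)
            sims = posterior_predictive_sims(
                prior_draws, model.simulator, data.contexts, 100, seed=78
            )
            md_prior = median_distance(data.observations, sims)
            wins += md_post < md_prior
        assert wins >= int(0.8 * n_rep)
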