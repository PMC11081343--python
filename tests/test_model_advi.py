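"""Joint density properties and the variational fitter."""

import itertools
import math

import numpy as np
import pytest

import quiltsurv as q
from quiltsurv import _autodiff as ad
from quiltsurv._autodiff import Tensor
from quiltsurv.advi import (AdviProblem, QuiltProblem, TrainConfig, fit,
                            posterior_summary)
from quiltsurv.model import ModelData, QuiltModel, QuiltModelConfig
from quiltsurv.pem import PEMConfig


def toy_model_and_data(n=10, seed=0):
    cfg = q.fixture_config(seed=seed, n=max(n, 50))
    df, truth = q.simulate(cfg)
    pem = PEMConfig()
    data = ModelData.build(truth.design[:n], truth.kappas[:n],
                           df["placement"].to_numpy()[:n],
                           np.maximum(df["time"].to_numpy()[:n], 0.5),
                           df["event"].to_numpy()[:n], cfg.lattice, pem)
    model = QuiltModel(QuiltModelConfig(cfg.lattice, truth.design.shape[1],
                                        pem, max_order=1))
    return model, data


class TestJointDensity:
    def test_full_batch_has_unit_scaling(self):
        model, data = toy_model_and_data()
        rng = np.random.default_rng(1)
        z = rng.normal(0, 0.2, model.dim)
        full = float(ad.value_of(model.joint_log_density(z, data, len(data))))
        parts = model.split(z)
        manual = float(ad.value_of(
            model.log_likelihood(model.tables(parts), data)
            + model.log_prior(parts)))
        assert full == pytest.approx(manual, rel=1e-12)

    def test_empty_batch_is_prior_only(self):
        model, data = toy_model_and_data()
        z = np.random.default_rng(2).normal(0, 0.2, model.dim)
        prior_only = float(ad.value_of(
            model.joint_log_density(z, data.subset(np.array([], dtype=int)),
                                    len(data))))
        assert prior_only == pytest.approx(
            float(ad.value_of(model.log_prior(model.split(z)))), rel=1e-12)

    def test_minibatch_estimator_unbiased_by_enumeration(self):
        # averaging the scaled joint density over every 5-of-10 batch
        # reproduces the full-data value exactly
        model, data = toy_model_and_data(n=10)
        z = np.random.default_rng(3).normal(0, 0.2, model.dim)
        full = float(ad.value_of(model.joint_log_density(z, data, 10)))
        prior = float(ad.value_of(model.log_prior(model.split(z))))
        vals = []
        for idx in itertools.combinations(range(10), 5):
            batch = data.subset(np.array(idx))
            vals.append(float(ad.value_of(
                model.joint_log_density(z, batch, 10))))
        assert np.mean(vals) == pytest.approx(full, rel=1e-10)
        # the likelihood part alone is exactly unbiased as well
        assert np.mean(np.asarray(vals) - prior) == pytest.approx(
            full - prior, rel=1e-10)

    def test_density_is_double_precision(self):
        model, data = toy_model_and_data()
        lp = model.joint_log_density(Tensor(np.zeros(model.dim)), data,
                                     len(data))
        assert lp.value.dtype == np.float64

    def test_more_mc_samples_reduce_elbo_variance(self):
        model, data = toy_model_and_data(n=40)
        rng = np.random.default_rng(4)
        mu = rng.normal(0, 0.1, model.dim)
        sigma = 0.05

        def elbo_estimate(S, rng):
            vals = [float(ad.value_of(model.joint_log_density(
                mu + sigma * rng.standard_normal(model.dim), data, len(data))))
                for _ in range(S)]
            return np.mean(vals)

        est1 = [elbo_estimate(1, rng) for _ in range(120)]
        est8 = [elbo_estimate(8, rng) for _ in range(120)]
        assert np.var(est8) < np.var(est1)

    def test_nonfinite_density_aborts_with_trace(self):
        model, data = toy_model_and_data(n=20)

        class Bad(AdviProblem):
            dim = 2
            n_total = 20

            def log_density(self, z, idx):
                return z[0:1].sum() * np.inf

        with pytest.raises(FloatingPointError, match="non-finite"):
            fit(Bad(), TrainConfig(batch_size=5, seed=0))


class ConjugateNormal(AdviProblem):
    """y ~ N(μ, 1) with μ ~ N(0, prior_sd²): closed-form posterior."""

    def __init__(self, y, prior_sd=10.0):
        self.y = y
        self.dim = 1
        self.n_total = len(y)
        self.prior_sd = prior_sd

    def log_density(self, z, idx):
        mu = z[0:1]
        scale = self.n_total / len(idx)
        ll = -0.5 * ad.tsum(ad.square(mu - self.y[idx]))
        return scale * ll - 0.5 * ad.tsum(ad.square(mu / self.prior_sd))


class TestFit:
    def test_conjugate_posterior_recovery(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.5, 1.0, 1000)
        post = fit(ConjugateNormal(y), TrainConfig(batch_size=20, seed=5))
        s2 = 100.0
        n = len(y)
        analytic_mean = y.sum() * s2 / (n * s2 + 1.0)
        analytic_sd = math.sqrt(s2 / (n * s2 + 1.0))
        assert abs(post.mu[0] - analytic_mean) < 0.05
        assert abs(post.sigma[0] - analytic_sd) < 0.02

    def test_loss_decreases_on_synthetic_data(self):
        model, data = toy_model_and_data(n=50)
        post = fit(QuiltProblem(model, data),
                   TrainConfig(batch_size=25, max_epochs=15, seed=2))
        assert post.trace[-1][0] <= post.trace[0][0]

    def test_deterministic_given_seed(self):
        model, data = toy_model_and_data(n=30)
        cfg = TrainConfig(batch_size=15, max_epochs=6, seed=9)
        p1 = fit(QuiltProblem(model, data), cfg)
        p2 = fit(QuiltProblem(model, data), cfg)
        np.testing.assert_array_equal(p1.mu, p2.mu)
        np.testing.assert_array_equal(p1.omega, p2.omega)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(decay=1.5)
        with pytest.raises(ValueError):
            TrainConfig(patience=200, max_epochs=100)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestPosteriorSummary:
    def _posterior(self, mu, omega):
        from quiltsurv.advi import Posterior
        return Posterior(np.asarray(mu, dtype=float),
                         np.asarray(omega, dtype=float), [], TrainConfig())

    def test_degenerate_scale_collapses_to_location(self):
        post = self._posterior([1.5], [-30.0])
        s = posterior_summary(post, n_draws=500, seed=0)
        assert s["mean"][0] == pytest.approx(1.5, abs=1e-9)
        assert s["hi95"][0] - s["lo95"][0] < 1e-9

    def test_matches_gaussian_closed_form(self):
        post = self._posterior([2.0], [0.0])  # N(2, 1)
        s = posterior_summary(post, n_draws=40_000, seed=1)
        assert s["mean"][0] == pytest.approx(2.0, abs=0.03)
        assert s["sd"][0] == pytest.approx(1.0, abs=0.03)
        assert s["lo95"][0] == pytest.approx(2 - 1.96, abs=0.06)

    def test_constrained_transform_stays_nonpositive(self):
        post = self._posterior([1.0], [0.5])
        s = posterior_summary(post, n_draws=2000, seed=2,
                              transform=lambda z: -np.logaddexp(0, z))
        assert s["mean"][0] <= 0 and s["hi95"][0] <= 0

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            posterior_summary(self._posterior([0.0], [0.0]), n_draws=1)
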