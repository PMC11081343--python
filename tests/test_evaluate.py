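"""Metrics, interpretation tables, exact attribution and KernelSHAP."""

import itertools
import math

import numpy as np
import pytest

from quiltsurv.advi import Posterior, TrainConfig
from quiltsurv.decomposition import Lattice
from quiltsurv.evaluate import (AttributionVector, cohort_baseline_table,
                                disagreement_metrics,
                                ground_truth_attribution, horizon_metrics,
                                kernel_shap, risk_factor_table,
                                treatment_effect_table)
from quiltsurv.model import QuiltModel, QuiltModelConfig
from quiltsurv.pem import PEMConfig


def pairwise_auroc_oracle(scores, labels):
    """Exhaustive positive-negative pair comparison with half-credit ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestHorizonMetrics:
    def test_perfect_separation(self):
        auroc, auprc = horizon_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auroc == 1.0 and auprc == 1.0

    def test_all_tied_scores(self):
        auroc, _ = horizon_metrics([0.5] * 6, [1, 0, 1, 0, 0, 1])
        assert auroc == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=300).round(2)  # rounding forces ties
        labels = rng.integers(0, 2, 300)
        auroc, _ = horizon_metrics(scores, labels)
        assert auroc == pytest.approx(pairwise_auroc_oracle(scores, labels),
                                      abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            horizon_metrics([0.1, 0.2], [1, 1])


def shrunk_posterior(model, assignments, scale=-20.0):
    """Posterior concentrated at chosen latent locations (tiny scales)."""
    mu = np.zeros(model.dim)
    for key, value in assignments.items():
        lo, hi, shape = model._slices[key]
        mu[lo:hi] = np.asarray(value, dtype=float).ravel()
    return Posterior(mu, np.full(model.dim, scale), [], TrainConfig())


@pytest.fixture
def small_model():
    lat = Lattice(("a", "b"), (2, 2))
    return QuiltModel(QuiltModelConfig(lat, 4, PEMConfig(), max_order=2))


class TestInterpretationTables:
    def test_planted_signal_ranks_first(self, small_model):
        raw = np.zeros((4, 4))
        raw[0, 2] = 3.0  # interval 0, feature 2
        post = shrunk_posterior(small_model, {("beta", 0, "value"): raw,
                                              ("beta", 0, "ulocal"): np.full((4, 4), 2.0),
                                              ("beta", None, "uglobal"): 2.0})
        table = risk_factor_table(small_model, post, interval=0, k=4,
                                  n_draws=100, seed=0)
        assert table.iloc[0]["predictor"] == "x2"
        assert table.iloc[0]["mean"] > 0

    def test_k_zero_empty_and_k_large_warns(self, small_model):
        post = shrunk_posterior(small_model, {})
        assert len(risk_factor_table(small_model, post, k=0, n_draws=50)) == 0
        with pytest.warns(UserWarning, match="truncated"):
            risk_factor_table(small_model, post, k=99, n_draws=50)

    def test_zero_order_alpha_gives_identical_rows(self, small_model):
        post = shrunk_posterior(
            small_model, {("alpha", 0, "value"): [-3.0, -4.0, -4.5, -5.0]})
        table = cohort_baseline_table(small_model, post, n_draws=100, seed=1)
        hazard_cols = table.columns[2:]
        assert len(table) == 4  # one row per lattice cell
        assert np.allclose(table[hazard_cols].std(axis=0), 0.0, atol=1e-6)

    def test_planted_cohort_elevation_is_cell_maximum(self, small_model):
        first_order = np.zeros((2, 4))
        first_order[1, 0] = 2.0   # cohorts with a=1 elevated in interval 0
        post = shrunk_posterior(small_model,
                                {("alpha", 1, "value"): first_order})
        table = cohort_baseline_table(small_model, post, n_draws=100, seed=2)
        col = table.columns[2]    # first interval
        assert table.loc[table[col].idxmax(), "a"] == 1

    def test_treatment_effects_nonpositive_with_positive_sd(self, small_model):
        rng = np.random.default_rng(3)
        post = shrunk_posterior(
            small_model,
            {("gamma", 0, "value"): rng.normal(size=(4, 10))}, scale=-2.0)
        table = treatment_effect_table(small_model, post, n_draws=200, seed=3)
        means = table[[c for c in table.columns if c.endswith("mean")]]
        sds = table[[c for c in table.columns if c.endswith("sd")]]
        assert (means.to_numpy() <= 0).all()
        assert (sds.to_numpy() > 0).all()

    def test_strong_cohort_effect_is_most_negative(self, small_model):
        raw = np.zeros((4, 10))
        raw[0, 5:] = 0.0
        second = np.zeros((2, 2, 4, 10))
        second[1, 1, 0, 5:] = -4.0  # cohort (1,1): strongly negative effects
        post = shrunk_posterior(small_model,
                                {("gamma", 3, "value"): second})
        table = treatment_effect_table(small_model, post, n_draws=100, seed=4)
        col = "placement>=5 mean"
        worst = table.loc[table[col].idxmin()]
        assert worst["a"] == 1 and worst["b"] == 1


class TestGroundTruthAttribution:
    def test_zero_features(self):
        att = ground_truth_attribution(np.array([0.3, -0.2]), np.zeros(2), -3.0)
        assert att.contributions.tolist() == [0.0, 0.0]
        assert att.total == -3.0

    def test_simple_arithmetic(self):
        att = ground_truth_attribution(np.array([0.2, -0.1]), np.ones(2), -3.0)
        np.testing.assert_allclose(att.contributions, [0.2, -0.1])
        assert att.total == pytest.approx(-2.9, abs=1e-15)

    def test_exactness_against_log_hazard(self, small_model):
        # base + sum of contributions reproduces the model's linear predictor
        rng = np.random.default_rng(5)
        z = rng.normal(0, 0.3, small_model.dim)
        from quiltsurv import _autodiff as ad
        tabs = {k: ad.value_of(v) for k, v in
                small_model.tables(small_model.split(z)).items()}
        x = rng.integers(0, 2, 4).astype(float)
        treat = np.concatenate([np.sort(rng.uniform(size=5))[::-1],
                                [1, 0, 0, 0, 0]])
        cell, interval = 2, 1
        base = tabs["alpha"][cell, interval] + \
            tabs["gamma"][cell, interval] @ treat
        att = ground_truth_attribution(tabs["beta"][cell, interval], x, base)
        manual = tabs["alpha"][cell, interval] \
            + tabs["beta"][cell, interval] @ x \
            + tabs["gamma"][cell, interval] @ treat
        assert att.total == pytest.approx(manual, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="align"):
            ground_truth_attribution(np.ones(3), np.ones(2), 0.0)


def exact_shapley(value_fn, p):
    """Enumerate all orderings: the textbook Shapley value."""
    phi = np.zeros(p)
    for order in itertools.permutations(range(p)):
        cur = frozenset()
        for j in order:
            phi[j] += value_fn(cur | {j}) - value_fn(cur)
            cur = cur | {j}
    return phi / math.factorial(p)


DUP_BG = np.array([[0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=float)


def dup_model(mat):
    """Uses feature 0 (whose twin is feature 1) and feature 2."""
    return 1.0 * mat[:, 0] + 0.8 * mat[:, 2]


class TestKernelShap:
    def test_additive_model_closed_form(self):
        rng = np.random.default_rng(6)
        beta = np.array([0.5, -0.3, 0.8, 0.1])
        bg = rng.integers(0, 2, size=(64, 4)).astype(float)
        x = np.array([1.0, 1.0, 0.0, 1.0])

        def f(mat):
            return mat @ beta

        att = kernel_shap(f, x, bg, n_coalitions=64, seed=0)
        np.testing.assert_allclose(att.contributions,
                                   beta * (x - bg.mean(axis=0)), atol=1e-8)

    def test_efficiency_constraint(self):
        rng = np.random.default_rng(7)
        bg = rng.normal(size=(50, 6))
        x = rng.normal(size=6)

        def f(mat):
            return np.tanh(mat).sum(axis=1)

        att = kernel_shap(f, x, bg, n_coalitions=40, seed=1)
        assert att.total == pytest.approx(float(f(x[None, :])[0]), abs=1e-8)

    def test_duplicated_feature_splits_attribution(self):
        x = np.ones(3)
        att = kernel_shap(dup_model, x, DUP_BG, n_coalitions=8, seed=0,
                          sampling="conditional")

        def v(S):
            if not S:
                return float(dup_model(DUP_BG).mean())
            mask = np.zeros(3, dtype=bool)
            mask[list(S)] = True
            match = np.all(DUP_BG[:, mask] == x[mask], axis=1)
            return float(dup_model(DUP_BG[match]).mean())

        oracle = exact_shapley(v, 3)
        np.testing.assert_allclose(att.contributions, oracle, atol=1e-8)
        # the twin features share what the exact attribution gives to one
        assert att.contributions[0] == pytest.approx(att.contributions[1],
                                                     abs=1e-8)
        truth = ground_truth_attribution(np.array([1.0, 0.0, 0.8]), x,
                                         base=0.0)
        rho, overlap = disagreement_metrics(att, truth, top_k=1)
        assert overlap == 0.0 or rho < 1.0

    def test_coalition_budget_validation(self):
        with pytest.raises(ValueError, match="n_coalitions"):
            kernel_shap(lambda m: m.sum(1), np.ones(5), np.ones((3, 5)),
                        n_coalitions=3)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        bg = rng.normal(size=(30, 8))
        x = rng.normal(size=8)

        def f(mat):
            return (mat ** 2).sum(axis=1)

        a = kernel_shap(f, x, bg, n_coalitions=100, seed=3)
        b = kernel_shap(f, x, bg, n_coalitions=100, seed=3)
        np.testing.assert_array_equal(a.contributions, b.contributions)


class TestDisagreementMetrics:
    def test_identical_vectors(self):
        a = AttributionVector(np.array([0.5, -0.3, 0.1]), 0.0)
        rho, overlap = disagreement_metrics(a, a, top_k=2)
        assert rho == pytest.approx(1.0) and overlap == 1.0

    def test_reversed_ranking(self):
        a = AttributionVector(np.array([3.0, 2.0, 1.0]), 0.0)
        b = AttributionVector(np.array([1.0, 2.0, 3.0]), 0.0)
        rho, _ = disagreement_metrics(a, b)
        assert rho == pytest.approx(-1.0)

    def test_too_few_features(self):
        a = AttributionVector(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            disagreement_metrics(a, a)
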