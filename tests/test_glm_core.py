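"""Core gamma-divergence math: probabilities, per-sample terms, objective,
analytic gradient and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammaglm import (
    Dataset, ModelConfig, PenaltySpec,
    objective, objective_gradient, predict, sample_gradients,
    sample_term, sample_term_logit_form, success_prob, add_intercept,
)


class TestSuccessProb:
    @pytest.mark.parametrize("link", ["logit", "probit"])
    def test_zero_beta_gives_half(self, rng, link):
        X = rng.standard_normal((20, 4))
        assert np.allclose(success_prob(X, np.zeros(4), link), 0.5)

    def test_logit_closed_form(self):
        # x'beta = ln 3  =>  pi = 3/4
        assert success_prob([[1.0]], [np.log(3.0)], "logit")[0] == pytest.approx(0.75)

    def test_extreme_predictor_no_overflow(self):
        p = success_prob([[1.0]], [1000.0], "logit")[0]
        assert np.isfinite(p) and p < 1.0
        # log-domain evaluation agrees where both are representable
        z = 30.0
        direct = np.exp(z) / (1.0 + np.exp(z))
        assert success_prob([[1.0]], [z], "logit")[0] == pytest.approx(direct, rel=1e-12)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        X = rng.standard_normal((50, 2)) * 100
        for link in ("logit", "probit"):
            p = success_prob(X, np.array([5.0, -5.0]), link)
            assert np.all(p > 0.0) and np.all(p < 1.0)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            success_prob(rng.standard_normal((5, 3)), np.zeros(4))

    def test_nonfinite_beta_raises(self):
        with pytest.raises(ValueError):
            success_prob([[1.0, 2.0]], [np.nan, 1.0])


class TestSampleTerm:
    def test_zero_beta_value(self, rng):
        # pi = 1/2 => phi = (1/2)^{gamma/(gamma+1)} = 2^{-1/3} at gamma=0.5
        X = rng.standard_normal((10, 3))
        y = rng.integers(0, 2, 10)
        phi = sample_term(X, y, np.zeros(3), gamma=0.5)
        assert np.allclose(phi, 2.0 ** (-1.0 / 3.0))

    def test_gamma_to_zero_limit_is_one(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.integers(0, 2, 10)
        beta = rng.standard_normal(3)
        phi = sample_term(X, y, beta, gamma=1e-8)
        assert np.allclose(phi, 1.0, atol=1e-6)

    def test_logit_form_identity(self, rng):
        """The general form and the logistic algebraic form agree to 1e-12."""
        for _ in range(200):
            n, d = 5, 3
            X = rng.standard_normal((n, d)) * rng.uniform(0.5, 3)
            y = rng.integers(0, 2, n)
            beta = rng.standard_normal(d) * rng.uniform(0.5, 3)
            gamma = rng.uniform(0.05, 3.0)
            a = sample_term(X, y, beta, gamma, "logit")
            b = sample_term_logit_form(X, y, beta, gamma)
            np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("link", ["logit", "probit"])
    def test_bounds(self, rng, link):
        X = rng.standard_normal((100, 4)) * 10
        y = rng.integers(0, 2, 100)
        beta = rng.standard_normal(4) * 5
        phi = sample_term(X, y, beta, 0.5, link)
        assert np.all(phi > 0.0) and np.all(phi <= 1.0)

    def test_monotone_in_margin(self):
        """For y=1 phi increases with x'beta; for y=0 it decreases (logit)."""
        z = np.linspace(-6, 6, 200)[:, None]
        up = sample_term(z, np.ones(200, dtype=int), [1.0], 0.5)
        dn = sample_term(z, np.zeros(200, dtype=int), [1.0], 0.5)
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(dn) < 0)

    def test_invalid_gamma(self, rng):
        with pytest.raises(ValueError):
            sample_term(rng.standard_normal((3, 2)), [0, 1, 0], np.zeros(2), 0.0)


class TestObjective:
    def test_zero_beta_closed_form(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.integers(0, 2, 10)
        ds = Dataset(X=X, y_observed=y)
        cfg = ModelConfig(gamma=0.5, penalty=PenaltySpec("scad", lambda_n=1.0))
        # P(0) = 0 for every penalty, so only the sample sum remains
        assert objective(ds, np.zeros(4), cfg) == pytest.approx(10 * 2 ** (-1 / 3))

    def test_no_penalty_equals_zero_lambda(self, rng):
        X = rng.standard_normal((15, 3))
        y = rng.integers(0, 2, 15)
        beta = rng.standard_normal(3)
        ds = Dataset(X=X, y_observed=y)
        a = objective(ds, beta, ModelConfig(penalty=PenaltySpec("none")))
        b = objective(ds, beta, ModelConfig(penalty=PenaltySpec("scad", lambda_n=0.0)))
        assert a == pytest.approx(b, abs=1e-12)

    def test_composition_oracle(self, rng):
        """Q equals independent re-summation of phi minus n * penalty total."""
        from gammaglm.penalties import penalty_value
        X = rng.standard_normal((12, 5))
        y = rng.integers(0, 2, 12)
        beta = rng.standard_normal(5)
        ds = Dataset(X=X, y_observed=y)
        spec = PenaltySpec("mcp", lambda_n=0.4)
        cfg = ModelConfig(gamma=0.7, penalty=spec)
        expected = (sum(sample_term(X[i:i + 1], y[i:i + 1], beta, 0.7)[0]
                        for i in range(12))
                    - 12 * penalty_value(np.abs(beta), spec).sum())
        assert objective(ds, beta, cfg) == pytest.approx(expected, abs=1e-12)


class TestGradient:
    def test_symmetric_pair_cancels_at_zero(self):
        # same x, one y=1 and one y=0 at beta=0: scores cancel exactly
        X = np.array([[0.7, -1.2], [0.7, -1.2]])
        ds = Dataset(X=X, y_observed=[1, 0])
        cfg = ModelConfig(gamma=0.5)
        g = objective_gradient(ds, np.zeros(2), cfg)
        np.testing.assert_allclose(g, 0.0, atol=1e-14)

    @pytest.mark.parametrize("link", ["logit", "probit"])
    @pytest.mark.parametrize("kind", ["none", "scad", "mcp", "lasso"])
    def test_finite_difference_oracle(self, rng, link, kind):
        for _ in range(7):
            n, d = 10, 4
            X = rng.standard_normal((n, d))
            y = rng.integers(0, 2, n)
            beta = rng.standard_normal(d)
            ds = Dataset(X=X, y_observed=y)
            cfg = ModelConfig(gamma=float(rng.uniform(0.2, 1.5)), link=link,
                              penalty=PenaltySpec(kind, lambda_n=0.3))
            g = objective_gradient(ds, beta, cfg)
            h = 1e-6
            for j in range(d):
                bp, bm = beta.copy(), beta.copy()
                bp[j] += h
                bm[j] -= h
                fd = (objective(ds, bp, cfg) - objective(ds, bm, cfg)) / (2 * h)
                assert abs(g[j] - fd) / (1.0 + abs(fd)) < 1e-6

    def test_scad_flat_past_alpha_lambda(self, rng):
        """Past alpha*lambda the SCAD force vanishes: penalized and
        unpenalized gradients coincide."""
        X = rng.standard_normal((8, 3))
        y = rng.integers(0, 2, 8)
        ds = Dataset(X=X, y_observed=y)
        beta = np.array([5.0, -6.0, 7.0])  # all |beta_j| > 3.7 * 1.0
        g_pen = objective_gradient(ds, beta, ModelConfig(
            penalty=PenaltySpec("scad", lambda_n=1.0)))
        g_none = objective_gradient(ds, beta, ModelConfig())
        np.testing.assert_allclose(g_pen, g_none, atol=1e-12)

    def test_per_sample_gradients_sum_to_total(self, rng):
        X = rng.standard_normal((9, 3))
        y = rng.integers(0, 2, 9)
        beta = rng.standard_normal(3)
        phi, G = sample_gradients(X, y, beta, 0.5)
        ds = Dataset(X=X, y_observed=y)
        g = objective_gradient(ds, beta, ModelConfig(gamma=0.5))
        np.testing.assert_allclose(G.sum(axis=0), g, atol=1e-12)
        assert G.shape == (9, 3)
        assert np.all(phi > 0) and np.all(phi <= 1)


class TestPredict:
    def test_zero_beta_ties_to_one(self, rng):
        X = rng.standard_normal((10, 3))
        assert np.all(predict(X, np.zeros(3)) == 1)

    @pytest.mark.parametrize("link", ["logit", "probit"])
    def test_sign_of_margin(self, rng, link):
        X = rng.standard_normal((50, 4))
        beta = rng.standard_normal(4)
        preds = predict(X, beta, link)
        margin = X @ beta
        assert np.all(preds[margin > 0] == 1)
        assert np.all(preds[margin < 0] == 0)

    def test_equals_thresholded_probability(self, rng):
        X = rng.standard_normal((30, 3))
        beta = rng.standard_normal(3)
        np.testing.assert_array_equal(
            predict(X, beta), (success_prob(X, beta) >= 0.5).astype(int))


class TestDataset:
    def test_rejects_nonbinary_labels(self, rng):
        with pytest.raises(ValueError):
            Dataset(X=rng.standard_normal((3, 2)), y_observed=[0, 1, 2])

    def test_rejects_nonfinite_features(self):
        with pytest.raises(ValueError):
            Dataset(X=[[1.0, np.inf]], y_observed=[1])

    def test_rejects_inconsistent_flip_mask(self, rng):
        X = rng.standard_normal((2, 2))
        with pytest.raises(ValueError):
            Dataset(X=X, y_observed=[0, 1], y_true=[0, 0],
                    flip_mask=[True, False])

    def test_intercept_helper(self, rng):
        X = rng.standard_normal((4, 2))
        Xi = add_intercept(X)
        assert Xi.shape == (4, 3)
        assert np.all(Xi[:, 0] == 1.0)


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 2**31 - 1))
def test_sample_term_bounds_property(seed):
    """phi stays in (0, 1] for arbitrary finite inputs."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((20, 3)) * rng.uniform(0.1, 20)
    y = rng.integers(0, 2, 20)
    beta = rng.standard_normal(3) * rng.uniform(0.1, 20)
    gamma = rng.uniform(0.01, 5.0)
    for link in ("logit", "probit"):
        phi = sample_term(X, y, beta, gamma, link)
        assert np.all(phi > 0.0)
        assert np.all(phi <= 1.0)
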