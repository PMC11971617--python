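import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import regpcm as rp
from regpcm.likelihood import (
    NominalEvaluator,
    PatternEvaluator,
    nominal_score_vector,
)

LOG_2_6487 = np.log(1 + np.exp(0.5))


def finite_difference_gradient(f, theta, h=1e-6):
    g = np.zeros_like(theta)
    for i in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        g[i] = (f(tp) - f(tm)) / (2 * h)
    return g


def random_small_model(rng, v=4):
    design = rp.TestDesign(m=(2, 1, 2))
    spec = rp.CGFSpec(v=v, deg2=None)
    free = rng.normal(scale=0.1, size=spec.n_free)
    return rp.ModelParams(
        design=design,
        beta=rng.normal(scale=1.0, size=design.n_beta),
        alpha=rng.uniform(0.5, 1.5, size=design.k),
        eps=spec.epsilons(free),
        y0=(0, 0, 0),
        support=rp.all_patterns(design),
    )


class TestLinearPredictor:
    def test_example_fit_pattern(self, example_fit):
        c = rp.dummy_code((1, 0, 0, 0, 0), (0, 0, 0, 0, 0), example_fit.params.design)
        u = rp.linear_predictor(example_fit.params.alpha, c.y_tilde)
        assert u == pytest.approx(1.397, abs=2e-3)

    def test_zero_and_mixed(self):
        assert rp.linear_predictor([1.0, 2.0], [0, 0]) == 0.0
        assert rp.linear_predictor([1.0, 1.0], [-2, 3]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rp.linear_predictor([1.0], [1, 2])


class TestPatternLogWeight:
    def test_reference_pattern_weight_is_zero(self, toy_two_pattern):
        assert rp.pattern_log_weight(toy_two_pattern, (0,)) == 0.0

    def test_toy_weight_is_half(self, toy_two_pattern):
        assert rp.pattern_log_weight(toy_two_pattern, (1,)) == pytest.approx(0.5)

    def test_example_fit_weight(self, example_fit):
        # beta_11 + K(alpha_1) = -4.340 + 0.869
        w = rp.pattern_log_weight(example_fit.params, (1, 0, 0, 0, 0))
        assert w == pytest.approx(-3.471, abs=5e-3)


class TestLogNormalizer:
    def test_singleton_support(self):
        design = rp.TestDesign(m=(1,))
        params = rp.ModelParams(
            design=design,
            beta=np.array([0.3]),
            alpha=np.array([1.0]),
            eps=rp.CGFSpec(v=2).epsilons(),
            y0=(0,),
            support=np.array([[0]]),
        )
        assert rp.log_normalizer(params) == pytest.approx(0.0)

    def test_toy_two_pattern(self, toy_two_pattern):
        assert rp.log_normalizer(toy_two_pattern) == pytest.approx(-LOG_2_6487)

    def test_shift_invariance_of_probabilities(self, toy_two_pattern):
        # adding c to every log weight (shift all beta slots by c with
        # x~ summing to the same) changes ln tau by -c: equivalently,
        # probabilities are invariant to a constant weight shift
        ev = PatternEvaluator(toy_two_pattern)
        w = ev.log_weights()
        from scipy.special import softmax

        np.testing.assert_allclose(softmax(w), softmax(w + 3.7), atol=1e-12)

    def test_y0_outside_support_rejected(self):
        design = rp.TestDesign(m=(1,))
        with pytest.raises(ValueError, match="degenerate"):
            rp.ModelParams(
                design=design,
                beta=np.zeros(1),
                alpha=np.ones(1),
                eps=rp.CGFSpec(v=2).epsilons(),
                y0=(0,),
                support=np.array([[1]]),
            )


class TestPatternProbabilities:
    def test_toy_values(self, toy_two_pattern):
        probs = rp.pattern_probabilities(toy_two_pattern)
        assert probs[(0,)] == pytest.approx(1 / (1 + np.exp(0.5)), abs=1e-4)
        assert probs[(1,)] == pytest.approx(np.exp(0.5) / (1 + np.exp(0.5)), abs=1e-4)

    def test_example_fit_sums_to_one(self, example_fit):
        probs = rp.pattern_probabilities(example_fit.params)
        assert len(probs) == 85
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_normalization_random_models(self, seed):
        params = random_small_model(np.random.default_rng(seed))
        probs = rp.pattern_probabilities(params)
        total = sum(probs.values())
        assert total == pytest.approx(1.0, abs=1e-12)
        assert all(p > 0 for p in probs.values())


class TestLogLikelihood:
    def test_toy_counts(self, toy_two_pattern):
        data = rp.PatternCounts(
            toy_two_pattern.design, np.array([[0], [1]]), np.array([1, 1])
        )
        expected = np.log(1 / (1 + np.exp(0.5))) + np.log(np.exp(0.5) / (1 + np.exp(0.5)))
        assert rp.log_likelihood(toy_two_pattern, data) == pytest.approx(expected)

    def test_single_cell_is_zero(self):
        design = rp.TestDesign(m=(1,))
        params = rp.ModelParams(
            design=design,
            beta=np.array([-2.0]),
            alpha=np.array([0.7]),
            eps=rp.CGFSpec(v=2).epsilons(),
            y0=(0,),
            support=np.array([[0]]),
        )
        data = rp.PatternCounts(design, np.array([[0]]), np.array([9]))
        assert rp.log_likelihood(params, data) == 0.0

    def test_observed_pattern_outside_support_rejected(self, toy_two_pattern):
        design = rp.TestDesign(m=(1,))
        params = rp.ModelParams(
            design=design,
            beta=np.zeros(1),
            alpha=np.ones(1),
            eps=rp.CGFSpec(v=2).epsilons(),
            y0=(0,),
            support=np.array([[0]]),
        )
        data = rp.PatternCounts(design, np.array([[0], [1]]), np.array([1, 1]))
        with pytest.raises(ValueError, match="outside support"):
            rp.log_likelihood(params, data)

    def test_example_fit_loglik(self, example_fit, aggression):
        ll = rp.log_likelihood(example_fit.params, aggression)
        assert ll == pytest.approx(-1055.679, abs=0.02)


class TestScoreVector:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        params = random_small_model(rng)
        data = rp.simulate_from_model(params, 500, seed=rng)
        analytic = rp.score_vector(params, data)

        def loglik_of(theta):
            return rp.log_likelihood(params.with_free_vector(theta), data)

        numeric = finite_difference_gradient(loglik_of, params.free_vector())
        np.testing.assert_allclose(analytic, numeric, rtol=1e-7, atol=1e-5)

    def test_zero_at_optimum(self, example_fit, aggression):
        g = rp.score_vector(example_fit.params, aggression)
        assert np.max(np.abs(g)) < 1e-4

    def test_beta_block_is_moment_difference(self):
        rng = np.random.default_rng(11)
        params = random_small_model(rng)
        data = rp.simulate_from_model(params, 400, seed=rng)
        ev = PatternEvaluator(params)
        counts = ev.counts_on_support(data)
        g = rp.score_vector(params, data)
        n_tilde = counts @ ev.X
        expected_x = data.n * (ev.probabilities() @ ev.X)
        nb = params.design.n_beta
        np.testing.assert_allclose(g[:nb], n_tilde - expected_x, rtol=1e-10)

    def test_concave_in_beta_and_lambda_at_fixed_alpha(self):
        # The multinomial log-likelihood is log-concave in the natural
        # coordinates (beta, lambda) at fixed alpha, where the log
        # weights w = X beta + sum_r lambda_r u^r / r! are linear in the
        # parameters.  (The auxiliary sum-of-squares eps coordinates are
        # a curved image of that space, so concavity is not preserved
        # along eps segments; the maximum value is nonetheless unique.)
        from math import factorial

        from scipy.special import logsumexp

        rng = np.random.default_rng(5)
        params = random_small_model(rng)
        data = rp.simulate_from_model(params, 1000, seed=rng)
        ev = PatternEvaluator(params)
        counts = ev.counts_on_support(data)
        u = ev.Yt @ params.alpha
        v = params.spec.v
        U = np.column_stack([u**r / factorial(r) for r in range(3, v + 1)])

        def loglik(beta, lam_free):
            w = ev.X @ beta + u**2 / 2 + U @ lam_free
            return counts @ w - counts.sum() * logsumexp(w)

        beta0 = params.beta
        lam0 = params.lambdas[3:]
        for _ in range(10):
            db = rng.normal(size=beta0.shape)
            dl = rng.normal(size=lam0.shape)
            norm = np.sqrt(db @ db + dl @ dl)
            db, dl = db / norm, dl / norm
            vals = [
                loglik(beta0 + t * db, lam0 + t * dl) for t in np.linspace(-1, 1, 21)
            ]
            assert np.all(np.diff(vals, 2) <= 1e-8 * max(1.0, np.abs(vals).max()))


class TestNominalModel:
    def test_reduces_to_partial_credit(self, example_fit, aggression):
        nominal = rp.NominalParams.from_gpcm(example_fit.params)
        assert rp.nominal_log_likelihood(nominal, aggression) == pytest.approx(
            example_fit.loglik, abs=1e-9
        )

    def test_toy_weight_under_eta(self):
        design = rp.TestDesign(m=(1,))
        params = rp.NominalParams(
            design=design,
            beta=np.zeros(1),
            eta=np.array([0.5]),
            eps=rp.CGFSpec(v=2).epsilons(),
            y0=(0,),
            support=np.array([[0], [1]]),
        )
        ev = NominalEvaluator(params)
        w = ev.log_weights()
        np.testing.assert_allclose(w, [0.0, 0.125])  # K(0.5) = 0.125

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        base = random_small_model(rng)
        params = rp.NominalParams.from_gpcm(base)
        data = rp.simulate_from_model(base, 600, seed=rng)
        analytic = nominal_score_vector(params, data)

        def loglik_of(theta):
            return rp.nominal_log_likelihood(params.with_free_vector(theta), data)

        numeric = finite_difference_gradient(loglik_of, params.free_vector())
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-5)
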