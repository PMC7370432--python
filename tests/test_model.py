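"""Statistical core: aggregate patterns, ML scaling, Gamma prior, scores.

Independent oracles: numeric argmax for the ML scaling, adaptive quadrature
of the Gamma-Poisson integral for the posterior predictive, and closed-form
reductions (all-zero counts, the d = 1 negative-binomial identity).
"""

import json

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from enhancerscan.model import (
    CLASSES,
    ClassModel,
    ClassModelSet,
    GammaPrior,
    aggregate_pattern,
    build_feature_matrix,
    fit_gamma_prior,
    log_likelihood_score,
    log_posterior_predictive,
    ml_alpha,
)


def quadrature_log_pp(y, x, a0, b0):
    """Oracle: log of integral Gamma(a|a0,b0) * prod_j Poisson(y_j|a*x_j) da,
    evaluated by adaptive quadrature after factoring out the mode value."""
    y, x = np.asarray(y, float), np.asarray(x, float)

    def logf(a):
        return (
            stats.gamma.logpdf(a, a0, scale=1 / b0)
            + np.sum(stats.poisson.logpmf(y, a * x))
        )

    # crude mode bracket
    grid = np.linspace(1e-6, max(10.0, 5 * (y.sum() + a0) / (x.sum() + b0)), 400)
    fmax = max(logf(a) for a in grid)
    val, _ = integrate.quad(
        lambda a: np.exp(logf(a) - fmax), 0, np.inf, limit=400
    )
    return fmax + np.log(val)


class TestAggregatePattern:
    def test_column_mean(self):
        np.testing.assert_allclose(
            aggregate_pattern(np.array([[2, 4], [0, 2]])), [1, 3]
        )

    def test_identical_rows(self):
        r = np.array([3.0, 1.0, 4.0])
        np.testing.assert_allclose(aggregate_pattern(np.tile(r, (7, 1))), r)

    def test_random_matrix_matches_oracle(self, rng):
        Y = rng.integers(0, 40, size=(50, 20))
        oracle = np.array([Y[:, j].sum() / 50 for j in range(20)])
        np.testing.assert_allclose(aggregate_pattern(Y), oracle)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            aggregate_pattern(np.empty((0, 5)))


class TestMlAlpha:
    def test_identity_and_simple_ratio(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ml_alpha(x, x) == 1.0
        assert ml_alpha(np.array([2, 4, 6]), x) == 2.0

    def test_zero_counts_give_zero(self):
        assert ml_alpha(np.zeros(3), np.ones(3)) == 0.0

    def test_degenerate_pattern_is_error(self):
        with pytest.raises(ValueError):
            ml_alpha(np.ones(3), np.zeros(3))

    def test_closed_form_matches_numeric_argmax(self, rng):
        for _ in range(30):
            d = int(rng.integers(1, 10))
            x = rng.uniform(0.1, 5.0, d)
            y = rng.poisson(2.0 * x)
            if y.sum() == 0:
                continue
            ahat = ml_alpha(y, x)
            res = minimize_scalar(
                lambda a: -log_likelihood_score(y, x, a),
                bounds=(1e-9, 10 * ahat),
                method="bounded",
                options={"xatol": 1e-12},
            )
            assert abs(res.x - ahat) / ahat < 1e-6


class TestGammaPrior:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GammaPrior(0.0, 1.0)
        with pytest.raises(ValueError):
            GammaPrior(1.0, -2.0)

    def test_all_equal_is_degenerate(self):
        with pytest.raises(ValueError, match="variance"):
            fit_gamma_prior(np.full(100, 2.0))

    def test_recovery_on_gamma_draws(self):
        rng = np.random.default_rng(42)
        draws = rng.gamma(3.0, 1 / 2.0, size=5000)
        prior = fit_gamma_prior(draws)
        assert abs(prior.a0 - 3.0) / 3.0 < 0.05
        assert abs(prior.b0 - 2.0) / 2.0 < 0.05

    def test_mle_beats_moments_initializer(self, rng):
        draws = rng.gamma(2.5, 1 / 1.5, size=400)
        prior = fit_gamma_prior(draws)
        m, v = draws.mean(), draws.var()
        mom = (m * m / v, m / v)
        ll_fit = stats.gamma.logpdf(draws, prior.a0, scale=1 / prior.b0).sum()
        ll_mom = stats.gamma.logpdf(draws, mom[0], scale=1 / (mom[1])).sum()
        assert ll_fit >= ll_mom - 1e-8

    def test_zeros_excluded_and_reported(self, rng):
        draws = np.concatenate([rng.gamma(3, 0.5, 200), np.zeros(7)])
        prior = fit_gamma_prior(draws)
        assert prior.n_zero_excluded == 7


class TestLikelihoodScore:
    def test_closed_form_single_bin(self):
        # Poisson(0 | 1) = e^-1
        assert log_likelihood_score(np.array([0]), np.array([1.0]), 1.0) == -1.0

    def test_score_maximized_at_ml_alpha(self, rng):
        x = rng.uniform(0.2, 4.0, 8)
        y = rng.poisson(1.5 * x)
        ahat = ml_alpha(y, x)
        best = log_likelihood_score(y, x, ahat)
        for a in [0.5 * ahat, 0.9 * ahat, 1.1 * ahat, 2 * ahat]:
            assert log_likelihood_score(y, x, a) <= best + 1e-12

    def test_matches_pmf_summation_oracle(self, rng):
        for _ in range(20):
            d = int(rng.integers(1, 12))
            x = rng.uniform(0.1, 6.0, d)
            y = rng.poisson(2.0 * x)
            a = float(rng.uniform(0.2, 4.0))
            oracle = stats.poisson.logpmf(y, a * x).sum()
            assert abs(log_likelihood_score(y, x, a) - oracle) < 1e-10

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood_score(np.array([-1]), np.array([1.0]), 1.0)

    def test_concatenation_factorizes(self, rng):
        x1, x2 = rng.uniform(0.5, 3, 4), rng.uniform(0.5, 3, 6)
        y1, y2 = rng.poisson(x1), rng.poisson(x2)
        a = 1.3
        whole = log_likelihood_score(
            np.concatenate([y1, y2]), np.concatenate([x1, x2]), a
        )
        parts = log_likelihood_score(y1, x1, a) + log_likelihood_score(y2, x2, a)
        assert abs(whole - parts) < 1e-10


class TestPosteriorPredictive:
    def test_all_zero_counts_reduce_analytically(self):
        x = np.array([1.0, 2.0, 0.5])
        prior = GammaPrior(2.0, 3.0)
        expected = 2.0 * (np.log(3.0) - np.log(3.0 + x.sum()))
        got = log_posterior_predictive(np.zeros(3), x, prior)
        assert abs(got - expected) < 1e-12

    def test_d1_equals_negative_binomial(self, rng):
        # single bin: the marginal is exactly NB(a0, p = b0/(b0+x))
        for _ in range(20):
            a0, b0 = rng.uniform(0.5, 8), rng.uniform(0.5, 8)
            x = float(rng.uniform(0.1, 10))
            y = int(rng.integers(0, 30))
            got = log_posterior_predictive(
                np.array([y]), np.array([x]), GammaPrior(a0, b0)
            )
            oracle = stats.nbinom.logpmf(y, a0, b0 / (b0 + x))
            assert abs(got - oracle) < 1e-10

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(10):
            d = int(rng.integers(2, 8))
            x = rng.uniform(0.1, 5.0, d)
            a0, b0 = float(rng.uniform(1, 6)), float(rng.uniform(0.5, 4))
            alpha = rng.gamma(a0, 1 / b0)
            y = rng.poisson(alpha * x)
            got = log_posterior_predictive(y, x, GammaPrior(a0, b0))
            oracle = quadrature_log_pp(y, x, a0, b0)
            assert abs(got - oracle) < 1e-6

    def test_permutation_invariance(self, rng):
        x = rng.uniform(0.2, 4, 10)
        y = rng.poisson(2 * x).astype(float)
        prior = GammaPrior(3.0, 2.0)
        perm = rng.permutation(10)
        a = log_posterior_predictive(y, x, prior)
        b = log_posterior_predictive(y[perm], x[perm], prior)
        assert abs(a - b) < 1e-10

    def test_concentrated_prior_limit_is_ml_score(self, rng):
        # a0, b0 -> inf with a0/b0 = alpha* recovers the plain likelihood
        x = rng.uniform(0.5, 3, 6)
        astar = 1.7
        y = rng.poisson(astar * x)
        big = 1e6
        bayes = log_posterior_predictive(
            y, x, GammaPrior(big * astar, big)
        )
        ml = log_likelihood_score(y, x, astar)
        assert abs(bayes - ml) < 1e-3


class TestClassModelSet:
    @pytest.fixture
    def fitted(self, rng):
        cov = {}
        labels = np.repeat(list(CLASSES), [30, 30, 60])
        for feat in ("h3k4me1", "dnase"):
            blocks = []
            for base in (4.0, 2.0, 0.5):
                x = base * (1 + np.sin(np.linspace(0, 3, 20)) ** 2)
                blocks.append(rng.poisson(x, size=(30 if base != 0.5 else 60, 20)))
            cov[feat] = np.vstack(blocks)
        return cov, labels, ClassModelSet.fit(cov, labels)

    def test_score_matrix_shape_and_column_order(self, fitted):
        cov, labels, ms = fitted
        X = ms.score_matrix(cov, "bayes")
        assert X.shape == (120, 6)
        assert np.isfinite(X).all()

    def test_bayes_columns_equal_per_sample_calls(self, fitted):
        cov, labels, ms = fitted
        X = ms.score_matrix(cov, "bayes")
        feat = ms.features[1]
        m = ms.models[feat]["prom"]
        col = 3 * 1 + 1  # feature 1, class prom
        for i in (0, 17, 119):
            expected = log_posterior_predictive(
                cov[feat][i].astype(float), m.x, m.prior
            )
            assert abs(X[i, col] - expected) < 1e-10

    def test_ml_mode_self_class_scores_highest_on_pattern(self, fitted):
        cov, labels, ms = fitted
        feat = ms.features[0]
        # a sample exactly equal to the enhancer aggregate pattern
        probe = {f: np.round(ms.models[f]["enh"].x)[None, :] for f in ms.features}
        X = ms.score_matrix(probe, "ml")
        triplet = X[0, :3]
        assert np.argmax(triplet) == 0

    def test_ml_all_zero_sample_is_finite(self, fitted):
        cov, labels, ms = fitted
        probe = {f: np.zeros((1, 20)) for f in ms.features}
        X = ms.score_matrix(probe, "ml")
        assert np.isfinite(X).all()
        np.testing.assert_allclose(X[0], 0.0)

    def test_serialization_roundtrip(self, fitted, tmp_path):
        cov, labels, ms = fitted
        path = tmp_path / "models.json"
        ms.save(path)
        again = ClassModelSet.load(path)
        np.testing.assert_allclose(
            ms.score_matrix(cov, "bayes"), again.score_matrix(cov, "bayes")
        )
        # the model file is plain JSON, inspectable without the package
        payload = json.loads(path.read_text())
        assert payload["d"] == 20 and set(payload["features"]) == set(ms.features)

    def test_mismatched_bins_rejected(self, fitted):
        cov, labels, ms = fitted
        with pytest.raises(ValueError, match="bins"):
            ms.score_matrix({f: np.zeros((2, 7)) for f in ms.features})

    def test_build_feature_matrix_wrapper(self, fitted):
        cov, labels, ms = fitted
        np.testing.assert_array_equal(
            build_feature_matrix(cov, ms, "ml"), ms.score_matrix(cov, "ml")
        )


class TestZeroBinFloor:
    def test_zero_pattern_bins_floored_no_minus_inf(self, rng):
        # class whose aggregate has an all-zero bin, scored on a sample with
        # a count there: the floor keeps the score finite
        Y = np.zeros((25, 10), dtype=int)
        Y[:, :5] = rng.poisson(3.0, size=(25, 5))
        m = ClassModel.fit(Y, feature="f", class_id="rand")
        assert m.epsilon == 1.0 / (25 * 10)
        assert (m.x[5:] == m.epsilon).all()
        probe = np.zeros((1, 10))
        probe[0, 7] = 4
        assert np.isfinite(m.bayes_scores(probe)).all()
        assert np.isfinite(m.ml_scores(probe)).all()
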