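"""Kernel correctness against independent numerical marginalization oracles.

The conditional phenotype probabilities must equal brute-force integration
of the probit-approximated phenotype model over the normal law of the
unobserved omics layer(s); the Gaussian product-integral identity must
match adaptive quadrature of its left-hand side.
"""

import numpy as np
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy import integrate
from scipy.stats import norm

from triomics import (APPROX_BETA, cond_prob_missing_E, cond_prob_missing_EM,
                      cond_prob_missing_M, lemma1_integral,
                      marginal_density_E_given_G, sigmoid,
                      sigmoid_probit_approx)
from triomics.kernels import log_sigmoid

from conftest import draw_params


def _gh_nodes(n=80):
    z, w = hermgauss(n)
    return z * np.sqrt(2.0), w / np.sqrt(np.pi)  # for N(0,1) expectations


class TestSigmoid:
    def test_symmetry_and_midpoint(self):
        assert sigmoid(0.0) == 0.5
        v = np.linspace(-30, 30, 41)
        np.testing.assert_allclose(sigmoid(v) + sigmoid(-v), 1.0, atol=1e-12)

    def test_direct_value(self):
        # intercept-only linear predictor beta0 + 0.3
        assert sigmoid(1.3) == pytest.approx(1.0 / (1.0 + np.exp(-1.3)), abs=1e-14)

    def test_extreme_arguments_saturate(self):
        assert sigmoid(700.0) == pytest.approx(1.0)
        assert sigmoid(-700.0) == pytest.approx(0.0, abs=1e-300)
        assert np.isfinite(log_sigmoid(-700.0))

    def test_log_sigmoid_matches(self):
        v = np.linspace(-20, 20, 31)
        np.testing.assert_allclose(log_sigmoid(v), np.log(sigmoid(v)), atol=1e-12)


class TestProbitApproximation:
    def test_midpoint_and_limit(self):
        assert sigmoid_probit_approx(0.0) == 0.5
        assert sigmoid_probit_approx(50.0) == pytest.approx(1.0)

    def test_sup_norm_on_grid(self):
        # with the variance-matching scale pi/sqrt(3) the worst-case error
        # over a dense grid is 0.02266 (attained near |v| ~ 1.24)
        v = np.linspace(-10, 10, 4001)
        err = np.abs(sigmoid(v) - sigmoid_probit_approx(v))
        assert err.max() == pytest.approx(0.022662801, abs=1e-6)
        assert err.max() < 0.025

    def test_scale_constant(self):
        assert APPROX_BETA == pytest.approx(np.pi / np.sqrt(3.0), rel=1e-15)


class TestLemma1:
    def test_reduces_to_phi_at_zero(self):
        # a=1, b=c=d=0: integral of phi(x) * phi(0) = phi(0) = 1/sqrt(2 pi)
        val = lemma1_integral(1.0, 0.0, 0.0, 0.0, 1.0, 1.0)
        assert val == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("args", [
        (2.0, 1.0, 0.5, 1.5, 1.0, 2.0),
        (1.5, -0.7, 2.0, 0.9, 0.6, 1.3),
        (0.0, 1.0, 0.3, 1.1, 2.0, 0.8),   # a = 0 but d != 0
    ])
    def test_matches_quadrature(self, args):
        a, b, c, d, s1, s2 = args
        f = lambda x: norm.pdf((a * x - b) / s1) * norm.pdf((c - d * x) / s2)
        expected, err = integrate.quad(f, -np.inf, np.inf, epsabs=1e-12)
        assert lemma1_integral(*args) == pytest.approx(expected, abs=1e-8)

    def test_random_admissible_parameters(self, make_rng):
        rng = make_rng(5)
        for _ in range(25):
            a, b, c, d = rng.uniform(-2, 2, size=4)
            if abs(a) < 0.05 and abs(d) < 0.05:
                a = 1.0
            s1, s2 = rng.uniform(0.3, 2.0, size=2)
            f = lambda x: norm.pdf((a * x - b) / s1) * norm.pdf((c - d * x) / s2)
            expected, _ = integrate.quad(f, -np.inf, np.inf, epsabs=1e-12)
            assert lemma1_integral(a, b, c, d, s1, s2) == pytest.approx(
                expected, abs=1e-8)

    def test_swapped_configuration(self):
        # swapping (a, b, sigma1) with (d, c, sigma2) is still admissible
        args = (1.5, 0.5, 1.0, 2.0, 1.0, 2.0)
        swapped = (args[3], args[2], args[1], args[0], args[5], args[4])
        f = lambda x: norm.pdf((swapped[0] * x - swapped[1]) / swapped[4]) \
            * norm.pdf((swapped[2] - swapped[3] * x) / swapped[5])
        expected, _ = integrate.quad(f, -np.inf, np.inf, epsabs=1e-12)
        assert lemma1_integral(*swapped) == pytest.approx(expected, abs=1e-8)

    def test_degenerate_integrand_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lemma1_integral(0.0, 1.0, 1.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            lemma1_integral(1.0, 0.0, 0.0, 1.0, -1.0, 1.0)


def _probit_phenotype(y, x, g, m, e, p):
    lp = (p.beta0 + np.dot(p.beta_x, x) + p.beta_g * g + p.beta_m * m
          + p.beta_e * e)
    return sigmoid_probit_approx(y * lp)


class TestConditionalProbabilities:
    """Each closed form equals numerical marginalization of the
    probit-approximated complete model (>= 100 random configurations)."""

    def test_missing_E_against_marginalization(self, make_rng):
        rng = make_rng(21)
        z, w = _gh_nodes()
        for _ in range(100):
            p = draw_params(rng)
            x = rng.normal(size=2)
            g = float(rng.integers(0, 3))
            m = float(rng.normal())
            mu0 = p.gamma0 + p.gamma_g * g + p.gamma_m * m
            for y in (-1.0, 1.0):
                e_nodes = mu0 + np.sqrt(p.sigma2_sq) * z
                oracle = float(w @ _probit_phenotype(y, x, g, m, e_nodes, p))
                assert cond_prob_missing_E(y, x, g, m, p) == pytest.approx(
                    oracle, abs=1e-6)

    def test_missing_E_against_scipy_quad(self, make_rng):
        # independent second oracle on a handful of configurations
        rng = make_rng(22)
        for _ in range(5):
            p = draw_params(rng)
            x = rng.normal(size=2)
            g, m = 1.0, float(rng.normal())
            mu0 = p.gamma0 + p.gamma_g * g + p.gamma_m * m
            f = lambda e: _probit_phenotype(1.0, x, g, m, e, p) \
                * norm.pdf(e, mu0, np.sqrt(p.sigma2_sq))
            oracle, _ = integrate.quad(f, -np.inf, np.inf, epsabs=1e-10)
            assert cond_prob_missing_E(1.0, x, g, m, p) == pytest.approx(
                oracle, abs=1e-6)

    def test_missing_M_against_marginalization(self, make_rng):
        rng = make_rng(23)
        z, w = _gh_nodes()
        for _ in range(100):
            p = draw_params(rng)
            x = rng.normal(size=2)
            g = float(rng.integers(0, 3))
            e = float(rng.normal())
            # conditional law of M given (E, G) implied by the two layers
            A = p.alpha0 + p.alpha_g * g
            Gam = p.gamma0 + p.gamma_g * g
            V = p.sigma2_sq + p.gamma_m**2 * p.sigma1_sq
            mu_m = A + p.gamma_m * p.sigma1_sq * (e - Gam - p.gamma_m * A) / V
            var_m = p.sigma1_sq * p.sigma2_sq / V
            for y in (-1.0, 1.0):
                m_nodes = mu_m + np.sqrt(var_m) * z
                oracle = float(w @ _probit_phenotype(y, x, g, m_nodes, e, p))
                assert cond_prob_missing_M(y, x, g, e, p) == pytest.approx(
                    oracle, abs=1e-6)

    def test_missing_M_reduces_when_beta_m_zero(self, make_rng):
        rng = make_rng(24)
        p = draw_params(rng)
        p = type(p)(**{**{f: getattr(p, f) for f in (
            "beta0", "beta_x", "beta_g", "beta_m", "beta_e", "alpha0",
            "alpha_g", "gamma0", "gamma_g", "gamma_m", "sigma1_sq",
            "sigma2_sq", "p")}, "beta_m": 0.0})
        x, g, e = rng.normal(size=2), 1.0, 0.4
        lp = (p.beta0 + p.beta_x @ x + p.beta_g * g + p.beta_e * e)
        assert cond_prob_missing_M(1.0, x, g, e, p) == pytest.approx(
            sigmoid_probit_approx(lp), abs=1e-12)

    def test_missing_EM_against_2d_marginalization(self, make_rng):
        rng = make_rng(25)
        z, w = _gh_nodes(60)
        Z1, Z2 = np.meshgrid(z, z)
        W = np.outer(w, w)
        for _ in range(100):
            p = draw_params(rng)
            x = rng.normal(size=2)
            g = float(rng.integers(0, 3))
            M = p.alpha0 + p.alpha_g * g + np.sqrt(p.sigma1_sq) * Z1
            E = (p.gamma0 + p.gamma_g * g + p.gamma_m * M
                 + np.sqrt(p.sigma2_sq) * Z2)
            for y in (-1.0, 1.0):
                oracle = float(np.sum(W * _probit_phenotype(y, x, g, M, E, p)))
                assert cond_prob_missing_EM(y, x, g, p) == pytest.approx(
                    oracle, abs=1e-5)

    def test_missing_EM_degenerate_variance_limit(self, make_rng):
        rng = make_rng(26)
        base = draw_params(rng)
        kw = {f: getattr(base, f) for f in (
            "beta0", "beta_x", "beta_g", "beta_m", "beta_e", "alpha0",
            "alpha_g", "gamma0", "gamma_g", "gamma_m", "sigma1_sq",
            "sigma2_sq", "p")}
        kw["sigma1_sq"] = kw["sigma2_sq"] = 1e-10
        p = type(base)(**kw)
        x, g = np.zeros(2), 1.0
        m_plug = p.alpha0 + p.alpha_g * g
        e_plug = p.gamma0 + p.gamma_g * g + p.gamma_m * m_plug
        lp = (p.beta0 + p.beta_g * g + p.beta_m * m_plug + p.beta_e * e_plug)
        assert cond_prob_missing_EM(1.0, x, g, p) == pytest.approx(
            sigmoid_probit_approx(lp), abs=1e-4)

    def test_probabilities_sum_to_one_and_lie_inside_unit_interval(self, make_rng):
        rng = make_rng(27)
        for _ in range(100):
            p = draw_params(rng)
            x = rng.normal(size=2)
            g = float(rng.integers(0, 3))
            m, e = rng.normal(size=2)
            pairs = [
                (cond_prob_missing_E(1, x, g, m, p), cond_prob_missing_E(-1, x, g, m, p)),
                (cond_prob_missing_M(1, x, g, e, p), cond_prob_missing_M(-1, x, g, e, p)),
                (cond_prob_missing_EM(1, x, g, p), cond_prob_missing_EM(-1, x, g, p)),
            ]
            for a, b in pairs:
                assert 0.0 < a < 1.0 and 0.0 < b < 1.0
                assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_all_beta_zero_gives_half(self):
        from triomics import ModelParams
        p = ModelParams.null(n_covariates=2, alpha0=1.0, gamma_m=0.7)
        x = np.array([3.0, 1.0])
        assert cond_prob_missing_E(1, x, 2.0, 0.3, p) == pytest.approx(0.5)
        assert cond_prob_missing_M(-1, x, 1.0, 0.1, p) == pytest.approx(0.5)
        assert cond_prob_missing_EM(1, x, 0.0, p) == pytest.approx(0.5)


class TestMarginalExpressionDensity:
    def test_reduction_when_gamma_m_zero(self, make_rng):
        rng = make_rng(31)
        base = draw_params(rng)
        kw = {f: getattr(base, f) for f in (
            "beta0", "beta_x", "beta_g", "beta_m", "beta_e", "alpha0",
            "alpha_g", "gamma0", "gamma_g", "gamma_m", "sigma1_sq",
            "sigma2_sq", "p")}
        kw["gamma_m"] = 0.0
        p = type(base)(**kw)
        e, g = 0.7, 1.0
        expected = norm.pdf(e, p.gamma0 + p.gamma_g * g, np.sqrt(p.sigma2_sq))
        assert marginal_density_E_given_G(e, g, p) == pytest.approx(expected,
                                                                    abs=1e-12)

    def test_normalization(self, make_rng):
        p = draw_params(make_rng(32))
        total, _ = integrate.quad(lambda e: marginal_density_E_given_G(e, 1.0, p),
                                  -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_numerical_convolution(self, make_rng):
        p = draw_params(make_rng(33))
        g = 2.0

        def f(e):
            inner = lambda m: norm.pdf(m, p.alpha0 + p.alpha_g * g,
                                       np.sqrt(p.sigma1_sq)) \
                * norm.pdf(e, p.gamma0 + p.gamma_g * g + p.gamma_m * m,
                           np.sqrt(p.sigma2_sq))
            val, _ = integrate.quad(inner, -np.inf, np.inf)
            return val

        for e in (-1.0, 0.5, 3.0):
            assert marginal_density_E_given_G(e, g, p) == pytest.approx(
                f(e), abs=1e-8)
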