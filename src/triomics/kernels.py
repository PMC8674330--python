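"""Closed-form probability kernels for the integrative trio model.

These are the mathematical primitives the missing-data likelihood is built
from: the logistic link, its normal-CDF (probit) approximation, the Gaussian
product-integral identity used to marginalize unobserved omics layers, and
the resulting conditional phenotype probabilities for each missingness
pattern.

Conventions
-----------
* Phenotype ``y`` is coded -1 (control) / +1 (case).
* All kernels are vectorized over their data arguments.
* ``cond_prob_*`` return probabilities on the natural scale; the paired
  ``log_cond_prob_*`` variants are the numerically safe forms used inside
  likelihoods.

The conditional probabilities marginalize the probit-approximated phenotype
model over the normal law of the unobserved layer(s), which is available in
closed form: integrating ``Phi((a + b*t)/k)`` against ``t ~ N(mu, s2)``
yields ``Phi((a + b*mu) / sqrt(k^2 + b^2 s2))``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr

from .params import APPROX_BETA, ModelParams

__all__ = [
    "sigmoid",
    "log_sigmoid",
    "sigmoid_probit_approx",
    "lemma1_integral",
    "cond_prob_missing_E",
    "cond_prob_missing_M",
    "cond_prob_missing_EM",
    "marginal_density_E_given_G",
    "log_marginal_density_E_given_G",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def sigmoid(v):
    """Logistic function 1 / (1 + exp(-v)), stable for large |v|."""
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out if out.ndim else float(out)


def log_sigmoid(v):
    """log(sigmoid(v)) without underflow: -log1p(exp(-v)) for v >= 0."""
    v = np.asarray(v, dtype=float)
    out = np.where(v >= 0, -np.log1p(np.exp(-np.abs(v))),
                   v - np.log1p(np.exp(-np.abs(v))))
    return out if out.ndim else float(out)


def sigmoid_probit_approx(v):
    """Normal-CDF approximation of the logistic: Phi(v / (pi/sqrt(3)))."""
    v = np.asarray(v, dtype=float)
    out = ndtr(v / APPROX_BETA)
    return out if out.ndim else float(out)


def lemma1_integral(a, b, c, d, sigma1, sigma2):
    """Integral of ``phi((a x - b)/sigma1) * phi((c - d x)/sigma2)`` over x.

    ``phi`` is the standard normal density.  The closed form is

        phi((a c - b d) / sqrt(a^2 sigma2^2 + d^2 sigma1^2))
        / sqrt(a^2 / sigma1^2 + d^2 / sigma2^2)

    which requires ``a`` and ``d`` not both zero (otherwise the integrand is
    constant in x and the integral diverges).
    """
    a, b, c, d = (np.asarray(t, dtype=float) for t in (a, b, c, d))
    sigma1 = np.asarray(sigma1, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma1 <= 0) or np.any(sigma2 <= 0):
        raise ValueError("sigma1 and sigma2 must be strictly positive")
    if np.any((a == 0) & (d == 0)):
        raise ValueError("degenerate integrand: a and d are both zero")
    denom = np.sqrt(a**2 * sigma2**2 + d**2 * sigma1**2)
    z = (a * c - b * d) / denom
    dens = np.exp(-0.5 * z**2 - 0.5 * _LOG_2PI)
    out = dens / np.sqrt(a**2 / sigma1**2 + d**2 / sigma2**2)
    return out if out.ndim else float(out)


def _xdot(x, params: ModelParams):
    """beta_x' x for x of shape (J,) or (n, J) (or scalar when J == 1)."""
    x = np.asarray(x, dtype=float)
    if x.ndim <= 1 and params.n_covariates == 1:
        return x * params.beta_x[0]
    if x.ndim == 1:
        return x @ params.beta_x
    return x @ params.beta_x


def probit_score_missing_E(x, g, m, params: ModelParams):
    """Phi-scale score u with P(Y=+1 | X, G, M) = Phi(u) when E is missing."""
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    mu0 = params.gamma0 + params.gamma_g * g + params.gamma_m * m
    num = (params.beta0 + _xdot(x, params) + params.beta_g * g
           + params.beta_m * m + params.beta_e * mu0)
    den = np.sqrt(APPROX_BETA**2 + params.beta_e**2 * params.sigma2_sq)
    return num / den


def probit_score_missing_M(x, g, e, params: ModelParams):
    """Phi-scale score with methylation marginalized given (E, G)."""
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    s1, s2 = params.sigma1_sq, params.sigma2_sq
    v = s2 + params.gamma_m**2 * s1
    mu_m = ((params.alpha0 + params.alpha_g * g) * s2
            + params.gamma_m * (e - params.gamma0 - params.gamma_g * g) * s1) / v
    num = (params.beta0 + _xdot(x, params) + params.beta_g * g
           + params.beta_e * e + params.beta_m * mu_m)
    den = np.sqrt(APPROX_BETA**2 + params.beta_m**2 * s1 * s2 / v)
    return num / den


def probit_score_missing_EM(x, g, params: ModelParams):
    """Phi-scale score with both omics layers marginalized given G."""
    g = np.asarray(g, dtype=float)
    a_mean = params.alpha0 + params.alpha_g * g
    combo = params.beta_e * params.gamma_m + params.beta_m
    num = (params.beta0 + _xdot(x, params) + params.beta_g * g
           + params.beta_e * (params.gamma0 + params.gamma_g * g)
           + a_mean * combo)
    den = np.sqrt(APPROX_BETA**2 + params.beta_e**2 * params.sigma2_sq
                  + combo**2 * params.sigma1_sq)
    return num / den


def cond_prob_missing_E(y, x, g, m, params: ModelParams):
    """P(Y = y | covariates, genotype, methylation) when expression is missing."""
    u = probit_score_missing_E(x, g, m, params)
    out = ndtr(np.asarray(y, dtype=float) * u)
    return out if np.ndim(out) else float(out)


def cond_prob_missing_M(y, x, g, e, params: ModelParams):
    """P(Y = y | covariates, genotype, expression) when methylation is missing."""
    u = probit_score_missing_M(x, g, e, params)
    out = ndtr(np.asarray(y, dtype=float) * u)
    return out if np.ndim(out) else float(out)


def cond_prob_missing_EM(y, x, g, params: ModelParams):
    """P(Y = y | covariates, genotype) when both omics layers are missing."""
    u = probit_score_missing_EM(x, g, params)
    out = ndtr(np.asarray(y, dtype=float) * u)
    return out if np.ndim(out) else float(out)


def log_cond_prob_missing_E(y, x, g, m, params: ModelParams):
    return log_ndtr(np.asarray(y, dtype=float)
                    * probit_score_missing_E(x, g, m, params))


def log_cond_prob_missing_M(y, x, g, e, params: ModelParams):
    return log_ndtr(np.asarray(y, dtype=float)
                    * probit_score_missing_M(x, g, e, params))


def log_cond_prob_missing_EM(y, x, g, params: ModelParams):
    return log_ndtr(np.asarray(y, dtype=float)
                    * probit_score_missing_EM(x, g, params))


def log_marginal_density_E_given_G(e, g, params: ModelParams):
    """Log density of expression given genotype only (methylation integrated out).

    E | G is normal with mean gamma0 + gamma_g G + gamma_m (alpha0 + alpha_g G)
    and variance sigma2^2 + gamma_m^2 sigma1^2.
    """
    e = np.asarray(e, dtype=float)
    g = np.asarray(g, dtype=float)
    mean = (params.gamma0 + params.gamma_g * g
            + params.gamma_m * (params.alpha0 + params.alpha_g * g))
    var = params.sigma2_sq + params.gamma_m**2 * params.sigma1_sq
    return -0.5 * (_LOG_2PI + np.log(var) + (e - mean) ** 2 / var)


def marginal_density_E_given_G(e, g, params: ModelParams):
    out = np.exp(log_marginal_density_E_given_G(e, g, params))
    return out if np.ndim(out) else float(out)
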