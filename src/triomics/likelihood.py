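"""Observed-data log-likelihood and maximum-likelihood fitting.

The joint likelihood factorizes per individual according to the missingness
pattern:

* both omics observed: exact logistic phenotype probability times the normal
  densities of E | M, G and M | G;
* expression missing: the probit-marginalized phenotype probability
  (``cond_prob_missing_E``) times the normal density of M | G;
* methylation missing: ``cond_prob_missing_M`` times the marginal normal
  density of E | G;
* both missing: ``cond_prob_missing_EM`` alone;

and every individual contributes the Binomial(2, p) genotype mass.  The
genotype factor is separable from everything else, so the minor-allele
frequency is profiled out at its closed-form MLE (half the sample allele
count) and the remaining parameters are maximized numerically.

For a fully observed dataset the likelihood factorizes further into a
logistic regression (phenotype layer), two ordinary least-squares layers
(omics regressions) and the genotype mass, whose separate maximizers are the
joint MLE; fitting exploits this.  Otherwise the conditional phenotype
kernels couple all layers and the joint objective is maximized with
L-BFGS-B using the analytic gradient implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr

from . import kernels
from .data import TrioDataset
from .params import APPROX_BETA, TESTABLE_EFFECTS, ModelParams

__all__ = ["FitResult", "loglik", "fit_mle"]

_LOG_2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-6
_VAR_CEIL = 1e6
_COEF_BOUND = 50.0
_PGTOL = 1e-8
_FTOL = 1e-11
_RESTART_SEED = 987654321  # fixed secondary seed for the single jittered restart


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params_hat: ModelParams
    loglik: float
    converged: bool
    n_iter: int
    constrained: frozenset = field(default_factory=frozenset)
    gradient_norm: float = np.nan
    n_restarts: int = 0


# ---------------------------------------------------------------------------
# public log-likelihood (assembled from the closed-form kernels)
# ---------------------------------------------------------------------------

def _log_binom2(g: np.ndarray, p: float) -> np.ndarray:
    coef = np.where(g == 1.0, np.log(2.0), 0.0)
    return coef + g * np.log(p) + (2.0 - g) * np.log1p(-p)


def _log_normal(resid: np.ndarray, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var) + resid**2 / var)


def loglik(data: TrioDataset, params: ModelParams) -> float:
    """Observed-data log-likelihood of the general missingness scheme.

    Reduces exactly to the complete-data, expression-missing-only or
    methylation-missing-only forms when the corresponding subsets are empty.
    """
    if params.n_covariates != data.n_covariates:
        raise ValueError("covariate dimension of params does not match data")
    total = float(np.sum(_log_binom2(data.G, params.p)))

    i1 = data.idx_full
    if i1.size:
        eta = (params.beta0 + data.X[i1] @ params.beta_x
               + params.beta_g * data.G[i1] + params.beta_m * data.M[i1]
               + params.beta_e * data.E[i1])
        total += float(np.sum(kernels.log_sigmoid(data.y[i1] * eta)))
        r2 = (data.E[i1] - params.gamma0 - params.gamma_g * data.G[i1]
              - params.gamma_m * data.M[i1])
        total += float(np.sum(_log_normal(r2, params.sigma2_sq)))

    im = np.concatenate([i1, data.idx_missing_e])  # rows with M observed
    if im.size:
        r1 = data.M[im] - params.alpha0 - params.alpha_g * data.G[im]
        total += float(np.sum(_log_normal(r1, params.sigma1_sq)))

    i2 = data.idx_missing_e
    if i2.size:
        total += float(np.sum(kernels.log_cond_prob_missing_E(
            data.y[i2], data.X[i2], data.G[i2], data.M[i2], params)))

    i3 = data.idx_missing_m
    if i3.size:
        total += float(np.sum(kernels.log_cond_prob_missing_M(
            data.y[i3], data.X[i3], data.G[i3], data.E[i3], params)))
        total += float(np.sum(kernels.log_marginal_density_E_given_G(
            data.E[i3], data.G[i3], params)))

    i4 = data.idx_missing_em
    if i4.size:
        total += float(np.sum(kernels.log_cond_prob_missing_EM(
            data.y[i4], data.X[i4], data.G[i4], params)))
    return total


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

class _Layout:
    """Mapping between the free optimization vector and named parameters.

    Full order: beta0, beta_x (J), beta_g, beta_m, beta_e, alpha0, alpha_g,
    gamma0, gamma_g, gamma_m, sigma1_sq, sigma2_sq.  The minor-allele
    frequency is profiled out, and constrained phenotype effects are removed
    from the free vector and pinned at zero.
    """

    def __init__(self, n_cov: int, constrained: frozenset):
        self.n_cov = n_cov
        names = (["beta0"] + [f"beta_x{j}" for j in range(n_cov)]
                 + ["beta_g", "beta_m", "beta_e", "alpha0", "alpha_g",
                    "gamma0", "gamma_g", "gamma_m", "sigma1_sq", "sigma2_sq"])
        self.full_names = names
        self.free_idx = np.array(
            [k for k, nm in enumerate(names) if nm not in constrained])
        self.n_full = len(names)

    def expand(self, theta_free: np.ndarray) -> np.ndarray:
        full = np.zeros(self.n_full)
        full[self.free_idx] = theta_free
        return full

    def to_params(self, theta_free: np.ndarray, p: float) -> ModelParams:
        f = self.expand(theta_free)
        J = self.n_cov
        return ModelParams(
            beta0=f[0], beta_x=f[1:1 + J], beta_g=f[1 + J], beta_m=f[2 + J],
            beta_e=f[3 + J], alpha0=f[4 + J], alpha_g=f[5 + J],
            gamma0=f[6 + J], gamma_g=f[7 + J], gamma_m=f[8 + J],
            sigma1_sq=max(f[9 + J], _VAR_FLOOR),
            sigma2_sq=max(f[10 + J], _VAR_FLOOR), p=p)

    def from_params(self, params: ModelParams) -> np.ndarray:
        full = np.concatenate([
            [params.beta0], params.beta_x,
            [params.beta_g, params.beta_m, params.beta_e, params.alpha0,
             params.alpha_g, params.gamma0, params.gamma_g, params.gamma_m,
             params.sigma1_sq, params.sigma2_sq]])
        return full[self.free_idx]

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for k in self.free_idx:
            nm = self.full_names[k]
            if nm.startswith("sigma"):
                out.append((_VAR_FLOOR, _VAR_CEIL))
            else:
                out.append((-_COEF_BOUND, _COEF_BOUND))
        return out


# ---------------------------------------------------------------------------
# fast objective + analytic gradient (genotype mass excluded: constant in
# everything but p, which is profiled out)
# ---------------------------------------------------------------------------

class _Workspace:
    def __init__(self, data: TrioDataset):
        self.J = data.n_covariates
        for tag, idx in (("f", data.idx_full), ("e", data.idx_missing_e),
                         ("m", data.idx_missing_m), ("b", data.idx_missing_em)):
            setattr(self, "y" + tag, data.y[idx])
            setattr(self, "X" + tag, data.X[idx])
            setattr(self, "g" + tag, data.G[idx])
        self.mf, self.ef = data.M[data.idx_full], data.E[data.idx_full]
        self.me = data.M[data.idx_missing_e]
        self.em = data.E[data.idx_missing_m]


def _phi_over_Phi(u: np.ndarray) -> np.ndarray:
    # exp(log phi(u) - log Phi(u)); stable in the deep lower tail
    return np.exp(-0.5 * u**2 - 0.5 * _LOG_2PI - log_ndtr(u))


def _nll_grad(theta_free: np.ndarray, ws: _Workspace, lay: _Layout):
    f = lay.expand(theta_free)
    J = lay.n_cov
    b0, bx = f[0], f[1:1 + J]
    bg, bm, be = f[1 + J], f[2 + J], f[3 + J]
    a0, ag = f[4 + J], f[5 + J]
    c0, cg, cm = f[6 + J], f[7 + J], f[8 + J]
    s1 = max(f[9 + J], _VAR_FLOOR)
    s2 = max(f[10 + J], _VAR_FLOOR)
    kappa2 = APPROX_BETA**2

    ll = 0.0
    grad = np.zeros(lay.n_full)
    gb0 = gbg = gbm = gbe = ga0 = gag = gc0 = gcg = gcm = gs1 = gs2 = 0.0
    gbx = np.zeros(J)

    # ---- fully observed rows: exact logistic + two gaussian layers
    y, X, g, m, e = ws.yf, ws.Xf, ws.gf, ws.mf, ws.ef
    if y.size:
        eta = b0 + X @ bx + bg * g + bm * m + be * e
        t = y * eta
        ll += float(np.sum(np.where(t >= 0, -np.log1p(np.exp(-np.abs(t))),
                                    t - np.log1p(np.exp(-np.abs(t))))))
        w1 = y / (1.0 + np.exp(np.clip(t, -500.0, 500.0)))  # y * (1 - sigmoid(t))
        gb0 += w1.sum(); gbx += X.T @ w1
        gbg += float(w1 @ g); gbm += float(w1 @ m); gbe += float(w1 @ e)
        r2 = e - c0 - cg * g - cm * m
        ll += float(np.sum(_log_normal(r2, s2)))
        gc0 += r2.sum() / s2; gcg += float(r2 @ g) / s2
        gcm += float(r2 @ m) / s2
        gs2 += float(np.sum(r2**2 / s2 - 1.0)) / (2.0 * s2)

    # ---- M | G layer for every row where methylation is observed
    for (yy, gg_, mm) in ((ws.yf, ws.gf, ws.mf), (ws.ye, ws.ge, ws.me)):
        if yy.size:
            r1 = mm - a0 - ag * gg_
            ll += float(np.sum(_log_normal(r1, s1)))
            ga0 += r1.sum() / s1; gag += float(r1 @ gg_) / s1
            gs1 += float(np.sum(r1**2 / s1 - 1.0)) / (2.0 * s1)

    # ---- expression-missing rows
    y, X, g, m = ws.ye, ws.Xe, ws.ge, ws.me
    if y.size:
        mu0 = c0 + cg * g + cm * m
        Dv = kappa2 + be**2 * s2
        D = np.sqrt(Dv)
        N = b0 + X @ bx + bg * g + bm * m + be * mu0
        u = y * N / D
        ll += float(np.sum(log_ndtr(u)))
        r = _phi_over_Phi(u)
        com = r * y / D
        gb0 += com.sum(); gbx += X.T @ com
        gbg += float(com @ g); gbm += float(com @ m)
        gbe += float(np.sum(r * (y * mu0 / D - u * be * s2 / Dv)))
        gc0 += be * com.sum(); gcg += be * float(com @ g)
        gcm += be * float(com @ m)
        gs2 += float(np.sum(r * (-u * be**2 / (2.0 * Dv))))

    # ---- methylation-missing rows
    y, X, g, e = ws.ym, ws.Xm, ws.gm, ws.em
    if y.size:
        A = a0 + ag * g
        Gam = c0 + cg * g
        V = s2 + cm**2 * s1
        mu_m = (A * s2 + cm * (e - Gam) * s1) / V
        Dv = kappa2 + bm**2 * s1 * s2 / V
        D = np.sqrt(Dv)
        N = b0 + X @ bx + bg * g + be * e + bm * mu_m
        u = y * N / D
        ll += float(np.sum(log_ndtr(u)))
        r = _phi_over_Phi(u)
        com = r * y / D
        gb0 += com.sum(); gbx += X.T @ com
        gbg += float(com @ g); gbe += float(com @ e)
        gbm += float(np.sum(r * (y * mu_m / D - u * bm * s1 * s2 / (V * Dv))))
        ga0 += bm * s2 / V * com.sum()
        gag += bm * s2 / V * float(com @ g)
        gc0 += -bm * cm * s1 / V * com.sum()
        gcg += -bm * cm * s1 / V * float(com @ g)
        dmu_dcm = ((e - Gam) * s1 - 2.0 * cm * s1 * mu_m) / V
        gcm += float(np.sum(r * (y * bm * dmu_dcm / D
                                 + u * bm**2 * s1**2 * s2 * cm / (V**2 * Dv))))
        dmu_ds1 = (cm * (e - Gam) - cm**2 * mu_m) / V
        gs1 += float(np.sum(r * (y * bm * dmu_ds1 / D
                                 - u * bm**2 * s2**2 / (2.0 * V**2 * Dv))))
        dmu_ds2 = (A - mu_m) / V
        gs2 += float(np.sum(r * (y * bm * dmu_ds2 / D
                                 - u * bm**2 * s1**2 * cm**2 / (2.0 * V**2 * Dv))))
        # marginal E | G density
        rE = e - Gam - cm * A
        ll += float(np.sum(_log_normal(rE, V)))
        gc0 += rE.sum() / V; gcg += float(rE @ g) / V
        ga0 += cm * rE.sum() / V; gag += cm * float(rE @ g) / V
        dV_term = np.sum(rE**2 / V - 1.0) / (2.0 * V)
        gcm += float(np.sum(rE * A)) / V + float(dV_term) * 2.0 * cm * s1
        gs1 += float(dV_term) * cm**2
        gs2 += float(dV_term)

    # ---- rows with both omics missing
    y, X, g = ws.yb, ws.Xb, ws.gb
    if y.size:
        A = a0 + ag * g
        Gam = c0 + cg * g
        cmb = be * cm + bm
        Dv = kappa2 + be**2 * s2 + cmb**2 * s1
        D = np.sqrt(Dv)
        N = b0 + X @ bx + bg * g + be * Gam + A * cmb
        u = y * N / D
        ll += float(np.sum(log_ndtr(u)))
        r = _phi_over_Phi(u)
        com = r * y / D
        gb0 += com.sum(); gbx += X.T @ com
        gbg += float(com @ g)
        gbe += float(np.sum(r * (y * (Gam + A * cm) / D
                                 - u * (be * s2 + cmb * cm * s1) / Dv)))
        gbm += float(np.sum(r * (y * A / D - u * cmb * s1 / Dv)))
        ga0 += cmb * com.sum(); gag += cmb * float(com @ g)
        gc0 += be * com.sum(); gcg += be * float(com @ g)
        gcm += float(np.sum(r * (y * be * A / D - u * cmb * be * s1 / Dv)))
        gs1 += float(np.sum(r * (-u * cmb**2 / (2.0 * Dv))))
        gs2 += float(np.sum(r * (-u * be**2 / (2.0 * Dv))))

    grad[0] = gb0; grad[1:1 + J] = gbx
    grad[1 + J], grad[2 + J], grad[3 + J] = gbg, gbm, gbe
    grad[4 + J], grad[5 + J] = ga0, gag
    grad[6 + J], grad[7 + J], grad[8 + J] = gc0, gcg, gcm
    grad[9 + J], grad[10 + J] = gs1, gs2
    return -ll, -grad[lay.free_idx]


# ---------------------------------------------------------------------------
# closed-form building blocks
# ---------------------------------------------------------------------------

def _ols(Z: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(Z, t, rcond=None)
    resid = t - Z @ coef
    var = float(resid @ resid) / t.size
    return coef, max(var, _VAR_FLOOR)


def _newton_logistic(Z: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                     tol: float = 1e-10, max_iter: int = 60):
    """Unpenalized (or lightly ridged) logistic MLE by Newton's method.

    y is coded -1/+1; returns (coef, loglik, converged, grad_norm, n_iter).
    """
    y01 = (y > 0).astype(float)
    coef = np.zeros(Z.shape[1])
    gnorm = np.inf
    for it in range(1, max_iter + 1):
        eta = np.clip(Z @ coef, -500, 500)
        pi = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (y01 - pi) - ridge * coef
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol:
            break
        W = pi * (1.0 - pi)
        H = (Z * W[:, None]).T @ Z + (ridge + 1e-10) * np.eye(Z.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps (quasi-separation guard)
        snorm = float(np.max(np.abs(step)))
        if snorm > 10.0:
            step *= 10.0 / snorm
        coef = coef + step
    t = y * (Z @ coef)
    ll = float(np.sum(np.where(t >= 0, -np.log1p(np.exp(-np.abs(t))),
                               t - np.log1p(np.exp(-np.abs(t))))))
    return coef, ll, gnorm < 1e-6, gnorm, it


def _profile_maf(data: TrioDataset) -> float:
    p_hat = float(np.mean(data.G)) / 2.0
    if p_hat <= 0.0 or p_hat >= 1.0:
        warnings.warn("all genotypes identical: minor-allele frequency "
                      "estimate is at the boundary", stacklevel=3)
    return float(np.clip(p_hat, _VAR_FLOOR, 1.0 - _VAR_FLOOR))


def _starting_values(data: TrioDataset, lay: _Layout) -> np.ndarray:
    """Deterministic near-basin starts from complete-case regressions."""
    J = data.n_covariates
    obs_m = data.observed_m
    full = data.idx_full
    f = np.zeros(lay.n_full)
    f[9 + J] = f[10 + J] = 1.0
    if obs_m.sum() >= 3:
        g = data.G[obs_m]
        (f[4 + J], f[5 + J]), f[9 + J] = _ols(
            np.c_[np.ones(int(obs_m.sum())), g], data.M[obs_m])
    if full.size >= 5:
        Z = np.c_[np.ones(full.size), data.G[full], data.M[full]]
        (f[6 + J], f[7 + J], f[8 + J]), f[10 + J] = _ols(Z, data.E[full])
        Zb = np.c_[np.ones(full.size), data.X[full], data.G[full],
                   data.M[full], data.E[full]]
        coef, *_ = _newton_logistic(Zb, data.y[full], ridge=1e-3, max_iter=25)
        f[0] = coef[0]; f[1:1 + J] = coef[1:1 + J]
        f[1 + J], f[2 + J], f[3 + J] = coef[1 + J], coef[2 + J], coef[3 + J]
    theta = f[lay.free_idx]
    lo_hi = np.array(lay.bounds())
    return np.clip(theta, lo_hi[:, 0], lo_hi[:, 1])


# ---------------------------------------------------------------------------
# the fitting driver
# ---------------------------------------------------------------------------

def _fit_complete(data: TrioDataset, constrained: frozenset,
                  p_hat: float) -> FitResult:
    """Factorized MLE for fully observed data (each block fit exactly)."""
    J = data.n_covariates
    a_coef, s1 = _ols(np.c_[np.ones(data.n), data.G], data.M)
    c_coef, s2 = _ols(np.c_[np.ones(data.n), data.G, data.M], data.E)
    cols = [np.ones((data.n, 1)), data.X]
    names = ["beta0"] + [f"__x{j}" for j in range(J)]
    for nm, arr in (("beta_g", data.G), ("beta_m", data.M), ("beta_e", data.E)):
        if nm not in constrained:
            cols.append(arr[:, None])
            names.append(nm)
    Z = np.hstack(cols)
    coef, _, conv, gnorm, n_iter = _newton_logistic(Z, data.y)
    beta_x = coef[1:1 + J]
    eff = {nm: 0.0 for nm in TESTABLE_EFFECTS}
    for k, nm in enumerate(names[1 + J:]):
        eff[nm] = float(coef[1 + J + k])
    params = ModelParams(
        beta0=float(coef[0]), beta_x=beta_x, beta_g=eff["beta_g"],
        beta_m=eff["beta_m"], beta_e=eff["beta_e"],
        alpha0=float(a_coef[0]), alpha_g=float(a_coef[1]),
        gamma0=float(c_coef[0]), gamma_g=float(c_coef[1]),
        gamma_m=float(c_coef[2]), sigma1_sq=s1, sigma2_sq=s2, p=p_hat)
    return FitResult(params_hat=params, loglik=loglik(data, params),
                     converged=bool(conv), n_iter=n_iter,
                     constrained=constrained, gradient_norm=gnorm)


def fit_mle(data: TrioDataset, constrained=(), start: ModelParams | None = None,
            maxiter: int = 500) -> FitResult:
    """Maximize the observed-data log-likelihood.

    Parameters named in ``constrained`` (any subset of ``beta_g``, ``beta_m``,
    ``beta_e``) are removed from the search space and fixed at zero, giving
    the null fits of the association tests.  Deterministic given ``data`` and
    ``start``.
    """
    constrained = frozenset(constrained)
    unknown = constrained - set(TESTABLE_EFFECTS)
    if unknown:
        raise ValueError(f"cannot constrain {sorted(unknown)}")
    p_hat = _profile_maf(data)
    if data.n < 10:
        warnings.warn("fewer than 10 individuals: estimates are unlikely to "
                      "be identifiable", stacklevel=2)
    if data.is_complete and start is None:
        res = _fit_complete(data, constrained, p_hat)
        if res.converged:
            return res

    lay = _Layout(data.n_covariates, constrained)
    ws = _Workspace(data)
    theta0 = (lay.from_params(start.constrain(constrained)) if start is not None
              else _starting_values(data, lay))
    bounds = lay.bounds()
    opts = dict(maxiter=maxiter, ftol=_FTOL, gtol=_PGTOL, maxcor=20)

    best = None
    n_restarts = 0
    for attempt in range(2):
        th = theta0
        if attempt == 1:
            n_restarts = 1
            rng = np.random.default_rng(_RESTART_SEED)
            th = theta0 + rng.normal(0.0, 0.1, size=theta0.shape)
            th = np.clip(th, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(_nll_grad, th, args=(ws, lay), method="L-BFGS-B",
                       jac=True, bounds=bounds, options=opts)
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break

    params = lay.to_params(best.x, p_hat)
    ll = -float(best.fun) + float(np.sum(_log_binom2(data.G, p_hat)))
    return FitResult(params_hat=params, loglik=ll, converged=bool(best.success),
                     n_iter=int(best.nit), constrained=constrained,
                     gradient_norm=float(np.max(np.abs(best.jac))),
                     n_restarts=n_restarts)
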