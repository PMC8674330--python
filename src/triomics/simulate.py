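"""Case-control trio simulator.

Generates synthetic (genotype, methylation, expression, phenotype) datasets
from the three-layer generative model, with a case-control design:

* control genotypes follow Hardy-Weinberg equilibrium at the configured
  minor-allele frequency; case genotypes follow the law implied by an
  additive genotype-relative-risk model and the disease prevalence;
* methylation and expression follow the two linear regression layers with
  independent normal errors; cases receive a mean shift (the disease effect
  on the molecular layers);
* two covariates emulate age ~ N(40, sd 6) and sex ~ Bernoulli(0.5).

Missingness is injected completely at random afterwards, blanking
expression and/or methylation for disjoint subsets balanced across the two
strata.

Under ``null_scenario`` the case and control strata share one generative
law (HWE genotypes, no shift), so the phenotype carries no information
about the trio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import TrioDataset
from .params import ModelParams

__all__ = ["SimConfig", "hwe_freqs", "genotype_freqs_case",
           "simulate_covariates", "simulate_omics", "simulate_dataset",
           "inject_missingness", "simulate_study_dataset"]


@dataclass
class SimConfig:
    """Every knob of the generative process.

    The defaults are the simulation study's operating point: MAF 0.2,
    genotype relative risk 1.2 at prevalence 0.1, omics coefficients
    (alpha0, alpha_g, gamma0, gamma_g, gamma_m) = (1.3, 2.4, 1.9, 0.6, 2.3)
    with unit error variances, a 0.3 case-control separation of the
    methylation/expression means, and phenotype-layer coefficients
    (beta0, beta_x, beta_g, beta_m, beta_e) = (1, 0.01, 0.1, 0.2, 0.3).
    """

    n_case: int = 200
    n_control: int = 200
    maf: float = 0.2
    rr: float = 1.2
    prevalence: float = 0.1
    alpha0: float = 1.3
    alpha_g: float = 2.4
    gamma0: float = 1.9
    gamma_g: float = 0.6
    gamma_m: float = 2.3
    sigma1_sq: float = 1.0
    sigma2_sq: float = 1.0
    case_shift: float = 0.3
    beta0: float = 1.0
    beta_x: Sequence[float] = (0.01, 0.01)
    beta_g: float = 0.1
    beta_m: float = 0.2
    beta_e: float = 0.3
    age_mean: float = 40.0
    age_sd: float = 6.0
    sex_prob: float = 0.5
    m_both: float = 0.0
    m_meth_only: float = 0.0
    m_expr_only: float = 0.0
    null_scenario: bool = False
    #: how the 0.3 case-control separation enters: "intercept" adds it to the
    #: intercepts of both omics regressions before generation (expression
    #: additionally inherits the methylation shift through gamma_m); "post"
    #: adds it to the final M and E values.
    shift_mode: str = "intercept"
    #: "retrospective" draws n_case/n_control strata directly (quota design);
    #: "prospective" labels a source population by the phenotype model and
    #: samples until the quotas fill.
    sampling: str = "retrospective"
    risk_model: str = "additive"
    seed: int | None = None

    def __post_init__(self) -> None:
        fracs = (self.m_both, self.m_meth_only, self.m_expr_only)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValueError("missing fractions must lie in [0,1] and sum to <= 1")
        if self.shift_mode not in ("intercept", "post"):
            raise ValueError("shift_mode must be 'intercept' or 'post'")
        if self.sampling not in ("retrospective", "prospective"):
            raise ValueError("sampling must be 'retrospective' or 'prospective'")
        if self.risk_model not in ("additive", "multiplicative"):
            raise ValueError("risk_model must be 'additive' or 'multiplicative'")
        self.beta_x = tuple(float(b) for b in np.atleast_1d(self.beta_x))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def true_params(self) -> ModelParams:
        """The generative parameter vector (excluding the case shift)."""
        return ModelParams(
            beta0=self.beta0, beta_x=np.asarray(self.beta_x),
            beta_g=self.beta_g, beta_m=self.beta_m, beta_e=self.beta_e,
            alpha0=self.alpha0, alpha_g=self.alpha_g, gamma0=self.gamma0,
            gamma_g=self.gamma_g, gamma_m=self.gamma_m,
            sigma1_sq=self.sigma1_sq, sigma2_sq=self.sigma2_sq, p=self.maf)


def hwe_freqs(maf: float) -> np.ndarray:
    """P(G = 0, 1, 2) minor-allele copies under Hardy-Weinberg equilibrium."""
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


def genotype_freqs_case(maf: float, rr: float, prevalence: float,
                        risk_model: str = "additive") -> np.ndarray:
    """Genotype law among cases under a genotype-relative-risk model.

    Penetrances relative to the zero-copy baseline f0 are (1, rr, 2 rr - 1)
    for the additive model (equal per-copy increments) or (1, rr, rr^2) for
    the multiplicative model; f0 is solved so that the population prevalence
    matches, and the case law follows by Bayes' rule.
    """
    if risk_model == "additive":
        rel = np.array([1.0, rr, 2.0 * rr - 1.0])
    elif risk_model == "multiplicative":
        rel = np.array([1.0, rr, rr * rr])
    else:
        raise ValueError("risk_model must be 'additive' or 'multiplicative'")
    hwe = hwe_freqs(maf)
    f0 = prevalence / float(hwe @ rel)
    pen = f0 * rel
    if f0 <= 0.0 or np.any(pen >= 1.0) or np.any(pen <= 0.0):
        raise ValueError("infeasible penetrances for this (maf, rr, prevalence)")
    out = pen * hwe / prevalence
    return out / out.sum()


def simulate_covariates(n: int, config: SimConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Age ~ N(age_mean, age_sd) and sex ~ Bernoulli(sex_prob), as columns."""
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = rng.binomial(1, config.sex_prob, size=n).astype(float)
    return np.column_stack([age, sex])


def simulate_omics(G: np.ndarray, case_flag: np.ndarray, config: SimConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (M, E) from the two regression layers with the case mean shift."""
    G = np.asarray(G, dtype=float)
    case_flag = np.asarray(case_flag, dtype=bool)
    n = G.shape[0]
    shift = 0.0 if config.null_scenario else config.case_shift
    s = shift * case_flag
    e1 = rng.normal(0.0, np.sqrt(config.sigma1_sq), size=n)
    e2 = rng.normal(0.0, np.sqrt(config.sigma2_sq), size=n)
    if config.shift_mode == "intercept":
        M = config.alpha0 + s + config.alpha_g * G + e1
        E = config.gamma0 + s + config.gamma_g * G + config.gamma_m * M + e2
    else:  # post-hoc shift of the realized values
        M = config.alpha0 + config.alpha_g * G + e1
        E = config.gamma0 + config.gamma_g * G + config.gamma_m * M + e2
        M = M + s
        E = E + s
    return M, E


def _phenotype_prob(config: SimConfig, X, G, M, E) -> np.ndarray:
    """P(Y = +1) from the logistic phenotype layer (diagnostic record)."""
    bx = np.asarray(config.beta_x)
    lp = (config.beta0 + X @ bx + config.beta_g * G + config.beta_m * M
          + config.beta_e * E)
    return 1.0 / (1.0 + np.exp(-lp))


def _simulate_retrospective(config: SimConfig,
                            rng: np.random.Generator) -> TrioDataset:
    hwe = hwe_freqs(config.maf)
    case_law = (hwe if config.null_scenario else
                genotype_freqs_case(config.maf, config.rr, config.prevalence,
                                    config.risk_model))
    G = np.concatenate([rng.choice(3, size=config.n_control, p=hwe),
                        rng.choice(3, size=config.n_case, p=case_law)]).astype(float)
    y = np.concatenate([-np.ones(config.n_control), np.ones(config.n_case)])
    X = simulate_covariates(config.n_control + config.n_case, config, rng)
    M, E = simulate_omics(G, y > 0, config, rng)
    return TrioDataset(y=y, X=X, G=G, M=M, E=E, covariate_names=("age", "sex"))


def _simulate_prospective(config: SimConfig,
                          rng: np.random.Generator) -> TrioDataset:
    """Label a source population by the phenotype model, fill the quotas."""
    hwe = hwe_freqs(config.maf)
    need = {1.0: config.n_case, -1.0: config.n_control}
    rows: list[np.ndarray] = []
    guard = 0
    while (need[1.0] > 0 or need[-1.0] > 0) and guard < 10_000:
        guard += 1
        k = 4 * (config.n_case + config.n_control)
        G = rng.choice(3, size=k, p=hwe).astype(float)
        X = simulate_covariates(k, config, rng)
        M, E = simulate_omics(G, np.zeros(k, dtype=bool), config, rng)
        if config.null_scenario:
            lp = config.beta0 + X @ np.asarray(config.beta_x)
            prob = 1.0 / (1.0 + np.exp(-lp))
        else:
            prob = _phenotype_prob(config, X, G, M, E)
        yy = np.where(rng.random(k) < prob, 1.0, -1.0)
        for i in range(k):
            if need[yy[i]] > 0:
                need[yy[i]] -= 1
                rows.append(np.r_[yy[i], X[i], G[i], M[i], E[i]])
            if need[1.0] == 0 and need[-1.0] == 0:
                break
    arr = np.asarray(rows)
    order = np.argsort(arr[:, 0], kind="stable")  # controls first
    arr = arr[order]
    return TrioDataset(y=arr[:, 0], X=arr[:, 1:3], G=arr[:, 3],
                       M=arr[:, 4], E=arr[:, 5], covariate_names=("age", "sex"))


def simulate_dataset(config: SimConfig,
                     rng: np.random.Generator | None = None) -> TrioDataset:
    """Draw one complete (no-missingness) case-control dataset.

    The per-individual phenotype-layer probability is recorded on the
    returned dataset as ``bernoulli_prob`` for diagnostics.
    """
    rng = config.rng() if rng is None else rng
    if config.sampling == "retrospective":
        data = _simulate_retrospective(config, rng)
    else:
        data = _simulate_prospective(config, rng)
    data.bernoulli_prob = _phenotype_prob(config, data.X, data.G, data.M, data.E)
    return data


def inject_missingness(data: TrioDataset, m_both: float, m_meth_only: float,
                       m_expr_only: float,
                       rng: np.random.Generator) -> TrioDataset:
    """Blank omics entries completely at random, balanced across strata.

    Disjoint subsets of the given fractions (rounded per stratum) lose both
    layers, methylation only, or expression only.
    """
    fracs = (m_both, m_meth_only, m_expr_only)
    if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
        raise ValueError("missing fractions must lie in [0,1] and sum to <= 1")
    M = data.M.copy()
    E = data.E.copy()
    for stratum in (-1.0, 1.0):
        idx = np.flatnonzero(data.y == stratum)
        k_both = round(m_both * idx.size)
        k_meth = round(m_meth_only * idx.size)
        k_expr = round(m_expr_only * idx.size)
        if k_both + k_meth + k_expr > idx.size:
            raise ValueError("missing fractions exceed stratum size")
        perm = rng.permutation(idx)
        both = perm[:k_both]
        meth = perm[k_both:k_both + k_meth]
        expr = perm[k_both + k_meth:k_both + k_meth + k_expr]
        M[both] = np.nan
        E[both] = np.nan
        M[meth] = np.nan
        E[expr] = np.nan
    return TrioDataset(y=data.y.copy(), X=data.X.copy(), G=data.G.copy(),
                       M=M, E=E, covariate_names=data.covariate_names)


def simulate_study_dataset(config: SimConfig,
                           rng: np.random.Generator | None = None) -> TrioDataset:
    """Complete simulation plus the configured missingness injection."""
    rng = config.rng() if rng is None else rng
    data = simulate_dataset(config, rng)
    if config.m_both or config.m_meth_only or config.m_expr_only:
        data = inject_missingness(data, config.m_both, config.m_meth_only,
                                  config.m_expr_only, rng)
    return data
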