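"""Scikit-learn style estimators over the trio likelihood.

:class:`TrioAssociationTest` is the hypothesis-testing front end (fit
computes the null and alternative maximum-likelihood fits and the
likelihood-ratio statistic); :class:`TrioClassifier` is the predictive front
end (fit computes the unconstrained MLE, predict scores case probability
from whatever omics layers are observed, marginalizing the missing ones).

Both accept either a DataFrame with named genotype/methylation/expression
columns or a plain array whose *last three columns* are genotype,
methylation and expression; any remaining columns are covariates.
Methylation/expression entries may be NaN (missing); phenotype, covariates
and genotype may not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import kernels
from .data import TrioDataset
from .likelihood import fit_mle
from .params import TESTABLE_EFFECTS, ModelParams

__all__ = ["TrioAssociationTest", "TrioClassifier", "case_probability"]


def case_probability(params: ModelParams, X, G, M, E) -> np.ndarray:
    """P(Y = case) per individual, marginalizing missing omics layers.

    Fully observed rows use the exact logistic phenotype model; rows with a
    missing layer use the matching closed-form marginalized kernel.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1) if params.n_covariates == 1 else X.reshape(1, -1)
    G = np.atleast_1d(np.asarray(G, dtype=float))
    M = np.atleast_1d(np.asarray(M, dtype=float))
    E = np.atleast_1d(np.asarray(E, dtype=float))
    out = np.empty(G.shape[0])
    obs_m, obs_e = ~np.isnan(M), ~np.isnan(E)

    i = obs_m & obs_e
    if i.any():
        lp = (params.beta0 + X[i] @ params.beta_x + params.beta_g * G[i]
              + params.beta_m * M[i] + params.beta_e * E[i])
        out[i] = kernels.sigmoid(lp)
    i = obs_m & ~obs_e
    if i.any():
        out[i] = kernels.cond_prob_missing_E(1.0, X[i], G[i], M[i], params)
    i = ~obs_m & obs_e
    if i.any():
        out[i] = kernels.cond_prob_missing_M(1.0, X[i], G[i], E[i], params)
    i = ~obs_m & ~obs_e
    if i.any():
        out[i] = kernels.cond_prob_missing_EM(1.0, X[i], G[i], params)
    return out


def _split_features(X, g_col: str, m_col: str, e_col: str):
    """Split a feature table into (covariates, names, G, M, E)."""
    if isinstance(X, pd.DataFrame):
        for col in (g_col, m_col, e_col):
            if col not in X.columns:
                raise ValueError(f"missing required column {col!r}")
        cov_cols = [c for c in X.columns if c not in {g_col, m_col, e_col}]
        return (X[cov_cols].to_numpy(dtype=float), tuple(cov_cols),
                X[g_col].to_numpy(dtype=float),
                X[m_col].to_numpy(dtype=float),
                X[e_col].to_numpy(dtype=float))
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("X must be 2-D with at least 3 columns (G, M, E last)")
    J = X.shape[1] - 3
    names = tuple(f"x{j+1}" for j in range(J))
    return X[:, :J], names, X[:, J], X[:, J + 1], X[:, J + 2]


def _encode_phenotype(y) -> tuple[np.ndarray, np.ndarray]:
    """Map labels to -1/+1; returns (coded, classes in [control, case] order)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.shape[0] != 2:
        raise ValueError("phenotype must have exactly two classes")
    coded = np.where(y == classes[1], 1.0, -1.0)
    return coded, classes


class _TrioBase(BaseEstimator):
    def _dataset(self, X, y) -> tuple[TrioDataset, np.ndarray]:
        cov, names, G, M, E = _split_features(X, self.g_col, self.m_col,
                                              self.e_col)
        coded, classes = _encode_phenotype(y)
        data = TrioDataset(y=coded, X=cov, G=G, M=M, E=E, covariate_names=names)
        return data, classes


class TrioAssociationTest(_TrioBase):
    """Likelihood-ratio test of trio effects on a binary phenotype.

    Parameters
    ----------
    tested : tuple of str
        Subset of ``("beta_g", "beta_m", "beta_e")`` constrained to zero
        under the null; the default tests all three (df = 3).
    g_col, m_col, e_col : str
        Column names of genotype, methylation, expression when ``X`` is a
        DataFrame.

    Attributes
    ----------
    lambda_ : float       likelihood-ratio statistic (>= 0)
    df_ : int             degrees of freedom of the null chi-square
    p_value_ : float      asymptotic upper-tail p-value
    params_ : ModelParams alternative-fit parameter estimates
    fit_null_, fit_alt_ : FitResult
    """

    def __init__(self, tested: tuple = TESTABLE_EFFECTS,
                 g_col: str = "G", m_col: str = "M", e_col: str = "E"):
        self.tested = tested
        self.g_col = g_col
        self.m_col = m_col
        self.e_col = e_col

    def fit(self, X, y):
        from .inference import lrt_subset  # local import avoids cycle
        data, classes = self._dataset(X, y)
        res = lrt_subset(data, self.tested)
        self.classes_ = classes
        self.result_ = res
        self.lambda_ = res.lambda_stat
        self.df_ = res.df
        self.p_value_ = res.p_value
        self.fit_null_ = res.fit_null
        self.fit_alt_ = res.fit_alt
        self.params_ = res.fit_alt.params_hat
        self.n_features_in_ = (X.shape[1] if hasattr(X, "shape")
                               else len(X[0]))
        return self


class TrioClassifier(_TrioBase, ClassifierMixin):
    """Case/control classifier built on the full trio likelihood.

    Fits the unconstrained MLE and predicts the case probability through the
    phenotype layer, marginalizing any missing omics entries of the rows
    being scored (no imputation).
    """

    def __init__(self, threshold: float = 0.5,
                 g_col: str = "G", m_col: str = "M", e_col: str = "E"):
        self.threshold = threshold
        self.g_col = g_col
        self.m_col = m_col
        self.e_col = e_col

    def fit(self, X, y):
        data, classes = self._dataset(X, y)
        self.fit_result_ = fit_mle(data)
        self.params_ = self.fit_result_.params_hat
        self.classes_ = classes
        self.n_features_in_ = (X.shape[1] if hasattr(X, "shape")
                               else len(X[0]))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        cov, _, G, M, E = _split_features(X, self.g_col, self.m_col, self.e_col)
        p_case = case_probability(self.params_, cov, G, M, E)
        return np.column_stack([1.0 - p_case, p_case])

    def predict(self, X):
        p_case = self.predict_proba(X)[:, 1]
        return np.where(p_case > self.threshold,
                        self.classes_[1], self.classes_[0])
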