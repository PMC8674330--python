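"""Operating-characteristic studies: type I error, power, CV prediction.

Monte-Carlo studies over the simulator: empirical type I error of the trio
test at the asymptotic threshold, power at an empirical 5% cutoff taken
from the null Lambda distribution (holding type I error at exactly the
nominal level for comparisons), tenfold cross-validated classification
accuracy, ROC operating points, and the complete-case / mean-imputation /
KNN-imputation baselines the integrated likelihood is compared against.

Replicate counts default to desk-scale values (2000 null / 500 alternative
replicates); every rate is reported with its binomial Monte-Carlo standard
error so reduced-replicate results remain interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import chi2
from sklearn.impute import KNNImputer

from .data import TrioDataset
from .estimators import case_probability
from .likelihood import FitResult, fit_mle
from .inference import lrt_trio
from .params import ModelParams
from .simulate import SimConfig, simulate_study_dataset

__all__ = ["PowerStudyResult", "null_lambda_sample", "estimate_type1",
           "empirical_cutoff", "estimate_power", "classify",
           "crossvalidate_tenfold", "cv_case_probabilities", "roc_points",
           "baseline_fit", "prepare_baseline"]

_STRATEGIES = ("integrated", "complete_case", "mean_impute", "knn_impute")


@dataclass
class PowerStudyResult:
    """One cell of a type-I-error or power table."""

    scheme: tuple[float, float, float]   # (both, meth-only, expr-only) fractions
    sample_size: int                     # per-stratum n
    n_reps: int
    rejection_rate: float
    cutoff_source: str                   # "asymptotic" or "empirical-null"
    mc_se: float
    seed: int | None
    method: str = "integrated"

    @staticmethod
    def _se(rate: float, n_reps: int) -> float:
        return float(np.sqrt(rate * (1.0 - rate) / n_reps))


def prepare_baseline(data: TrioDataset, strategy: str) -> TrioDataset:
    """Transform a partially missing dataset per a baseline strategy.

    ``complete_case`` drops every row with a missing omics entry;
    ``mean_impute`` fills missing entries with the observed column mean;
    ``knn_impute`` fills them by k-nearest-neighbour averaging (k = 5,
    Euclidean distance over standardized covariates, genotype and the
    observed omics).  ``integrated`` returns the data unchanged.
    """
    if strategy not in _STRATEGIES:
        raise ValueError(f"strategy must be one of {_STRATEGIES}")
    if strategy == "integrated" or data.is_complete:
        return data
    if strategy == "complete_case":
        return data.complete_cases()
    M, E = data.M.copy(), data.E.copy()
    if strategy == "mean_impute":
        M[np.isnan(M)] = np.nanmean(M)
        E[np.isnan(E)] = np.nanmean(E)
    else:
        feats = np.column_stack([data.X, data.G, M, E])
        mu = np.nanmean(feats, axis=0)
        sd = np.nanstd(feats, axis=0)
        sd[sd == 0] = 1.0
        filled = KNNImputer(n_neighbors=5).fit_transform((feats - mu) / sd)
        filled = filled * sd + mu
        M, E = filled[:, -2], filled[:, -1]
    return TrioDataset(y=data.y, X=data.X, G=data.G, M=M, E=E,
                       covariate_names=data.covariate_names)


def baseline_fit(data: TrioDataset, strategy: str = "integrated",
                 constrained=()) -> FitResult:
    """MLE after applying a baseline missing-data strategy."""
    return fit_mle(prepare_baseline(data, strategy), constrained=constrained)


def _lambda_once(config: SimConfig, rng: np.random.Generator,
                 method: str) -> float:
    data = prepare_baseline(simulate_study_dataset(config, rng), method)
    return lrt_trio(data).lambda_stat


def null_lambda_sample(config: SimConfig, n_reps: int,
                       rng: np.random.Generator | None = None,
                       method: str = "integrated") -> np.ndarray:
    """Lambda statistics from replicates generated under the null."""
    config = replace(config, null_scenario=True)
    rng = config.rng() if rng is None else rng
    return np.array([_lambda_once(config, rng, method) for _ in range(n_reps)])


def estimate_type1(config: SimConfig, n_reps: int = 2000, level: float = 0.05,
                   rng: np.random.Generator | None = None,
                   method: str = "integrated") -> PowerStudyResult:
    """Empirical rejection rate of the asymptotic-level test under the null."""
    lam = null_lambda_sample(config, n_reps, rng, method)
    rate = float(np.mean(lam > chi2.ppf(1.0 - level, 3)))
    return PowerStudyResult(
        scheme=(config.m_both, config.m_meth_only, config.m_expr_only),
        sample_size=config.n_case, n_reps=n_reps, rejection_rate=rate,
        cutoff_source="asymptotic", mc_se=PowerStudyResult._se(rate, n_reps),
        seed=config.seed, method=method)


def empirical_cutoff(config: SimConfig, n_reps: int = 2000,
                     level: float = 0.05,
                     rng: np.random.Generator | None = None,
                     method: str = "integrated") -> float:
    """Empirical (1 - level) quantile of the null Lambda distribution."""
    lam = null_lambda_sample(config, n_reps, rng, method)
    return float(np.quantile(lam, 1.0 - level))


def estimate_power(config: SimConfig, n_reps: int = 500,
                   cutoff: float | None = None, level: float = 0.05,
                   rng: np.random.Generator | None = None,
                   method: str = "integrated") -> PowerStudyResult:
    """Rejection rate under the alternative at a given Lambda cutoff.

    ``cutoff`` is normally the :func:`empirical_cutoff` of the same scheme
    and sample size; if omitted, the asymptotic chi-square threshold is used.
    """
    source = "empirical-null"
    if cutoff is None:
        cutoff = float(chi2.ppf(1.0 - level, 3))
        source = "asymptotic"
    config = replace(config, null_scenario=False)
    rng = config.rng() if rng is None else rng
    lam = np.array([_lambda_once(config, rng, method) for _ in range(n_reps)])
    rate = float(np.mean(lam > cutoff))
    return PowerStudyResult(
        scheme=(config.m_both, config.m_meth_only, config.m_expr_only),
        sample_size=config.n_case, n_reps=n_reps, rejection_rate=rate,
        cutoff_source=source, mc_se=PowerStudyResult._se(rate, n_reps),
        seed=config.seed, method=method)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def classify(params: ModelParams, x, g, m=np.nan, e=np.nan) -> float | np.ndarray:
    """P(Y = case) through the phenotype layer, marginalizing missing omics."""
    out = case_probability(params, x, g, m, e)
    return float(out[0]) if out.size == 1 and np.ndim(g) == 0 else out


def _cv_folds(data: TrioDataset, n_folds: int,
              rng: np.random.Generator) -> list[np.ndarray]:
    """Stratified folds over the complete cases only (the test pool)."""
    complete = data.idx_full
    if complete.size < n_folds:
        raise ValueError(f"need at least {n_folds} complete cases for "
                         f"{n_folds}-fold cross-validation")
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for stratum in (-1.0, 1.0):
        idx = complete[data.y[complete] == stratum]
        idx = rng.permutation(idx)
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[k].extend(chunk.tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]


def cv_case_probabilities(data: TrioDataset, n_folds: int = 10,
                          rng: np.random.Generator | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold case probabilities for every complete case.

    Test folds are drawn from the complete cases; each training set is all
    remaining individuals including the incomplete ones (fitted through the
    missing-data likelihood).  Returns ``(test_indices, probabilities)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    idx_all, probs_all = [], []
    for test_idx in _cv_folds(data, n_folds, rng):
        train_mask = np.ones(data.n, dtype=bool)
        train_mask[test_idx] = False
        fit = fit_mle(data.subset(np.flatnonzero(train_mask)))
        p = case_probability(fit.params_hat, data.X[test_idx],
                             data.G[test_idx], data.M[test_idx],
                             data.E[test_idx])
        idx_all.append(test_idx)
        probs_all.append(p)
    return np.concatenate(idx_all), np.concatenate(probs_all)


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    acc = float(np.mean(y_pred == y_true))
    case, ctrl = y_true > 0, y_true < 0
    sens = float(np.mean(y_pred[case] == 1.0)) if case.any() else np.nan
    spec = float(np.mean(y_pred[ctrl] == -1.0)) if ctrl.any() else np.nan
    return acc, sens, spec


def crossvalidate_tenfold(data: TrioDataset, threshold: float = 0.5,
                          rng: np.random.Generator | None = None,
                          n_folds: int = 10) -> tuple[float, float, float]:
    """Tenfold CV (accuracy, sensitivity, specificity) at a threshold."""
    idx, probs = cv_case_probabilities(data, n_folds, rng)
    pred = np.where(probs > threshold, 1.0, -1.0)
    return _rates(data.y[idx], pred)


def roc_points(data: TrioDataset,
               thresholds: Sequence[float] | None = None,
               rng: np.random.Generator | None = None,
               n_folds: int = 10) -> np.ndarray:
    """CV-based ROC operating points (1 - specificity, sensitivity).

    One probability sweep over a threshold grid (default: 101 evenly spaced
    thresholds in [0, 1]); returns an array of shape (len(grid), 2).
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    idx, probs = cv_case_probabilities(data, n_folds, rng)
    y = data.y[idx]
    pts = []
    for t in thresholds:
        pred = np.where(probs > t, 1.0, -1.0)
        _, sens, spec = _rates(y, pred)
        pts.append((1.0 - spec, sens))
    return np.asarray(pts)
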