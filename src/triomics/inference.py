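"""Likelihood-ratio testing of trio effects and batch screening.

The primary hypothesis is H0: beta_e = beta_m = beta_g = 0 (no phenotype
effect of any trio component), tested with the likelihood-ratio statistic
Lambda = 2 (loglik_alt - loglik_null), asymptotically chi-square with 3
degrees of freedom under H0.  Any subset of the three effects can be tested
the same way (df = subset size).  Batch screens apply Benjamini-Hochberg
correction across all trios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .data import TrioDataset
from .likelihood import FitResult, fit_mle
from .params import TESTABLE_EFFECTS

__all__ = ["TrioTestResult", "lrt_trio", "lrt_subset", "bh_adjust",
           "run_trio_screen"]

logger = logging.getLogger(__name__)

#: negative Lambda larger than this magnitude triggers the restart path;
#: smaller wiggle is numerical noise and clamped to zero.
_LAMBDA_TOL = 1e-6


@dataclass
class TrioTestResult:
    """Result of one trio (or duo/single) likelihood-ratio test."""

    lambda_stat: float
    df: int
    p_value: float
    fit_null: FitResult
    fit_alt: FitResult
    hypothesis: tuple[str, ...]
    trio_id: Mapping[str, str] | None = None
    p_adjusted: float | None = None

    @property
    def converged(self) -> bool:
        return self.fit_null.converged and self.fit_alt.converged


def lrt_subset(data: TrioDataset,
               tested: Iterable[str] = TESTABLE_EFFECTS) -> TrioTestResult:
    """Likelihood-ratio test constraining the named phenotype effects to 0."""
    tested = tuple(tested)
    if not tested or not set(tested) <= set(TESTABLE_EFFECTS):
        raise ValueError(f"tested must be a nonempty subset of {TESTABLE_EFFECTS}")
    fit_alt = fit_mle(data)
    fit_null = fit_mle(data, constrained=tested)
    lam = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if lam < -_LAMBDA_TOL:
        # nested optima must satisfy Lambda >= 0: refit the worse side from
        # the better side's estimates
        logger.warning("negative LRT statistic %.3g; refitting", lam)
        fit_alt2 = fit_mle(data, start=fit_null.params_hat)
        if fit_alt2.loglik > fit_alt.loglik:
            fit_alt = fit_alt2
        lam = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if -_LAMBDA_TOL <= lam < 0.0:
        logger.debug("clamping tiny negative LRT statistic %.3g to 0", lam)
        lam = 0.0
    df = len(tested)
    return TrioTestResult(
        lambda_stat=float(lam), df=df,
        p_value=float(chi2.sf(lam, df)) if lam >= 0 else float("nan"),
        fit_null=fit_null, fit_alt=fit_alt, hypothesis=tested)


def lrt_trio(data: TrioDataset) -> TrioTestResult:
    """The 3-df trio test: H0: beta_e = beta_m = beta_g = 0."""
    return lrt_subset(data, TESTABLE_EFFECTS)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_trio_screen(catalog,
                    data_for_trio: Callable[..., TrioDataset],
                    alpha: float = 0.05) -> pd.DataFrame:
    """Run the trio test for every catalog entry and BH-adjust across all.

    ``data_for_trio`` maps one catalog entry to a :class:`TrioDataset`.
    Per-trio failures are logged and reported with status ``error`` without
    aborting the batch.  Rows are sorted by adjusted p-value.
    """
    entries = list(getattr(catalog, "entries", catalog))
    rows = []
    for entry in entries:
        gene, snp, cpg = entry[0], entry[1], entry[2]
        rec = dict(gene=gene, snp=snp, cpg=cpg, lambda_stat=np.nan, df=3,
                   p_value=np.nan, converged=False, status="ok")
        try:
            res = lrt_trio(data_for_trio(entry))
            rec.update(lambda_stat=res.lambda_stat, df=res.df,
                       p_value=res.p_value, converged=res.converged)
            if not res.converged:
                rec["status"] = "non-converged"
        except Exception as exc:  # noqa: BLE001 - batch must not abort
            logger.warning("trio (%s, %s, %s) failed: %s", gene, snp, cpg, exc)
            rec["status"] = "error"
        rows.append(rec)
    table = pd.DataFrame(rows)
    if len(table):
        ok = table["p_value"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = bh_adjust(table.loc[ok, "p_value"].to_numpy())
        table["p_adjusted"] = adj
        table["significant"] = table["p_adjusted"] < alpha
        table = table.sort_values("p_adjusted", kind="stable",
                                  na_position="last").reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=["gene", "snp", "cpg", "lambda_stat",
                                      "df", "p_value", "converged", "status",
                                      "p_adjusted", "significant"])
    n_bad = int((table["status"] != "ok").sum()) if len(table) else 0
    if n_bad:
        logger.warning("%d of %d trios failed or did not converge",
                       n_bad, len(table))
    return table
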