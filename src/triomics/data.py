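"""Per-individual trio dataset with an explicit missingness partition.

A :class:`TrioDataset` aligns, for ``n`` individuals, a binary phenotype
(-1 control / +1 case), a covariate matrix, a genotype vector (minor-allele
counts, never missing), and methylation/expression vectors in which entries
may be absent (``NaN``).  Phenotype, covariates and genotype are assumed
observed for everyone; only the two molecular layers may be missing.

The partition into the four observation patterns

* ``idx_full``       both layers observed            (size ``n1``)
* ``idx_missing_e``  expression missing, M observed  (size ``n2``)
* ``idx_missing_m``  methylation missing, E observed (size ``n3``)
* ``idx_missing_em`` both layers missing             (size ``n4``)

is derived from the NaN pattern and always disjoint and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["TrioDataset", "read_dataset", "write_dataset"]

_PHENOTYPE_CODES: Mapping[object, int] = {
    -1: -1, 1: 1, 0: -1,
    "-1": -1, "1": 1, "0": -1,
    "control": -1, "case": 1,
}


@dataclass
class TrioDataset:
    """Aligned phenotype / covariates / genotype / methylation / expression."""

    y: np.ndarray
    X: np.ndarray
    G: np.ndarray
    M: np.ndarray
    E: np.ndarray
    covariate_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.shape[0]
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(n, 1) if self.X.size == n else self.X.reshape(n, -1)
        self.G = np.asarray(self.G, dtype=float).ravel()
        self.M = np.asarray(self.M, dtype=float).ravel()
        self.E = np.asarray(self.E, dtype=float).ravel()
        for name, arr in (("X", self.X), ("G", self.G), ("M", self.M), ("E", self.E)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            bad = np.flatnonzero(~np.isin(self.y, (-1.0, 1.0)))
            raise ValueError(f"phenotype must be coded -1/+1; bad rows: {bad[:5]}")
        if np.isnan(self.X).any():
            raise ValueError("covariates must not contain missing values")
        if np.isnan(self.G).any() or not np.all(np.isin(self.G, (0.0, 1.0, 2.0))):
            bad = np.flatnonzero(~np.isin(self.G, (0.0, 1.0, 2.0)))
            raise ValueError(f"genotype must be 0/1/2 and observed; bad rows: {bad[:5]}")
        if not self.covariate_names:
            self.covariate_names = tuple(f"x{j+1}" for j in range(self.X.shape[1]))
        else:
            self.covariate_names = tuple(self.covariate_names)
            if len(self.covariate_names) != self.X.shape[1]:
                raise ValueError("covariate_names does not match X")

    # -- partition ---------------------------------------------------------

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def observed_m(self) -> np.ndarray:
        return ~np.isnan(self.M)

    @property
    def observed_e(self) -> np.ndarray:
        return ~np.isnan(self.E)

    @property
    def idx_full(self) -> np.ndarray:
        return np.flatnonzero(self.observed_m & self.observed_e)

    @property
    def idx_missing_e(self) -> np.ndarray:
        return np.flatnonzero(self.observed_m & ~self.observed_e)

    @property
    def idx_missing_m(self) -> np.ndarray:
        return np.flatnonzero(~self.observed_m & self.observed_e)

    @property
    def idx_missing_em(self) -> np.ndarray:
        return np.flatnonzero(~self.observed_m & ~self.observed_e)

    @property
    def partition_sizes(self) -> tuple[int, int, int, int]:
        """(n1, n2, n3, n4) = (full, E missing, M missing, both missing)."""
        return (self.idx_full.size, self.idx_missing_e.size,
                self.idx_missing_m.size, self.idx_missing_em.size)

    @property
    def is_complete(self) -> bool:
        return self.idx_full.size == self.n

    def subset(self, idx) -> "TrioDataset":
        idx = np.asarray(idx)
        return TrioDataset(self.y[idx], self.X[idx], self.G[idx],
                           self.M[idx], self.E[idx], self.covariate_names)

    def complete_cases(self) -> "TrioDataset":
        return self.subset(self.idx_full)

    # -- conversion --------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"y": self.y.astype(int)})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.X[:, j]
        df["G"] = self.G.astype(int)
        df["M"] = self.M
        df["E"] = self.E
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       y_col: str = "y", g_col: str = "G",
                       m_col: str = "M", e_col: str = "E",
                       covariate_cols: Sequence[str] | None = None,
                       ) -> "TrioDataset":
        for col in (y_col, g_col, m_col, e_col):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns
                              if c not in {y_col, g_col, m_col, e_col, "id"}]
        y_raw = df[y_col]
        if y_raw.isna().any():
            bad = list(df.index[y_raw.isna()][:5])
            raise ValueError(f"missing phenotype in rows {bad}")
        try:
            y = np.array([_PHENOTYPE_CODES[v if isinstance(v, str) else int(v)]
                          for v in y_raw], dtype=float)
        except (KeyError, ValueError, TypeError):
            raise ValueError(
                f"phenotype column {y_col!r} must be coded 0/1, -1/+1 or "
                "control/case") from None
        X = df[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols \
            else np.empty((len(df), 0))
        return cls(y=y, X=X, G=df[g_col].to_numpy(dtype=float),
                   M=df[m_col].to_numpy(dtype=float),
                   E=df[e_col].to_numpy(dtype=float),
                   covariate_names=tuple(covariate_cols))


def read_dataset(path: str | Path, sep: str = "\t", na_token: str = "NA",
                 **column_mapping) -> TrioDataset:
    """Read a delimited trio table (header required, ``NA`` for missing)."""
    df = pd.read_csv(path, sep=sep, na_values=[na_token], keep_default_na=False)
    return TrioDataset.from_dataframe(df, **column_mapping)


def write_dataset(data: TrioDataset, path: str | Path, sep: str = "\t",
                  na_token: str = "NA") -> None:
    """Write a trio dataset as a delimited table with an explicit NA token."""
    df = data.to_dataframe()
    df.insert(0, "id", np.arange(1, data.n + 1))
    df.to_csv(path, sep=sep, index=False, na_rep=na_token, float_format="%.10g")
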