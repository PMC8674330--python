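"""Trio catalog construction from annotation tables.

A trio couples a gene's expression with one cis-SNP genotype and one
cis-CpG methylation site.  cis-SNPs are SNPs within a symmetric window
(default 2000 bp, closed interval, strand ignored) of the gene body;
cis-CpGs are either taken from a gene-mapped annotation table (the array
annotation route) or, optionally, selected by the same positional window.

Coordinates are interpreted as 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["TrioCatalog", "build_trio_catalog",
           "apply_expression_missingness_filter"]


@dataclass
class TrioCatalog:
    """Ordered (gene, snp, cpg) combinations with provenance."""

    entries: list[tuple[str, str, str]]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene", "snp", "cpg"])


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table lacks columns {missing}")


def build_trio_catalog(genes: pd.DataFrame, snps: pd.DataFrame,
                       cpgs: pd.DataFrame, window: int = 2000,
                       cpg_window: int | None = None) -> TrioCatalog:
    """Enumerate every gene x cis-SNP x cis-CpG combination.

    Parameters
    ----------
    genes : DataFrame with columns (chrom, start, end, id), 1-based inclusive.
    snps : DataFrame with columns (chrom, pos, id) or BED-like
        (chrom, start, end, id), in which case ``start`` is the position.
    cpgs : DataFrame with columns (cpg_id, gene_id, chrom, position); if
        ``cpg_window`` is given, ``gene_id`` is ignored and CpGs are matched
        positionally like SNPs.
    window : SNP cis-window in bp on each side of the gene (closed interval).
    """
    _require(genes, ("chrom", "start", "end", "id"), "gene")
    if "pos" not in snps.columns:
        _require(snps, ("chrom", "start", "id"), "snp")
        snps = snps.rename(columns={"start": "pos"})
    _require(snps, ("chrom", "pos", "id"), "snp")
    if cpg_window is None:
        _require(cpgs, ("cpg_id", "gene_id"), "cpg")
    else:
        _require(cpgs, ("cpg_id", "chrom", "position"), "cpg")

    genes = genes.sort_values(["chrom", "start", "id"], kind="stable")
    entries: list[tuple[str, str, str]] = []
    for gene in genes.itertuples(index=False):
        lo, hi = gene.start - window, gene.end + window
        near = snps[(snps["chrom"] == gene.chrom)
                    & (snps["pos"] >= lo) & (snps["pos"] <= hi)]
        near = near.sort_values(["pos", "id"], kind="stable")
        if cpg_window is None:
            mine = cpgs[cpgs["gene_id"] == gene.id]
            if "position" in mine.columns:
                mine = mine.sort_values(["position", "cpg_id"], kind="stable")
            else:
                mine = mine.sort_values("cpg_id", kind="stable")
        else:
            clo, chi = gene.start - cpg_window, gene.end + cpg_window
            mine = cpgs[(cpgs["chrom"] == gene.chrom)
                        & (cpgs["position"] >= clo)
                        & (cpgs["position"] <= chi)]
            mine = mine.sort_values(["position", "cpg_id"], kind="stable")
        for snp in near.itertuples(index=False):
            for cpg in mine.itertuples(index=False):
                entries.append((str(gene.id), str(snp.id), str(cpg.cpg_id)))
    return TrioCatalog(entries=entries,
                       provenance={"window": window, "cpg_window": cpg_window,
                                   "n_genes": len(genes), "n_snps": len(snps),
                                   "n_cpgs": len(cpgs)})


def apply_expression_missingness_filter(expression: pd.DataFrame,
                                        is_case: Sequence[bool],
                                        max_case_missing: float = 0.5
                                        ) -> list[str]:
    """Genes whose expression is complete in controls and tolerably missing
    in cases.

    ``expression`` is individuals x genes (NaN = missing).  A gene is kept
    when no control value is missing and the case missing fraction is at
    most ``max_case_missing`` (boundary included).
    """
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.shape[0] != expression.shape[0]:
        raise ValueError("is_case length must match expression rows")
    na = expression.isna().to_numpy()
    ctrl_ok = ~na[~is_case].any(axis=0)
    case_frac = na[is_case].mean(axis=0) if is_case.any() else np.zeros(na.shape[1])
    keep = ctrl_ok & (case_frac <= max_case_missing + 1e-12)
    return [g for g, k in zip(expression.columns, keep) if k]
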