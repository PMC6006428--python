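"""Gene co-expression analysis of protein-complex components.

The pipeline mirrors the standard RNA-seq co-expression recipe:
``log2(FPKM + 1)`` -> quantile normalization across samples -> per-gene
mean centering -> pairwise Pearson correlation (PCC) with t-distribution
p-values, masking entries above a p threshold -> complete-linkage
hierarchical ordering -> within/between-module PCC distribution
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CorrelationMatrix",
    "log2_transform",
    "quantile_normalize",
    "center_genes",
    "normalize",
    "pcc_matrix",
    "order_by_clustering",
    "module_pcc_density",
]


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """``log2(x + 1)``; the +1 keeps genes with zero counts finite."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log2(matrix + 1.0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common distribution of
    cross-sample mean order statistics; ties receive the mean of their
    tied target values (rank-average convention)."""
    v = matrix.to_numpy(float)
    order = np.sort(v, axis=0)
    target = order.mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        ranks = stats.rankdata(v[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (target[lo] + target[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def center_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean across samples."""
    return matrix.sub(matrix.mean(axis=1), axis=0)


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Full normalization chain: log2(x+1), quantile normalization,
    gene-mean centering.  Stages are individually importable."""
    return center_genes(quantile_normalize(log2_transform(matrix)))


@dataclass
class CorrelationMatrix:
    """Gene x gene PCC with p-values and a significance mask."""

    pcc: pd.DataFrame
    p_values: pd.DataFrame
    mask: pd.DataFrame  # True where p <= threshold (diagonal always True)
    p_threshold: float
    degenerate_genes: list[str]

    @property
    def masked_pcc(self) -> pd.DataFrame:
        return self.pcc.where(self.mask)


def pcc_matrix(matrix: pd.DataFrame, p_threshold: float = 0.01) -> CorrelationMatrix:
    """All-pairs Pearson correlation with two-sided t-distribution
    p-values; entries with p above the threshold are masked.

    Constant (zero-variance) genes have undefined correlations: their
    off-diagonal entries are masked and the genes reported.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    v = matrix.to_numpy(float)
    sd = v.std(axis=1)
    degenerate = list(matrix.index[sd == 0])
    vc = v - v.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum(axis=1))
    denom_safe = np.where(denom > 0, denom, 1.0)
    r = (vc @ vc.T) / np.outer(denom_safe, denom_safe)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    mask = p <= p_threshold
    bad = sd == 0
    mask[bad, :] = False
    mask[:, bad] = False
    np.fill_diagonal(mask, True)
    idx = matrix.index
    return CorrelationMatrix(
        pcc=pd.DataFrame(r, index=idx, columns=idx),
        p_values=pd.DataFrame(p, index=idx, columns=idx),
        mask=pd.DataFrame(mask, index=idx, columns=idx),
        p_threshold=p_threshold,
        degenerate_genes=degenerate,
    )


def order_by_clustering(corr: CorrelationMatrix | pd.DataFrame) -> list[str]:
    """Leaf order of complete-linkage agglomerative clustering on the
    distance ``1 - PCC``.  Deterministic (scipy's stable tie-breaking on
    the condensed distance ordering)."""
    pcc = corr.pcc if isinstance(corr, CorrelationMatrix) else corr
    if isinstance(corr, CorrelationMatrix) and not corr.mask.to_numpy().any():
        raise ValueError("correlation matrix is fully masked")
    genes = list(pcc.index)
    if len(genes) == 1:
        return genes
    d = 1.0 - pcc.to_numpy(float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(np.maximum(d, 0.0), checks=False), method="complete")
    return [genes[i] for i in leaves_list(Z)]


def module_pcc_density(
    corr: CorrelationMatrix | pd.DataFrame,
    gene_sets: dict[str, list[str]],
) -> dict:
    """Within- and between-set PCC distributions with kernel-density
    summaries.

    Returns per-set PCC value collections (upper-triangle, diagonal
    excluded), between-set collections for every set pair, Gaussian
    KDEs (normal-reference bandwidth) where at least two values exist,
    and the separation statistic: the spread (max - min) of within-set
    median PCCs.
    """
    pcc = corr.pcc if isinstance(corr, CorrelationMatrix) else corr
    genes = set(pcc.index)
    for name, members in gene_sets.items():
        if len(members) < 2:
            raise ValueError(f"gene set {name!r} has fewer than 2 genes")
        missing = set(members) - genes
        if missing:
            raise ValueError(f"gene set {name!r} has genes absent from matrix: {missing}")
    within: dict[str, np.ndarray] = {}
    for name, members in gene_sets.items():
        sub = pcc.loc[members, members].to_numpy(float)
        iu = np.triu_indices(len(members), k=1)
        within[name] = sub[iu]
    between: dict[tuple[str, str], np.ndarray] = {}
    names = list(gene_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            between[(a, b)] = pcc.loc[gene_sets[a], gene_sets[b]].to_numpy(float).ravel()
    densities = {}
    for name, vals in within.items():
        if len(vals) >= 2 and np.ptp(vals) > 0:
            densities[name] = stats.gaussian_kde(vals)  # normal-reference bandwidth
    medians = {name: float(np.median(vals)) for name, vals in within.items()}
    sep = max(medians.values()) - min(medians.values()) if medians else 0.0
    return {
        "within": within,
        "between": between,
        "kde": densities,
        "within_medians": medians,
        "median_separation": float(sep),
    }
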