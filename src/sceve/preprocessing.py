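"""Per-pool feature selection and normalization transforms.

Every clustering recursion reselects highly variable genes (HVGs) on the
counts of its own pool, then hands the base clusterers either a
log1p(CP10K) matrix (``lognorm``) or a log2(CPM+1) matrix (``log2cpm``),
depending on the transform each clusterer declares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix

__all__ = ["NormalizedMatrix", "select_hvg", "log_normalize", "to_log2_cpm"]


@dataclass
class NormalizedMatrix:
    """A genes x cells matrix of normalized expression values."""

    values: np.ndarray
    gene_ids: list
    cell_ids: list
    transform_tag: str  # "lognorm" or "log2cpm"

    def subset_genes(self, gene_ids) -> "NormalizedMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return NormalizedMatrix(
            self.values[rows, :], list(gene_ids), self.cell_ids, self.transform_tag
        )

    def subset_cells(self, cell_ids) -> "NormalizedMatrix":
        index = {c: j for j, c in enumerate(self.cell_ids)}
        cols = [index[c] for c in cell_ids]
        return NormalizedMatrix(
            self.values[:, cols], self.gene_ids, list(cell_ids), self.transform_tag
        )


def _scale_per_cell(counts: CountMatrix, scale: float) -> np.ndarray:
    values = counts.values.astype(float)
    totals = values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) have zero total counts; "
            "their normalized column is all zero",
            stacklevel=3,
        )
    safe = np.where(zero, 1.0, totals)
    return values * (scale / safe)


def log_normalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """log(1 + scale * count / cell_total), the standard log1p(CP10K)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    scaled = _scale_per_cell(counts, scale)
    return NormalizedMatrix(np.log1p(scaled), counts.gene_ids, counts.cell_ids, "lognorm")


def to_log2_cpm(counts: CountMatrix) -> NormalizedMatrix:
    """log2(1 + counts-per-million).

    With UMI counts and no gene lengths, transcripts-per-million reduces
    to counts-per-million (per-cell scaling only).
    """
    scaled = _scale_per_cell(counts, 1e6)
    return NormalizedMatrix(np.log2(1.0 + scaled), counts.gene_ids, counts.cell_ids, "log2cpm")


def select_hvg(counts: CountMatrix, k: int) -> list:
    """Select up to ``k`` highly variable genes.

    Genes are ranked by the variance of their log-normalized expression
    standardized against a mean-variance trend fitted by lowess; when the
    pool offers fewer than 20 distinct gene means the trend is
    unidentifiable and the raw log-expression variance is used instead.
    Ties break on gene id, so the ranking does not depend on input order.

    Returns
    -------
    list of str
        min(k, n_genes) gene ids in descending rank order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if counts.n_genes == 0 or counts.n_cells == 0:
        raise ValueError("empty count matrix")
    if counts.values.sum() == 0:
        raise ValueError("no variable genes: count matrix is all zero")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        log_values = np.log1p(_scale_per_cell(counts, 1e4))
    means = log_values.mean(axis=1)
    variances = log_values.var(axis=1, ddof=1 if counts.n_cells > 1 else 0)

    if np.unique(np.round(means, 6)).size >= 20:
        # heavily robustified so that a minority of genuinely variable genes
        # cannot drag the technical trend up towards themselves
        trend = lowess(variances, means, frac=0.3, it=10, return_sorted=False)
        floor = max(1e-12, 1e-4 * float(variances.max()))
        score = variances / np.maximum(trend, floor)
    else:
        score = variances

    order = sorted(range(counts.n_genes), key=lambda i: (-score[i], counts.gene_ids[i]))
    k_eff = min(k, counts.n_genes)
    return [counts.gene_ids[i] for i in order[:k_eff]]
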