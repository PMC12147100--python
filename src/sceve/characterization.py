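"""Marker-gene detection and the biological-characterization filter.

A consensus split is only kept when the robust clusters it proposes are
biologically distinct from the rest of their pool: a *marker gene* is a
gene expressed 16 times more in a cluster than in the rest of the pool
(log2 fold change > 4), and a cluster is *well-characterized* once 10
such markers are found.  Poorly characterized robust clusters are merged
into the leftover and characterization is attempted a second time; if no
robust cluster survives, the pool is not split at all — the guard
against over-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .preprocessing import NormalizedMatrix

__all__ = [
    "MarkerRecord",
    "CharacterizedCluster",
    "find_markers",
    "is_well_characterized",
    "characterize_split",
]


@dataclass
class MarkerRecord:
    gene: str
    log2_fc: float
    p_value: float
    p_adjusted: float


@dataclass
class CharacterizedCluster:
    """A cluster that survived (or forms the leftover of) the filter."""

    cells: frozenset
    robustness: float
    markers: list = field(default_factory=list)
    methods: list = field(default_factory=list)
    is_leftover: bool = False


def _delog(values: np.ndarray, transform_tag: str) -> np.ndarray:
    if transform_tag == "lognorm":
        return np.expm1(values)
    if transform_tag == "log2cpm":
        return np.exp2(values) - 1.0
    raise ValueError(f"unknown transform {transform_tag!r}")


def find_markers(
    norm: NormalizedMatrix,
    in_cells,
    out_cells,
    min_log2fc: float = 4.0,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    significance_filter: bool = True,
) -> list:
    """Marker genes of ``in_cells`` against ``out_cells``.

    The fold change compares pseudocount-shifted means of de-logged
    normalized expression; significance is a two-sided Wilcoxon rank-sum
    test on the normalized values, Bonferroni-adjusted over all tested
    genes.  Returns records with log2 fold change > ``min_log2fc`` (and
    adjusted p < ``alpha`` unless the significance filter is off),
    sorted by descending fold change.
    """
    in_cells, out_cells = set(in_cells), set(out_cells)
    if not in_cells or not out_cells:
        raise ValueError("both cell sets must be non-empty")
    if in_cells & out_cells:
        raise ValueError("cell sets must be disjoint")
    col = {c: j for j, c in enumerate(norm.cell_ids)}
    in_idx = [col[c] for c in sorted(in_cells)]
    out_idx = [col[c] for c in sorted(out_cells)]

    expr = _delog(norm.values, norm.transform_tag)
    mean_in = expr[:, in_idx].mean(axis=1)
    mean_out = expr[:, out_idx].mean(axis=1)
    log2_fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))

    n_genes = norm.values.shape[0]
    candidates = np.where(log2_fc > min_log2fc)[0]
    records = []
    if candidates.size:
        res = mannwhitneyu(
            norm.values[candidates][:, in_idx],
            norm.values[candidates][:, out_idx],
            axis=1,
            alternative="two-sided",
        )
        p_values = np.atleast_1d(res.pvalue)
        p_adjusted = np.minimum(p_values * n_genes, 1.0)  # Bonferroni
        for g, p, padj in zip(candidates, p_values, p_adjusted):
            if significance_filter and padj >= alpha:
                continue
            records.append(
                MarkerRecord(norm.gene_ids[g], float(log2_fc[g]), float(p), float(padj))
            )
    records.sort(key=lambda r: (-r.log2_fc, r.gene))
    return records


def is_well_characterized(markers: list, min_markers: int = 10) -> bool:
    """True once at least ``min_markers`` marker genes were detected."""
    return len(markers) >= min_markers


def characterize_split(
    norm: NormalizedMatrix,
    outcome,
    min_log2fc: float = 4.0,
    min_markers: int = 10,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    significance_filter: bool = True,
):
    """Apply the two-pass characterization filter to a consensus outcome.

    Pass 1 tests every robust cluster (and the leftover) against the
    rest of the pool; clusters short of ``min_markers`` markers are
    merged into the leftover.  Pass 2 re-tests the survivors and the
    enlarged leftover.  Returns the surviving clusters (leftover last,
    robustness 0, kept regardless of its own marker count) or ``None``
    when no robust cluster remains characterized — the no-split outcome.
    """
    if not outcome.robust_clusters:
        return None
    pool = frozenset(outcome.leftover_cells) | frozenset().union(
        *(rc.cells for rc in outcome.robust_clusters)
    )

    def markers_vs_rest(cells):
        rest = pool - cells
        if not rest:
            return []  # a cluster spanning the pool cannot be distinct from it
        return find_markers(
            norm, cells, rest,
            min_log2fc=min_log2fc, pseudocount=pseudocount,
            alpha=alpha, significance_filter=significance_filter,
        )

    survivors = list(outcome.robust_clusters)
    leftover = set(outcome.leftover_cells)
    for _ in range(2):  # two characterization attempts
        kept, marker_sets = [], []
        for rc in survivors:
            markers = markers_vs_rest(rc.cells)
            if is_well_characterized(markers, min_markers):
                kept.append(rc)
                marker_sets.append(markers)
            else:
                leftover |= rc.cells
        survivors = kept
        if not survivors:
            return None

    result = [
        CharacterizedCluster(rc.cells, rc.robustness, markers, rc.methods)
        for rc, markers in zip(survivors, marker_sets)
    ]
    if leftover:
        result.append(
            CharacterizedCluster(
                frozenset(leftover), 0.0, markers_vs_rest(frozenset(leftover)), [],
                is_leftover=True,
            )
        )
    return result
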