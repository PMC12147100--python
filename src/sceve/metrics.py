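"""Clustering performance metrics.

Two extrinsic metrics compare a predicted labelling with ground truth —
normalized mutual information (NMI) and the adjusted Rand index (ARI) —
and two intrinsic metrics score cluster cohesion on expression space —
the silhouette index (SI) and neighborhood purity (nPurity, the mean
fraction of a cell's k nearest neighbours sharing its label).  All four
accept labellings over a subset of cells, so leftover-excluded
evaluation (keeping only cells the ensemble is confident about) is just
a restricted labelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
)
from sklearn.neighbors import NearestNeighbors

from .preprocessing import NormalizedMatrix

__all__ = [
    "nmi",
    "ari",
    "silhouette",
    "neighborhood_purity",
    "leaf_labelling_from_tables",
]


def _as_series(labelling) -> pd.Series:
    if isinstance(labelling, pd.Series):
        series = labelling
    else:
        series = pd.Series(dict(labelling))
    if series.index.duplicated().any():
        raise ValueError("duplicate cell ids in labelling")
    return series.astype(str)


def _align(a, b):
    a, b = _as_series(a), _as_series(b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("labellings share no cells")
    return a.loc[common], b.loc[common]


def nmi(a, b, average_method: str = "max") -> float:
    """Normalized mutual information between two labellings.

    Normalization is by the maximum of the two entropies by default
    ("min", "geometric" and "arithmetic" are accepted too).  Undefined —
    returned as NaN — when both labellings are a single cluster, where
    both entropies vanish.
    """
    a, b = _align(a, b)
    if a.nunique() == 1 and b.nunique() == 1:
        return float("nan")
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def ari(a, b) -> float:
    """Pair-counting adjusted Rand index; 1 iff the labellings agree."""
    a, b = _align(a, b)
    return float(adjusted_rand_score(a, b))


def _expression_matrix(norm: NormalizedMatrix, labels: pd.Series):
    col = {c: j for j, c in enumerate(norm.cell_ids)}
    missing = [c for c in labels.index if c not in col]
    if missing:
        raise ValueError(f"{len(missing)} labelled cells absent from the matrix")
    X = norm.values[:, [col[c] for c in labels.index]].T  # cells x genes
    return X


def silhouette(norm: NormalizedMatrix, labels) -> float:
    """Mean silhouette width on Euclidean expression space.

    Cells in singleton clusters score 0.  Undefined (NaN) when the
    labelling holds a single cluster.
    """
    labels = _as_series(labels)
    if labels.nunique() < 2:
        return float("nan")
    X = _expression_matrix(norm, labels)
    y = labels.to_numpy()
    counts = labels.value_counts()
    singleton = labels.map(counts).to_numpy() == 1
    scores = np.zeros(len(labels))
    if (~singleton).any():
        # sklearn requires >=2 clusters among the remaining cells
        rest_labels = y[~singleton]
        if np.unique(rest_labels).size >= 2:
            scores[~singleton] = silhouette_samples(X[~singleton], rest_labels)
    return float(scores.mean())


def neighborhood_purity(norm: NormalizedMatrix, labels, k_neighbors: int = 50) -> float:
    """Mean fraction of each cell's k nearest neighbours sharing its label."""
    labels = _as_series(labels)
    n = len(labels)
    if not 1 <= k_neighbors < n:
        raise ValueError("k_neighbors must satisfy 1 <= k < n_cells")
    X = _expression_matrix(norm, labels)
    y = labels.to_numpy()
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    same = y[idx[:, 1:]] == y[:, None]
    return float(same.mean())


def leaf_labelling_from_tables(tables, include_leftover: bool = True) -> pd.Series:
    """Reconstruct the leaf labelling from saved result tables.

    A leaf is a cluster that is nobody's parent; a cell's leaf is its
    label in the deepest resolution column of the samples table.
    Leftover leaves (labels ending in ".L") are dropped when
    ``include_leftover`` is false.
    """
    samples = tables.samples
    last = samples.columns[-1]
    series = pd.Series(
        samples[last].to_numpy(), index=samples["cell"].astype(str), name="cluster"
    )
    if not include_leftover:
        series = series[~series.str.endswith(".L")]
    return series
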