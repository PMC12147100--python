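"""Base clusterers and the ensemble runner.

Four built-in clusterers cover the methodological families commonly
combined in scRNA-seq ensembles: two community-detection variants on a
kNN graph (plain and shared-nearest-neighbour weighted), a
density-based clusterer on a PCA embedding of log2-CPM values, and a
hierarchical clusterer with silhouette-selected k.  Any callable
honouring the :class:`BaseClusterer` contract can be registered and
addressed by name, and externally computed partitions can be injected
from CSV, so the consensus layer stays method-agnostic.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from sklearn.cluster import HDBSCAN, AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix
from .preprocessing import NormalizedMatrix, log_normalize, to_log2_cpm

__all__ = [
    "BaseClusterer",
    "PartitionSet",
    "EnsembleError",
    "builtin_roster",
    "get_clusterer",
    "register_clusterer",
    "run_ensemble",
    "partition_clusterer",
    "load_partition_csv",
]


class EnsembleError(RuntimeError):
    """Fewer than two base clusterers produced a partition."""


@dataclass
class BaseClusterer:
    """A named clustering method with a declared input transform.

    ``fit(norm, seed)`` must return one label per cell of ``norm``
    (any hashable labels; names are opaque to the consensus layer).
    """

    name: str
    transform: str  # "lognorm" or "log2cpm"
    fit: Callable[[NormalizedMatrix, int], np.ndarray]


@dataclass
class PartitionSet:
    """One cell labelling per base clustering method over a common pool."""

    pool_cell_ids: list
    partitions: dict = field(default_factory=dict)  # method name -> label array

    @property
    def n_methods(self) -> int:
        return len(self.partitions)

    def add(self, name: str, labels) -> None:
        labels = np.asarray(labels)
        if labels.shape != (len(self.pool_cell_ids),):
            raise ValueError(
                f"partition {name!r} has {labels.shape} labels for "
                f"{len(self.pool_cell_ids)} cells"
            )
        self.partitions[name] = labels


# --------------------------------------------------------------------------
# shared numerical steps

def _embed(norm: NormalizedMatrix, seed: int, n_components: int = 50) -> np.ndarray:
    """PCA embedding of cells (cells x components), centred, deterministic."""
    X = norm.values.T  # cells x genes
    n_comp = min(n_components, X.shape[0] - 1, X.shape[1])
    n_comp = max(n_comp, 1)
    pca = PCA(n_components=n_comp, svd_solver="full" if min(X.shape) <= 2000 else "randomized",
              random_state=seed % (2**31))
    return pca.fit_transform(X)

def _knn_indices(emb: np.ndarray, n_neighbors: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    return idx[:, 1:]  # drop self

def _default_k(n_cells: int) -> int:
    return max(2, min(15, n_cells // 5))

def _knn_graph(emb: np.ndarray) -> igraph.Graph:
    idx = _knn_indices(emb, _default_k(emb.shape[0]))
    n = emb.shape[0]
    edges = {tuple(sorted((i, j))) for i in range(n) for j in idx[i]}
    return igraph.Graph(n=n, edges=sorted(edges), directed=False)

def _snn_graph(emb: np.ndarray, prune: float = 1 / 15) -> igraph.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    k = _default_k(emb.shape[0])
    idx = _knn_indices(emb, k)
    n = emb.shape[0]
    rows = np.repeat(np.arange(n), k)
    adj = csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    adj = adj.maximum(adj.T)  # symmetric neighbourhoods incl. both directions
    shared = (adj @ adj.T).tocoo()
    sizes = np.asarray(adj.sum(axis=1)).ravel()
    edges, weights = [], []
    for i, j, s in zip(shared.row, shared.col, shared.data):
        if i >= j:
            continue
        jac = s / (sizes[i] + sizes[j] - s)
        if jac >= prune:
            edges.append((int(i), int(j)))
            weights.append(float(jac))
    g = igraph.Graph(n=n, edges=edges, directed=False)
    g.es["weight"] = weights
    return g

def _leiden(graph: igraph.Graph, seed: int, resolution: float, weighted: bool) -> np.ndarray:
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=graph.es["weight"] if weighted and graph.ecount() else None,
        resolution_parameter=resolution,
        seed=seed % (2**31),
        n_iterations=2,
    )
    return np.asarray(part.membership)


# --------------------------------------------------------------------------
# the four built-in clusterers

def _fit_leiden_knn(norm: NormalizedMatrix, seed: int) -> np.ndarray:
    emb = _embed(norm, seed)
    return _leiden(_knn_graph(emb), seed, resolution=0.1, weighted=False)

def _fit_snn_leiden(norm: NormalizedMatrix, seed: int) -> np.ndarray:
    emb = _embed(norm, seed)
    return _leiden(_snn_graph(emb), seed, resolution=0.3, weighted=True)

def _fit_density(norm: NormalizedMatrix, seed: int) -> np.ndarray:
    emb = _embed(norm, seed)
    n = emb.shape[0]
    min_size = max(5, n // 100)
    labels = HDBSCAN(min_cluster_size=min_size, copy=True).fit_predict(emb)
    if (labels >= 0).sum() == 0:
        return np.zeros(n, dtype=int)
    # density clusterers leave low-density cells unlabelled; every cell must
    # carry a label, so noise points join the nearest cluster centroid
    if (labels < 0).any():
        centroids = np.vstack([emb[labels == c].mean(axis=0) for c in np.unique(labels[labels >= 0])])
        cluster_ids = np.unique(labels[labels >= 0])
        noise = np.where(labels < 0)[0]
        d = ((emb[noise, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = labels.copy()
        labels[noise] = cluster_ids[d.argmin(axis=1)]
    return labels

def _fit_hierarchical(norm: NormalizedMatrix, seed: int) -> np.ndarray:
    emb = _embed(norm, seed)
    n = emb.shape[0]
    best_labels, best_score = None, -np.inf
    for k in range(2, min(10, n - 1) + 1):
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(emb)
        score = silhouette_score(emb, labels)
        if score > best_score + 1e-12:
            best_labels, best_score = labels, score
    return best_labels


_BUILTINS = {
    "leiden": lambda: BaseClusterer("leiden", "lognorm", _fit_leiden_knn),
    "snn": lambda: BaseClusterer("snn", "lognorm", _fit_snn_leiden),
    "density": lambda: BaseClusterer("density", "log2cpm", _fit_density),
    "hier": lambda: BaseClusterer("hier", "lognorm", _fit_hierarchical),
}

_REGISTRY = dict(_BUILTINS)


def register_clusterer(name: str, factory: Callable[[], BaseClusterer]) -> None:
    """Register a clusterer factory addressable from configuration."""
    _REGISTRY[name] = factory


def get_clusterer(name: str) -> BaseClusterer:
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown clusterer {name!r}; registered: {sorted(_REGISTRY)}") from None


def builtin_roster() -> list:
    """The four built-in base clusterers, in stable order."""
    return [_BUILTINS[name]() for name in ("leiden", "snn", "density", "hier")]


def partition_clusterer(name: str, labels_by_cell: dict) -> BaseClusterer:
    """Wrap a precomputed labelling (cell id -> label) as a clusterer.

    Lets base clusterings computed elsewhere be injected into the
    ensemble; cells of the pool missing from the mapping raise.
    """

    def fit(norm: NormalizedMatrix, seed: int) -> np.ndarray:
        return np.asarray([labels_by_cell[c] for c in norm.cell_ids], dtype=object)

    return BaseClusterer(name, "lognorm", fit)


def load_partition_csv(path: str, name: str = None) -> BaseClusterer:
    """Load a two-column (cell_id,label) CSV as an injectable clusterer."""
    frame = pd.read_csv(path)
    cells, labels = frame.iloc[:, 0].astype(str), frame.iloc[:, 1]
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(path))[0]
    return partition_clusterer(name, dict(zip(cells, labels)))


def method_seed(seed: int, name: str) -> int:
    """Deterministic per-method seed: base seed + stable hash of the name."""
    return (int(seed) + zlib.crc32(name.encode())) % (2**31)


def run_ensemble(counts_pool: CountMatrix, hvg: list, roster: list, seed: int) -> PartitionSet:
    """Run every clusterer of the roster on the HVG-restricted pool.

    Each clusterer receives the pool under its declared transform
    (normalized on all genes, then restricted to the HVGs) and a
    deterministic per-method seed.  Clusterers that raise are logged and
    omitted; fewer than two surviving partitions is an
    :class:`EnsembleError` (the pool is then treated as unsplittable).
    """
    if len(roster) < 2:
        raise EnsembleError("at least two base clusterers are required")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        by_transform = {
            "lognorm": log_normalize(counts_pool).subset_genes(hvg),
            "log2cpm": to_log2_cpm(counts_pool).subset_genes(hvg),
        }
    ps = PartitionSet(pool_cell_ids=list(counts_pool.cell_ids))
    for clusterer in roster:
        norm = by_transform[clusterer.transform]
        try:
            labels = clusterer.fit(norm, method_seed(seed, clusterer.name))
            ps.add(clusterer.name, labels)
        except Exception as exc:  # noqa: BLE001 - failure contract: omit and warn
            warnings.warn(f"base clusterer {clusterer.name!r} failed: {exc}", stacklevel=2)
    if ps.n_methods < 2:
        raise EnsembleError(
            f"only {ps.n_methods} of {len(roster)} base clusterers completed"
        )
    return ps
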