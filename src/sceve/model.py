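"""The recursive ensemble-clustering model and its results object.

:class:`ScEve` is built from a :class:`~sceve.io.CountMatrix` plus an
:class:`EveConfig`; ``fit()`` runs the recursion — per pool: highly
variable gene selection, the base-clusterer ensemble, the
similarity-graph consensus, and the marker-based characterization
filter — and returns an :class:`EveResult` holding the multi-resolution
cluster tree, the per-cluster robustness values, the four output tables
and a structured per-recursion log.

Subdivision is only accepted when it is *more* robust than its parent:
a child cluster i of a cluster z is kept iff R_i > max(R_lim, R_z), so
effective thresholds rise monotonically from root to leaf.  The root is
labelled ``C``; robust children are ``<parent>.1, .2, ...`` in
descending size order and the leftover child is ``<parent>.L``.
"""

from __future__ import annotations

import zlib
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .base_clustering import EnsembleError, builtin_roster, get_clusterer, run_ensemble
from .characterization import characterize_split
from .consensus import consensus_step, majority, robustness_threshold
from .io import CountMatrix, ResultTables, write_result_tables
from .preprocessing import log_normalize, select_hvg

__all__ = ["EveConfig", "ClusterNode", "EveResult", "ScEve", "run_scEVE", "leaf_clusters"]


@dataclass
class EveConfig:
    """Tunable parameters of a clustering run.

    Defaults follow the algorithm's published operating point: 1000
    HVGs per recursion, similarity threshold 0.5 (clusters must share a
    majority of their cells), pools under 100 cells are not clustered,
    markers need a >4 log2 fold change and 10 of them characterize a
    cluster.
    """

    k_hvg: int = 1000
    s_lim: float = 0.5
    min_cells: int = 100
    min_log2fc: float = 4.0
    min_markers: int = 10
    alpha: float = 0.05
    roster: tuple = ("leiden", "snn", "density", "hier")
    seed: int = 0
    include_leftover_in_recursion: bool = True
    significance_filter: bool = True
    marker_pseudocount: float = 1.0

    def __post_init__(self):
        if not 0 < self.s_lim < 1:
            raise ValueError("s_lim must lie strictly in (0, 1)")
        if self.min_cells < 2:
            raise ValueError("min_cells must be >= 2")
        if self.k_hvg < 1 or self.min_markers < 0 or self.min_log2fc <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ClusterNode:
    """One node of the cluster tree."""

    label: str
    cells: frozenset
    robustness: float
    parent: str | None = None
    is_leftover: bool = False
    markers: list = field(default_factory=list)
    methods: list = field(default_factory=list)
    children: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def assign_labels(parent_label: str, children: list) -> list:
    """Name the characterized children of a node.

    Robust children become ``<parent>.1, .2, ...`` ordered by descending
    size (ties: lexicographically smallest member cell id); the leftover
    becomes ``<parent>.L``.  Returns (label, cluster) pairs.
    """
    robust = [c for c in children if not c.is_leftover]
    leftover = [c for c in children if c.is_leftover]
    robust.sort(key=lambda c: (-len(c.cells), min(c.cells)))
    labelled = [(f"{parent_label}.{i}", c) for i, c in enumerate(robust, start=1)]
    labelled += [(f"{parent_label}.L", c) for c in leftover]
    return labelled


class ScEve:
    """Recursive ensemble clustering of a single-cell count matrix.

    Parameters
    ----------
    counts : CountMatrix
        Genes x cells raw counts.
    config : EveConfig, optional
        Run parameters; defaults are the published operating point.
    roster : list of BaseClusterer, optional
        Overrides ``config.roster`` with concrete clusterer objects
        (e.g. injected external partitions).
    """

    def __init__(self, counts: CountMatrix, config: EveConfig = None, roster: list = None):
        self.counts = counts
        self.config = config if config is not None else EveConfig()
        self.roster = roster if roster is not None else [
            get_clusterer(name) for name in self.config.roster
        ]
        if len(self.roster) < 2:
            raise ValueError("at least two base clusterers are required")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: EveConfig = None, **kwargs) -> "ScEve":
        """Build from a genes x cells DataFrame (gene index, cell columns)."""
        counts = CountMatrix(frame.to_numpy(), list(frame.index), list(frame.columns))
        return cls(counts, config=config, **kwargs)

    # ----------------------------------------------------------------- fit

    def fit(self, seed: int = None) -> "EveResult":
        """Run the recursion and return the fitted result."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        all_cells = frozenset(self.counts.cell_ids)
        root = ClusterNode("C", all_cells, robustness=0.0)
        nodes = {"C": root}
        log = []
        queue = deque([root])
        while queue:
            node = queue.popleft()
            children = self._step(node, config, log)
            if children is None:
                continue
            for label, cc in assign_labels(node.label, children):
                child = ClusterNode(
                    label, frozenset(cc.cells), cc.robustness, parent=node.label,
                    is_leftover=cc.is_leftover, markers=cc.markers, methods=cc.methods,
                )
                nodes[label] = child
                node.children.append(label)
                if not cc.is_leftover or config.include_leftover_in_recursion:
                    queue.append(child)
        return EveResult(nodes, config, log, cell_ids=list(self.counts.cell_ids))

    def _step(self, node: ClusterNode, config: EveConfig, log: list):
        """One clustering recursion on a node's pool; None means leaf."""
        entry = {"pool": node.label, "n_cells": node.size}
        log.append(entry)
        if node.size < config.min_cells:
            entry["decision"] = "pool below min_cells"
            return None
        pool_cells = sorted(node.cells)
        pool_counts = self.counts.subset_cells(pool_cells)
        try:
            hvg = select_hvg(pool_counts, config.k_hvg)
        except ValueError as exc:
            entry["decision"] = f"no variable genes ({exc})"
            return None
        pool_seed = (config.seed + zlib.crc32(node.label.encode())) % (2**31)
        try:
            ps = run_ensemble(pool_counts, hvg, self.roster, pool_seed)
        except EnsembleError as exc:
            entry["decision"] = f"ensemble failed ({exc})"
            return None
        n_methods = ps.n_methods
        r_lim = robustness_threshold(config.s_lim, majority(n_methods), n_methods)
        threshold = max(r_lim, node.robustness)
        outcome = consensus_step(ps, config.s_lim, threshold, n_methods)
        entry.update(
            M=n_methods,
            r_lim=r_lim,
            threshold=threshold,
            component_robustness=[round(c.robustness, 4) for c in outcome.components],
            n_robust=len(outcome.robust_clusters),
        )
        if not outcome.robust_clusters:
            entry["decision"] = "no component above threshold"
            return None
        norm = log_normalize(pool_counts)
        children = characterize_split(
            norm, outcome,
            min_log2fc=config.min_log2fc, min_markers=config.min_markers,
            alpha=config.alpha, pseudocount=config.marker_pseudocount,
            significance_filter=config.significance_filter,
        )
        if children is None:
            entry["decision"] = "no characterized cluster (over-clustering guard)"
            return None
        # a single child equal to the pool would not subdivide anything
        if len(children) == 1 and children[0].cells == node.cells:
            entry["decision"] = "single child spans the pool"
            return None
        entry["decision"] = f"split into {len(children)} clusters"
        return children


class EveResult:
    """Fitted multi-resolution clustering: tree, tables, diagnostics."""

    def __init__(self, nodes: dict, config: EveConfig, log: list, cell_ids: list):
        self.nodes = nodes
        self.config = config
        self.log = log
        self.cell_ids = cell_ids
        self._tables = None

    # ------------------------------------------------------------- queries

    def leaf_clusters(self, include_leftover: bool = True) -> pd.Series:
        """Label each cell by its deepest node.

        With ``include_leftover=False`` cells whose leaf is a leftover
        cluster are omitted — the high-confidence-only protocol.
        """
        return leaf_clusters(self, include_leftover)

    def path(self, cell) -> list:
        """Root-to-leaf labels of one cell."""
        label, path = "C", ["C"]
        while True:
            nxt = None
            for child in self.nodes[label].children:
                if cell in self.nodes[child].cells:
                    nxt = child
                    break
            if nxt is None:
                return path
            path.append(nxt)
            label = nxt

    @property
    def max_depth(self) -> int:
        return max(label.count(".") for label in self.nodes)

    # -------------------------------------------------------------- tables

    @property
    def tables(self) -> ResultTables:
        if self._tables is None:
            self._tables = self._build_tables()
        return self._tables

    def _build_tables(self) -> ResultTables:
        order = sorted(self.nodes, key=lambda s: (s.count("."), s))
        meta = pd.DataFrame(
            {
                "cluster": order,
                "size": [self.nodes[x].size for x in order],
                "robustness": [float(self.nodes[x].robustness) for x in order],
                "parent": pd.array(
                    [self.nodes[x].parent if self.nodes[x].parent is not None else np.nan
                     for x in order],
                    dtype=object,
                ),
            }
        )
        depth = self.max_depth
        rows = []
        for cell in self.cell_ids:
            path = self.path(cell)
            padded = path + [path[-1]] * (depth + 1 - len(path))
            rows.append([cell] + padded)
        samples = pd.DataFrame(
            rows, columns=["cell"] + [f"resolution_{d}" for d in range(depth + 1)]
        )
        feat_rows = [
            {
                "cluster": x,
                "gene": m.gene,
                "log2_fc": m.log2_fc,
                "p_value": m.p_value,
                "p_adjusted": m.p_adjusted,
            }
            for x in order
            for m in self.nodes[x].markers
        ]
        features = pd.DataFrame(
            feat_rows, columns=["cluster", "gene", "log2_fc", "p_value", "p_adjusted"]
        )
        meth_rows = [
            {"cluster": x, "method": m} for x in order for m in self.nodes[x].methods
        ]
        methods = pd.DataFrame(meth_rows, columns=["cluster", "method"])
        return ResultTables(meta, samples, features, methods)

    def save(self, out_dir: str) -> dict:
        """Write the four result tables to ``out_dir`` as CSV."""
        return write_result_tables(self.tables, out_dir)

    # ------------------------------------------------------------- summary

    def summary(self) -> str:
        lines = [
            "Recursive ensemble clustering results",
            "=" * 58,
            f"cells: {len(self.cell_ids)}    clusters: {len(self.nodes)}"
            f"    max depth: {self.max_depth}",
            f"roster: {', '.join(self.config.roster)}    seed: {self.config.seed}",
            f"s_lim: {self.config.s_lim}    k_hvg: {self.config.k_hvg}"
            f"    min_cells: {self.config.min_cells}",
            "-" * 58,
            f"{'cluster':<14}{'size':>8}{'robustness':>12}  {'parent':<10}{'leaf':>5}",
        ]
        for label in sorted(self.nodes, key=lambda s: (s.count("."), s)):
            node = self.nodes[label]
            lines.append(
                f"{label:<14}{node.size:>8}{node.robustness:>12.4f}  "
                f"{node.parent or '-':<10}{'yes' if node.is_leaf else 'no':>5}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<EveResult: {len(self.cell_ids)} cells, {len(self.nodes)} clusters, "
            f"depth {self.max_depth}>"
        )


def leaf_clusters(result: EveResult, include_leftover: bool = True) -> pd.Series:
    """Deepest-node label per cell; optionally drop leftover-leaf cells."""
    labels = {}
    for cell in result.cell_ids:
        leaf = result.path(cell)[-1]
        if not include_leftover and result.nodes[leaf].is_leftover:
            continue
        labels[cell] = leaf
    return pd.Series(labels, name="cluster", dtype=object)


def run_scEVE(counts: CountMatrix, config: EveConfig = None) -> EveResult:
    """Convenience wrapper: build the model and fit it."""
    return ScEve(counts, config=config).fit()
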