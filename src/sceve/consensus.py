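"""Robust clusters from an ensemble of partitions.

Base clusters (one method's cluster) are vertices of a graph whose
edges carry the pairwise similarity

    S(x, y) = min(|x ∩ y| / |x|, |x ∩ y| / |y|),

the minimal proportion of cells the two clusters share (equivalently
the smaller of the two association-rule confidences conf(x→y) and
conf(y→x)).  Edges with S <= S_lim are dropped; each connected
component of the remaining graph yields a *robust cluster* — the cells
common to all its base clusters — whose robustness is the component's
weighted density

    R = (sum of retained edge similarities) / (M(M-1)/2),

where M is the number of clustering methods.  R is 1 exactly when all
M methods predict the same cluster.  Cells in no accepted robust
cluster form the *leftover* cluster, with robustness defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "BaseClusterVertex",
    "SimilarityEdge",
    "Component",
    "ConsensusOutcome",
    "RobustCluster",
    "pairwise_similarities",
    "build_graph",
    "components",
    "robustness_threshold",
    "majority",
    "consensus_step",
]


@dataclass(frozen=True)
class BaseClusterVertex:
    """One cluster predicted by one method."""

    method: str
    label: str
    cells: frozenset

    @property
    def key(self):
        return (self.method, self.label)

    def __post_init__(self):
        if not self.cells:
            raise ValueError("a base cluster cannot be empty")


@dataclass(frozen=True)
class SimilarityEdge:
    x: BaseClusterVertex
    y: BaseClusterVertex
    n_shared: int
    s: float


@dataclass
class Component:
    """A connected component of the strong-similarity graph."""

    vertices: list
    strong_edges: list
    core_cells: frozenset
    robustness: float

    @property
    def methods(self) -> list:
        return sorted({v.method for v in self.vertices})

    @property
    def sort_key(self):
        return (-self.robustness, -len(self.core_cells), min(v.key for v in self.vertices))


@dataclass
class RobustCluster:
    cells: frozenset
    robustness: float
    methods: list


@dataclass
class ConsensusOutcome:
    robust_clusters: list = field(default_factory=list)
    leftover_cells: frozenset = frozenset()
    leftover_robustness: float = 0.0  # by definition
    n_methods: int = 0
    components: list = field(default_factory=list)  # all components, diagnostics


def vertices_from_partitions(ps) -> list:
    """Base-cluster vertices of a :class:`~sceve.base_clustering.PartitionSet`."""
    vertices = []
    for method in sorted(ps.partitions):
        labels = ps.partitions[method]
        groups = {}
        for cell, lab in zip(ps.pool_cell_ids, labels):
            groups.setdefault(lab, set()).add(cell)
        for lab in sorted(groups, key=str):
            vertices.append(BaseClusterVertex(method, str(lab), frozenset(groups[lab])))
    return vertices


def pairwise_similarities(ps) -> list:
    """All non-zero cross-method similarity edges of a partition set."""
    if ps.n_methods < 2:
        raise ValueError("at least two partitions are required")
    vertices = vertices_from_partitions(ps)
    edges = []
    for i, x in enumerate(vertices):
        for y in vertices[i + 1:]:
            if x.method == y.method:
                continue
            n_shared = len(x.cells & y.cells)
            if n_shared == 0:
                continue
            s = min(n_shared / len(x.cells), n_shared / len(y.cells))
            edges.append(SimilarityEdge(x, y, n_shared, s))
    return edges


def build_graph(edges: list, s_lim: float, vertices: list = None) -> nx.Graph:
    """Graph over base clusters keeping only strong edges (s > s_lim, strict).

    Vertices not supplied explicitly are taken from the edge list;
    isolated vertices are retained either way.
    """
    if not 0 < s_lim < 1:
        raise ValueError("s_lim must lie strictly between 0 and 1")
    graph = nx.Graph()
    if vertices is None:
        vertices = [v for e in edges for v in (e.x, e.y)]
    for v in vertices:
        graph.add_node(v)
    for e in edges:
        if e.s > s_lim:
            graph.add_edge(e.x, e.y, s=e.s, n_shared=e.n_shared)
    return graph


def components(graph: nx.Graph, n_methods: int) -> list:
    """Connected components with their core cells and robustness.

    The core is the intersection of all member base clusters (empty if a
    component transitively contains two clusters of the same method);
    robustness is the sum of retained edge weights over M(M-1)/2.
    """
    if n_methods < 2:
        raise ValueError("n_methods must be >= 2")
    denom = n_methods * (n_methods - 1) / 2
    out = []
    for comp_nodes in nx.connected_components(graph):
        sub = graph.subgraph(comp_nodes)
        verts = sorted(comp_nodes, key=lambda v: v.key)
        core = frozenset.intersection(*(v.cells for v in verts))
        weight = sum(d["s"] for _, _, d in sub.edges(data=True))
        edges = [
            SimilarityEdge(u, v, d["n_shared"], d["s"])
            for u, v, d in sub.edges(data=True)
        ]
        out.append(Component(verts, edges, core, weight / denom))
    out.sort(key=lambda c: c.sort_key)
    return out


def majority(n_methods: int) -> int:
    """Smallest strict majority of M methods: floor(M/2) + 1."""
    return n_methods // 2 + 1


def robustness_threshold(s_lim: float, m: int = None, n_methods: int = 4) -> float:
    """Minimum expected robustness were m of M methods to agree at S_lim.

    R_lim = S_lim * m(m-1)/2 / (M(M-1)/2).  With the defaults
    (S_lim = 0.5, M = 4, m the strict majority 3) this is 0.25.
    """
    if n_methods < 2:
        raise ValueError("n_methods must be >= 2")
    if m is None:
        m = majority(n_methods)
    if not 2 <= m <= n_methods:
        raise ValueError(f"m must lie in [2, {n_methods}], got {m}")
    return s_lim * (m * (m - 1) / 2) / (n_methods * (n_methods - 1) / 2)


def consensus_step(ps, s_lim: float, r_threshold: float, n_methods: int = None) -> ConsensusOutcome:
    """One full consensus pass over a partition set.

    Components with robustness strictly above ``r_threshold`` and a
    non-empty core become robust clusters; should the cores of two
    accepted components overlap, the contested cells go to the component
    with higher robustness (ties: larger core, then lexicographically
    smallest member).  Everything else is the leftover cluster.
    """
    if n_methods is None:
        n_methods = ps.n_methods
    pool = frozenset(ps.pool_cell_ids)
    edges = pairwise_similarities(ps)
    graph = build_graph(edges, s_lim, vertices=vertices_from_partitions(ps))
    comps = components(graph, n_methods)

    accepted = [c for c in comps if c.robustness > r_threshold and c.core_cells]
    taken: set = set()
    robust = []
    for comp in accepted:  # comps already sorted by the tie-break key
        cells = frozenset(comp.core_cells - taken)
        if not cells:
            continue
        taken |= cells
        robust.append(RobustCluster(cells, comp.robustness, comp.methods))
    leftover = frozenset(pool - taken)
    return ConsensusOutcome(
        robust_clusters=robust,
        leftover_cells=leftover,
        n_methods=n_methods,
        components=comps,
    )
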