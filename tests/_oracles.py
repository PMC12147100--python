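"""Independent brute-force oracles used by the test suite.

Deliberately naive: cell-by-cell counting, union-find components and
all-pairs co-membership, with no code shared with the package paths
they check.
"""

from itertools import combinations

import numpy as np

from sceve.base_clustering import PartitionSet


def random_partition_set(rng: np.random.Generator, n_cells: int, n_methods: int) -> PartitionSet:
    cells = [f"c{i}" for i in range(n_cells)]
    ps = PartitionSet(pool_cell_ids=cells)
    for m in range(n_methods):
        k = int(rng.integers(1, 6))
        ps.add(f"m{m}", rng.integers(0, k, size=n_cells))
    return ps


def brute_similarities(ps: PartitionSet) -> dict:
    """((method,label),(method,label)) -> s, by per-cell counting."""
    clusters = {}
    for method, labels in ps.partitions.items():
        for cell, lab in zip(ps.pool_cell_ids, labels):
            clusters.setdefault((method, str(lab)), []).append(cell)
    out = {}
    for (kx, cx), (ky, cy) in combinations(sorted(clusters.items()), 2):
        if kx[0] == ky[0]:
            continue
        shared = 0
        for cell in cx:
            if cell in cy:
                shared += 1
        if shared:
            s = min(shared / len(cx), shared / len(cy))
            out[frozenset((kx, ky))] = s
    return out


def brute_components(vertex_keys, strong_pairs):
    """Connected components by union-find over vertex keys."""
    parent = {v: v for v in vertex_keys}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in strong_pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for v in vertex_keys:
        groups.setdefault(find(v), set()).add(v)
    return {frozenset(g) for g in groups.values()}


def brute_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from explicit pair counting over all cell pairs."""
    n = len(labels_a)
    a_pairs = b_pairs = both = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = labels_a[i] == labels_a[j]
            same_b = labels_b[i] == labels_b[j]
            a_pairs += same_a
            b_pairs += same_b
            both += same_a and same_b
    total = n * (n - 1) / 2
    expected = a_pairs * b_pairs / total
    maximum = (a_pairs + b_pairs) / 2
    if maximum == expected:
        return 1.0
    return (both - expected) / (maximum - expected)
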