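import warnings

import numpy as np
import pytest

from sceve.io import CountMatrix
from sceve.model import ClusterNode, EveConfig, EveResult, run_scEVE
from sceve.simulate import SynthSpec, generate

warnings.filterwarnings("ignore", message=".*zero total counts.*")


@pytest.fixture
def small_counts():
    """Deterministic 10-gene x 6-cell count matrix."""
    rng = np.random.default_rng(42)
    values = rng.poisson(4, size=(10, 6))
    return CountMatrix(values, [f"g{i}" for i in range(10)], [f"c{j}" for j in range(6)])


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Two strongly separated synthetic populations (k=2, defaults)."""
    return generate(SynthSpec(n_cells=400, n_clusters=2, n_genes=600, seed=21))


@pytest.fixture(scope="session")
def fitted_small():
    """A fitted three-population run reused by tree-level tests."""
    ds = generate(SynthSpec(n_cells=600, n_clusters=3, n_genes=800, seed=3))
    result = run_scEVE(ds.counts, EveConfig(k_hvg=500, min_cells=60, seed=3))
    return ds, result


def _node(nodes, label, cells, parent, robustness, leftover=False):
    nodes[label] = ClusterNode(
        label, frozenset(cells), robustness, parent=parent, is_leftover=leftover
    )
    if parent is not None:
        nodes[parent].children.append(label)


@pytest.fixture
def deep_tree_result():
    """A hand-built tree with robust and leftover branches.

    Topology: the root splits into three robust clusters and a leftover;
    the leftover yields one robust subcluster and a second leftover,
    which splits once more, ending in a terminal leftover.  Seven leaves:
    C.1, C.2, C.3, C.L.1, C.L.L.1, C.L.L.2, C.L.L.L.
    """
    cells = [f"c{i}" for i in range(100)]
    nodes = {"C": ClusterNode("C", frozenset(cells), 0.0)}
    _node(nodes, "C.1", cells[:30], "C", 0.9)
    _node(nodes, "C.2", cells[30:55], "C", 0.8)
    _node(nodes, "C.3", cells[55:70], "C", 0.7)
    _node(nodes, "C.L", cells[70:], "C", 0.0, leftover=True)
    _node(nodes, "C.L.1", cells[70:82], "C.L", 0.43)
    _node(nodes, "C.L.L", cells[82:], "C.L", 0.0, leftover=True)
    _node(nodes, "C.L.L.1", cells[82:90], "C.L.L", 0.5)
    _node(nodes, "C.L.L.2", cells[90:96], "C.L.L", 0.45)
    _node(nodes, "C.L.L.L", cells[96:], "C.L.L", 0.0, leftover=True)
    return EveResult(nodes, EveConfig(), log=[], cell_ids=cells)
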