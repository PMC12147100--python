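"""Ground-truth-labelled synthetic scRNA-seq count datasets.

Datasets are generated over a gamma-Poisson (negative binomial) count
model: a base gene-mean profile is drawn log-normally, each cluster's
profile perturbs it by multiplying a random subset of genes by
2^(+/-f), per-cell library sizes are log-normal, and counts follow
NB with var = mu + dispersion * mu^2.  Four design axes are exposed:
number of clusters, balanced vs geometrically imbalanced sizes,
and *related* (each cluster perturbs its predecessor, a chain) vs
*unrelated* (every cluster perturbs the base independently) cluster
transcriptomes — so rare and closely related cell populations can both
be emulated.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "SynthSpec",
    "SynthDataset",
    "balanced_sizes",
    "imbalanced_sizes",
    "perturb_profile",
    "generate",
    "write_dataset",
]


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset.

    Defaults emulate a UMI experiment with strongly distinct cell types:
    10% of genes differentially expressed per cluster at a 2^6 = 64-fold
    median effect (comfortably above the 16-fold marker definition, the
    scale of canonical cell-type markers), NB dispersion 0.25 and a
    log-normal library size around 7500 counts per cell.
    """

    n_cells: int = 2000
    n_clusters: int = 5
    balanced: bool = True
    related: bool = False
    n_genes: int = 2000
    de_fraction: float = 0.1
    fc_log2_mean: float = 6.0
    fc_log2_sd: float = 0.5
    dispersion: float = 0.25
    libsize_log_sd: float = 0.25
    mean_library_size: float = 7500.0
    profile_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0 < self.de_fraction < 1:
            raise ValueError("de_fraction must lie in (0, 1)")
        if self.de_fraction * self.n_genes < 1:
            raise ValueError("de_fraction * n_genes must be >= 1")
        if self.dispersion <= 0 or self.libsize_log_sd <= 0:
            raise ValueError("dispersion and libsize_log_sd must be positive")


@dataclass
class SynthDataset:
    counts: CountMatrix
    true_labels: pd.Series        # cell id -> cluster id ("c1", "c2", ...)
    profiles: np.ndarray          # clusters x genes mean profiles
    de_genes: list = field(default_factory=list)  # per-cluster perturbed gene sets
    spec: SynthSpec = None


def balanced_sizes(n_cells: int, n_clusters: int) -> list:
    """Equal sizes, remainder spread over the first clusters; sums to N."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    base, rem = divmod(n_cells, n_clusters)
    return [base + (1 if i < rem else 0) for i in range(n_clusters)]


def imbalanced_sizes(n_cells: int, n_clusters: int) -> list:
    """Geometric size ladder emulating rare populations.

    n_i = floor(N * 2^(-i) / (1 - 2^(-k))) for i = 1..k: normalized
    geometric weights, floored, with no redistribution of the remainder
    (the total may fall a few cells short of N).  For N=10000, k=5 this
    is [5161, 2580, 1290, 645, 322].
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    norm = 1.0 - 2.0 ** (-n_clusters)
    return [math.floor(n_cells * 2.0 ** (-i) / norm) for i in range(1, n_clusters + 1)]


def perturb_profile(mu: np.ndarray, spec: SynthSpec, stream: np.random.Generator):
    """Multiply a random subset of gene means by a random fold factor.

    ceil(de_fraction * n_genes) genes are chosen; each is scaled by
    2^(s*f) with f ~ Normal(fc_log2_mean, fc_log2_sd) and s a random
    sign.  Returns the new profile and the perturbed gene index set.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.ndim != 1 or (mu <= 0).any():
        raise ValueError("mu must be a strictly positive vector")
    n_de = math.ceil(spec.de_fraction * mu.size)
    chosen = stream.choice(mu.size, size=n_de, replace=False)
    f = stream.normal(spec.fc_log2_mean, spec.fc_log2_sd, size=n_de)
    sign = stream.choice([-1.0, 1.0], size=n_de)
    out = mu.copy()
    out[chosen] = out[chosen] * np.exp2(sign * np.abs(f))
    return out, frozenset(int(g) for g in chosen)


def generate(spec: SynthSpec) -> SynthDataset:
    """Draw one dataset under the spec; fixed seed gives identical output."""
    root = np.random.SeedSequence(spec.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(spec.n_clusters + 2)]
    base_stream, count_stream = streams[0], streams[1]
    cluster_streams = streams[2:]

    base = np.exp(base_stream.normal(0.0, spec.profile_log_sd, size=spec.n_genes))

    profiles, de_genes = [], []
    if spec.n_clusters == 1:
        profiles, de_genes = [base], [frozenset()]
    else:
        prev = base
        for i in range(spec.n_clusters):
            source = prev if spec.related else base
            mu, de = perturb_profile(source, spec, cluster_streams[i])
            profiles.append(mu)
            de_genes.append(de)
            prev = mu
    profiles = np.vstack(profiles)

    sizes = (
        balanced_sizes(spec.n_cells, spec.n_clusters)
        if spec.balanced
        else imbalanced_sizes(spec.n_cells, spec.n_clusters)
    )
    total = sum(sizes)
    labels = np.repeat([f"c{i + 1}" for i in range(spec.n_clusters)], sizes)

    libsizes = count_stream.lognormal(
        np.log(spec.mean_library_size), spec.libsize_log_sd, size=total
    )
    counts = np.empty((spec.n_genes, total), dtype=np.int64)
    start = 0
    for i, size in enumerate(sizes):
        props = profiles[i] / profiles[i].sum()
        mu = np.outer(props, libsizes[start:start + size])  # genes x cells
        shape = 1.0 / spec.dispersion
        lam = count_stream.gamma(shape, mu * spec.dispersion)
        counts[:, start:start + size] = count_stream.poisson(lam)
        start += size

    gene_ids = [f"g{j + 1}" for j in range(spec.n_genes)]
    cell_ids = [f"cell{j + 1}" for j in range(total)]
    matrix = CountMatrix(counts, gene_ids, cell_ids)
    truth = pd.Series(labels, index=cell_ids, name="cluster")
    return SynthDataset(matrix, truth, profiles, de_genes, spec)


def write_dataset(ds: SynthDataset, out_dir: str) -> dict:
    """Write counts as MTX with sidecars plus a labels CSV."""
    import scipy.io
    import scipy.sparse

    os.makedirs(out_dir, exist_ok=True)
    mtx = os.path.join(out_dir, "matrix.mtx")
    scipy.io.mmwrite(mtx, scipy.sparse.coo_matrix(ds.counts.values))
    feat = os.path.join(out_dir, "features.tsv")
    with open(feat, "w") as fh:
        fh.write("\n".join(ds.counts.gene_ids) + "\n")
    barc = os.path.join(out_dir, "barcodes.tsv")
    with open(barc, "w") as fh:
        fh.write("\n".join(ds.counts.cell_ids) + "\n")
    lab = os.path.join(out_dir, "labels.csv")
    ds.true_labels.rename_axis("cell").to_csv(lab)
    return {"matrix": mtx, "features": feat, "barcodes": barc, "labels": lab}
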