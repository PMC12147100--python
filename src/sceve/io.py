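"""Count-matrix input and tabular output.

The algorithm consumes a genes x cells matrix of non-negative integer
counts and emits four delimited tables describing the cluster tree:
``meta`` (label, size, robustness, parent), ``samples`` (one row per
cell, one column per resolution), ``features`` (marker genes per
cluster) and ``methods`` (contributing base clusterers per cluster).
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "ResultTables",
    "read_counts",
    "write_result_tables",
    "read_result_tables",
]


@dataclass
class CountMatrix:
    """A genes x cells matrix of non-negative integer counts.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_cells)
        Raw counts. Stored dense as int64.
    gene_ids : list of str
        Unique gene identifiers, one per row.
    cell_ids : list of str
        Unique cell identifiers, one per column.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)

    def __post_init__(self):
        values = self.values
        if scipy.sparse.issparse(values):
            values = values.toarray()
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        if np.issubdtype(values.dtype, np.floating):
            if not np.all(np.isfinite(values)):
                raise ValueError("count matrix contains non-finite entries")
            if not np.all(values == np.floor(values)):
                raise ValueError("count matrix contains non-integral entries")
        if values.size and values.min() < 0:
            raise ValueError("count matrix contains negative entries")
        self.values = values.astype(np.int64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell identifiers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cell_ids) -> "CountMatrix":
        """Restrict to the given cells, preserving their stated order."""
        index = {c: j for j, c in enumerate(self.cell_ids)}
        cols = [index[c] for c in cell_ids]
        return CountMatrix(self.values[:, cols], self.gene_ids, list(cell_ids))

    def subset_genes(self, gene_ids) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return CountMatrix(self.values[rows, :], list(gene_ids), self.cell_ids)


@dataclass
class ResultTables:
    """The four output tables of a clustering run."""

    meta: pd.DataFrame       # cluster, size, robustness, parent
    samples: pd.DataFrame    # cell + one label column per resolution
    features: pd.DataFrame   # cluster, gene, log2_fc, p_value, p_adjusted
    methods: pd.DataFrame    # cluster, method

    def validate(self) -> None:
        labels = set(self.meta["cluster"])
        sample_labels = set()
        for col in self.samples.columns:
            if col != "cell":
                sample_labels |= set(self.samples[col].dropna())
        if not sample_labels <= labels:
            raise ValueError("samples table references unknown clusters")
        rob = self.meta["robustness"].to_numpy(dtype=float)
        if rob.size and (rob.min() < 0 or rob.max() > 1):
            raise ValueError("robustness outside [0, 1]")
        if len(self.features) and not set(self.features["cluster"]) <= labels:
            raise ValueError("features table references unknown clusters")


def _find_sidecar(dirname: str, names) -> str | None:
    for name in names:
        for suffix in ("", ".gz"):
            cand = os.path.join(dirname, name + suffix)
            if os.path.exists(cand):
                return cand
    return None


def _read_id_column(path: str, column: int = 0) -> list:
    opener = gzip.open if path.endswith(".gz") else open
    ids = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[column])
    return ids


def _read_mtx(path: str) -> CountMatrix:
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:  # scipy raises assorted types on malformed input
        raise ValueError(f"failed to parse Matrix Market file {path}: {exc}") from exc
    dirname = os.path.dirname(os.path.abspath(path))
    feat_path = _find_sidecar(dirname, ("features.tsv", "genes.tsv", "features.txt", "genes.txt"))
    bc_path = _find_sidecar(dirname, ("barcodes.tsv", "barcodes.txt"))
    if feat_path is None or bc_path is None:
        raise ValueError(
            f"MTX sidecar files (features/genes and barcodes) not found next to {path}"
        )
    genes = _read_id_column(feat_path, 0)
    cells = _read_id_column(bc_path, 0)
    dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
    if dense.shape == (len(genes), len(cells)):
        pass
    elif dense.shape == (len(cells), len(genes)):
        dense = dense.T
    else:
        raise ValueError(
            f"matrix shape {dense.shape} matches neither ({len(genes)} genes, "
            f"{len(cells)} cells) nor its transpose"
        )
    return CountMatrix(dense, genes, cells)


def _read_csv(path: str, cells_in_rows: bool = False) -> CountMatrix:
    try:
        frame = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise ValueError(f"failed to parse CSV file {path}: {exc}") from exc
    if cells_in_rows:
        frame = frame.T
    return CountMatrix(frame.to_numpy(), list(frame.index), list(frame.columns))


def read_counts(path: str, format: str = None, cells_in_rows: bool = False) -> CountMatrix:
    """Read a count matrix from disk, normalized to genes x cells.

    Parameters
    ----------
    path : str
        Path to a ``.mtx`` triplet file (with ``features.tsv``/``genes.tsv``
        and ``barcodes.tsv`` sidecars next to it, optionally gzipped) or a
        dense CSV with gene rows and a header of cell ids.
    format : {"mtx", "csv"}, optional
        Inferred from the file extension when omitted.
    cells_in_rows : bool
        For CSV only: set when the file stores cells in rows.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = "mtx" if ext in ("mtx", "mm") else "csv"
    if format == "mtx":
        return _read_mtx(path)
    if format == "csv":
        return _read_csv(path, cells_in_rows=cells_in_rows)
    raise ValueError(f"unknown format {format!r} (expected 'mtx' or 'csv')")


_TABLE_FILES = {
    "meta": "meta.csv",
    "samples": "samples.csv",
    "features": "features.csv",
    "methods": "methods.csv",
}


def write_result_tables(tables: ResultTables, out_dir: str) -> dict:
    """Write the four result tables as CSV; returns name -> path.

    Comma-delimited, UTF-8, '.' decimal, no index column, so that
    ``read_result_tables`` reproduces the tables exactly.
    """
    tables.validate()
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, fname in _TABLE_FILES.items():
        path = os.path.join(out_dir, fname)
        getattr(tables, name).to_csv(path, index=False)
        paths[name] = path
    return paths


def read_result_tables(out_dir: str) -> ResultTables:
    """Reload tables written by :func:`write_result_tables`."""
    frames = {}
    for name, fname in _TABLE_FILES.items():
        path = os.path.join(out_dir, fname)
        frames[name] = pd.read_csv(path)
    # all-NaN object columns (e.g. parent of a root-only meta) read back as float
    meta = frames["meta"]
    if "parent" in meta and meta["parent"].isna().all():
        frames["meta"]["parent"] = meta["parent"].astype(object)
    return ResultTables(**frames)
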