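"""Expression-matrix IO, normalization, gene selection and the KNN cell graph.

The cell graph is the topological input of the autoencoder: each cell is
connected to its K nearest neighbours in expression space (default K=35) and
the directed KNN relation is symmetrized into a binary adjacency matrix with
zero diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances

__all__ = [
    "ExpressionMatrix",
    "CellGraph",
    "read_matrix",
    "write_matrix",
    "normalize",
    "select_genes",
    "build_knn_graph",
    "write_adjacency",
]

DEFAULT_K = 35


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix does not parse or validate."""


@dataclass
class ExpressionMatrix:
    """A cells × genes matrix with identifiers.

    ``values`` holds raw counts (``is_normalized=False``) or normalized,
    possibly log-transformed expression (``is_normalized=True``). Cells are
    always rows.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise MatrixFormatError(
                f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != g:
            raise MatrixFormatError(
                f"{len(self.gene_ids)} gene ids for {g} columns")
        for kind, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise MatrixFormatError(f"duplicate {kind} ids: {dupes[:5]}")
        if np.any(self.values < 0):
            raise MatrixFormatError("negative entries in expression matrix")
        if not self.is_normalized and not np.allclose(
                self.values, np.round(self.values)):
            raise MatrixFormatError("raw counts must be integers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class CellGraph:
    """Binary symmetric KNN adjacency over cells, zero diagonal."""

    adjacency: np.ndarray
    k_used: int
    metric_name: str = "euclidean"

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = A.astype(np.int8)

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_cells.txt"), Path(f"{stem}_genes.txt")


def read_matrix(path: str | Path, format: str | None = None,
                transposed: bool = False,
                is_normalized: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from ``mtx`` (with id sidecars), CSV or TSV.

    ``mtx`` expects ``<stem>_cells.txt`` and ``<stem>_genes.txt`` next to the
    matrix file, one id per line. Dense text formats use the first row as gene
    ids and the first column as cell ids. ``transposed=True`` declares the
    file is genes × cells and flips it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(
        path.suffix.lower())
    if fmt not in {"mtx", "csv", "tsv"}:
        raise MatrixFormatError(f"unknown matrix format for {path}")

    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError with line info
            raise MatrixFormatError(f"failed to parse {path}: {exc}") from exc
        values = np.asarray(mat.toarray() if sp.issparse(mat) else mat,
                            dtype=float)
        rows_f, cols_f = _sidecar_paths(path)
        if not rows_f.exists() or not cols_f.exists():
            raise MatrixFormatError(
                f"mtx requires id sidecars {rows_f.name} and {cols_f.name}")
        cell_ids = rows_f.read_text().split()
        gene_ids = cols_f.read_text().split()
    else:
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise MatrixFormatError(f"failed to parse {path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        cell_ids = [str(i) for i in df.index]
        gene_ids = [str(c) for c in df.columns]

    if transposed:
        values = values.T
        cell_ids, gene_ids = gene_ids, cell_ids
    return ExpressionMatrix(values, cell_ids, gene_ids,
                            is_normalized=is_normalized)


def write_matrix(m: ExpressionMatrix, path: str | Path,
                 format: str | None = None) -> None:
    """Write to ``mtx`` (+ id sidecars), CSV or TSV; inverse of read_matrix."""
    path = Path(path)
    fmt = format or {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(
        path.suffix.lower())
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), sp.csr_matrix(m.values))
        rows_f, cols_f = _sidecar_paths(path)
        rows_f.write_text("\n".join(m.cell_ids) + "\n")
        cols_f.write_text("\n".join(m.gene_ids) + "\n")
    elif fmt in {"csv", "tsv"}:
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(m.values, index=m.cell_ids,
                     columns=m.gene_ids).to_csv(path, sep=sep)
    else:
        raise MatrixFormatError(f"unknown matrix format for {path}")


# ---------------------------------------------------------------------------
# Normalization and gene selection
# ---------------------------------------------------------------------------

def normalize(m: ExpressionMatrix, target_sum: float = 1e4,
              log_transform: bool = True) -> ExpressionMatrix:
    """Library-size normalization to ``target_sum`` per cell, then log1p.

    This is the variance-stabilizing substitute this package uses in place of
    model-based normalizations: each cell's counts are scaled so they total
    ``target_sum``, optionally followed by ``log(1+x)``.
    """
    if m.is_normalized:
        raise ValueError("matrix is already normalized")
    totals = m.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = [m.cell_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"cells with zero total counts: {bad[:10]}")
    scaled = m.values * (target_sum / totals)[:, None]
    if log_transform:
        scaled = np.log1p(scaled)
    return ExpressionMatrix(scaled, list(m.cell_ids), list(m.gene_ids),
                            is_normalized=True)


def select_genes(m: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Keep the ``n_top`` highest-variance genes (cell order preserved)."""
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > m.n_genes:
        raise ValueError(f"n_top={n_top} exceeds n_genes={m.n_genes}")
    var = m.values.var(axis=0)
    order = np.argsort(-var, kind="stable")[:n_top]
    return ExpressionMatrix(m.values[:, order],
                            list(m.cell_ids),
                            [m.gene_ids[i] for i in order],
                            is_normalized=m.is_normalized)


# ---------------------------------------------------------------------------
# KNN graph
# ---------------------------------------------------------------------------

def _knn_adjacency(x: np.ndarray, k: int, metric: str = "euclidean",
                   symmetrize: str = "or") -> np.ndarray:
    """Binary adjacency from the K nearest neighbours of each row of ``x``.

    Ties in distance break by ascending row index (stable sort), so the graph
    is deterministic. ``symmetrize``: ``or`` (union of directed edges, the
    default), ``and`` (intersection), ``none`` (directed, then still returned
    as the asymmetric 0/1 matrix).
    """
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = pairwise_distances(x, metric=metric)
    np.fill_diagonal(d, np.inf)  # exclude self
    nbrs = np.argsort(d, axis=1, kind="stable")[:, :k]
    directed = np.zeros((n, n), dtype=np.int8)
    np.put_along_axis(directed, nbrs, 1, axis=1)
    if symmetrize == "or":
        adj = np.maximum(directed, directed.T)
    elif symmetrize == "and":
        adj = np.minimum(directed, directed.T)
    elif symmetrize == "none":
        adj = directed
    else:
        raise ValueError(f"unknown symmetrize mode {symmetrize!r}")
    np.fill_diagonal(adj, 0)
    return adj


def build_knn_graph(m: ExpressionMatrix, k: int = DEFAULT_K,
                    metric: str = "euclidean", symmetrize: str = "or",
                    pca_dims: int | None = None) -> CellGraph:
    """Build the binary KNN cell graph on the (normalized) expression matrix.

    With the default OR symmetrization every node keeps degree >= k. An
    optional PCA projection (``pca_dims``) can be applied before the
    neighbour search for large gene panels.
    """
    if not m.is_normalized:
        warnings.warn("building KNN graph on raw counts; normalize() first "
                      "for distance stability", stacklevel=2)
    x = m.values
    if pca_dims is not None and pca_dims < min(x.shape):
        x = PCA(n_components=pca_dims, random_state=0).fit_transform(x)
    if symmetrize == "none":
        # directed variant bypasses the CellGraph symmetry invariant
        raise ValueError("CellGraph requires a symmetrized graph; use "
                         "_knn_adjacency for the directed relation")
    adj = _knn_adjacency(x, k, metric=metric, symmetrize=symmetrize)
    return CellGraph(adjacency=adj, k_used=k, metric_name=metric)


def write_adjacency(g: CellGraph, cell_ids: list[str], path: str | Path,
                    format: str = "edgelist") -> None:
    """Export adjacency as an edge-list TSV (id pairs, i<j) or MatrixMarket."""
    path = Path(path)
    if format == "edgelist":
        ii, jj = np.nonzero(np.triu(g.adjacency, k=1))
        with open(path, "w") as fh:
            for i, j in zip(ii, jj):
                fh.write(f"{cell_ids[i]}\t{cell_ids[j]}\n")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(g.adjacency))
    else:
        raise ValueError(f"unknown adjacency format {format!r}")
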