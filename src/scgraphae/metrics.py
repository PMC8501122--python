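"""Evaluation metrics: NMI for clusterings, Kendall correlation for
orderings, Louvain clustering of embeddings, and a graph pseudotime utility.

NMI here normalizes mutual information by the *arithmetic mean* of the two
partition entropies (natural log). The Kendall coefficient defaults to the
tau-a convention with tied pairs counted as discordant:

    tau = 2 (N_concordant - N_discordant) / (n (n - 1)),

where every pair that is not strictly concordant is discordant; a tau-b
variant (delegating to scipy) is available for cross-checks against standard
libraries.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy import sparse as sp

from .io_preprocess import _knn_adjacency

__all__ = ["nmi", "kendall_tau", "louvain_on_embedding", "graph_pseudotime"]


def _contingency(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    ui, uinv = np.unique(u, return_inverse=True)
    vi, vinv = np.unique(v, return_inverse=True)
    C = np.zeros((ui.size, vi.size), dtype=np.int64)
    np.add.at(C, (uinv, vinv), 1)
    return C


def nmi(labels_true, labels_pred) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Symmetric and invariant to label permutation. Two trivial single-cluster
    partitions are identical, so their NMI is defined as 1.
    """
    u = np.asarray(labels_true).ravel()
    v = np.asarray(labels_pred).ravel()
    if u.size != v.size:
        raise ValueError(f"length mismatch: {u.size} vs {v.size}")
    if u.size == 0:
        raise ValueError("empty partitions")
    n = u.size
    C = _contingency(u, v)
    pu = C.sum(axis=1) / n
    pv = C.sum(axis=0) / n
    hu = -np.sum(pu * np.log(pu))
    hv = -np.sum(pv * np.log(pv))
    if hu == 0.0 and hv == 0.0:
        return 1.0
    nz = C > 0
    pij = C[nz] / n
    outer = np.outer(pu, pv)[nz]
    mi = float(np.sum(pij * np.log(pij / outer)))
    denom = 0.5 * (hu + hv)
    return float(max(0.0, mi / denom))


def kendall_tau(x, y, variant: str = "a") -> float:
    """Kendall correlation between two orderings.

    ``variant='a'``: pairwise concordance statistic with ties counted as
    discordant (so a constant vector scores -1 against anything).
    ``variant='b'``: the standard tie-corrected coefficient via scipy.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if variant == "b":
        from scipy.stats import kendalltau

        return float(kendalltau(x, y).statistic)
    if variant != "a":
        raise ValueError("variant must be 'a' or 'b'")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    conc = int(np.count_nonzero((sx * sy)[np.triu_indices(n, k=1)] > 0))
    npairs = n * (n - 1) // 2
    disc = npairs - conc
    return 2.0 * (conc - disc) / (n * (n - 1))


def louvain_on_embedding(h, k: int = 15, seed: int = 0,
                         resolution: float = 1.0) -> np.ndarray:
    """Louvain community labels on a KNN graph of the embedding."""
    from .deep_cluster import _louvain_labels
    from .graph_autoencoder import Embedding

    hv = h.h if isinstance(h, Embedding) else np.asarray(h, dtype=float)
    if not np.isfinite(hv).all():
        raise ValueError("embedding contains non-finite entries")
    if k >= hv.shape[0]:
        raise ValueError("k must be smaller than the number of cells")
    adj = _knn_adjacency(hv, k, metric="euclidean", symmetrize="or")
    return _louvain_labels(adj, seed=seed, resolution=resolution)


def graph_pseudotime(h, root: int = 0, k: int = 15) -> np.ndarray:
    """Pseudotime as shortest-path distance from ``root`` in the KNN graph.

    Edges are weighted by euclidean distance in the embedding. The KNN graph
    must be connected; otherwise the components are reported in the error.
    """
    from .graph_autoencoder import Embedding

    hv = h.h if isinstance(h, Embedding) else np.asarray(h, dtype=float)
    n = hv.shape[0]
    if not 0 <= root < n:
        raise ValueError(f"root {root} out of range for {n} cells")
    adj = _knn_adjacency(hv, min(k, n - 1), metric="euclidean",
                         symmetrize="or")
    ii, jj = np.nonzero(adj)
    # floor at a tiny positive weight: duplicate points would otherwise store
    # an explicit zero, which csgraph treats as a missing edge
    w = np.maximum(np.linalg.norm(hv[ii] - hv[jj], axis=1), 1e-12)
    W = sp.csr_matrix((w, (ii, jj)), shape=(n, n))
    n_comp, comp = connected_components(W, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise ValueError(f"KNN graph is disconnected: {n_comp} components "
                         f"with sizes {sizes.tolist()}")
    dist = dijkstra(W, directed=False, indices=root)
    return dist
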