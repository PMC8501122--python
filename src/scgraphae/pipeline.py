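"""End-to-end convenience pipeline: counts -> embedding (+ cluster labels).

Thin glue over the library modules, shared by the command-line interface and
the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import deep_cluster, graph_autoencoder, io_preprocess

__all__ = ["PipelineResult", "embed_counts"]


@dataclass
class PipelineResult:
    matrix: io_preprocess.ExpressionMatrix      # normalized, HVG-selected
    graph: io_preprocess.CellGraph
    params: graph_autoencoder.ModelParams
    embedding: graph_autoencoder.Embedding
    pretrain_history: list
    cluster_state: deep_cluster.ClusterState | None = None
    alter_history: list = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray | None:
        return None if self.cluster_state is None else \
            self.cluster_state.labels


def embed_counts(counts: io_preprocess.ExpressionMatrix,
                 config: graph_autoencoder.ModelConfig | None = None,
                 knn_k: int = io_preprocess.DEFAULT_K,
                 n_top_genes: int | None = None,
                 target_sum: float = 1e4,
                 pca_dims: int | None = None,
                 pretrain_only: bool = False) -> PipelineResult:
    """Normalize, select genes, build the cell graph, pretrain, alter-train.

    ``counts`` may already be normalized (``is_normalized=True``), in which
    case normalization is skipped. ``n_top_genes`` optionally restricts to
    the highest-variance genes before graph construction and training.
    By default the neighbour search runs directly on the normalized matrix;
    ``pca_dims`` switches it to a PCA projection, which denoises cell
    distances when dropout is heavy at the cost of deviating from the plain
    expression-space graph.
    """
    config = config or graph_autoencoder.ModelConfig()
    m = counts if counts.is_normalized else io_preprocess.normalize(
        counts, target_sum=target_sum)
    if n_top_genes is not None and n_top_genes < m.n_genes:
        m = io_preprocess.select_genes(m, n_top_genes)
    graph = io_preprocess.build_knn_graph(m, k=min(knn_k, m.n_cells - 1),
                                          pca_dims=pca_dims)
    X = m.values
    A = graph.adjacency.astype(float)
    params, history = graph_autoencoder.pretrain(X, A, config)
    state = None
    alter_history: list = []
    if not pretrain_only and config.alter_iterations > 0:
        params, state, alter_history = deep_cluster.alter_train(
            X, A, params, config)
    emb = graph_autoencoder.encode(X, A, params, config)
    return PipelineResult(matrix=m, graph=graph, params=params,
                          embedding=emb, pretrain_history=history,
                          cluster_state=state, alter_history=alter_history)
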