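"""Alternating deep-clustering refinement of the autoencoder embedding.

After pretraining, a second "alter-training" stage jointly refines the
embedding and a set of cluster centroids ``mu``:

* soft assignment ``Q``: Student-t kernel between embeddings and centroids,
  ``q_ij = (1 + ||h_i - mu_j||^2)^-1`` normalized over clusters;
* target distribution ``P``: squared/frequency-renormalized sharpening of
  ``Q`` (the DEC construction);
* clustering loss ``L_c = KL(P || Q)``;
* total loss ``L = L_r + gamma * L_c``.

Each outer iteration freezes ``P``, takes gradient epochs on the network
parameters minimizing ``L`` with centroids fixed, then updates the centroids
by gradient descent on ``L_c`` with the network fixed. Initial centroids come
from Louvain communities on a KNN graph of the pretrained embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Tensor
from .graph_autoencoder import (Embedding, ModelConfig, ModelParams,
                                TrainingDivergedError, _attention_mask,
                                _loss_graph)
from .io_preprocess import _knn_adjacency

__all__ = [
    "ClusterState",
    "init_centroids",
    "soft_assignment",
    "target_distribution",
    "clustering_loss",
    "assign_labels",
    "alter_train",
]


@dataclass
class ClusterState:
    """Centroids, soft/target assignments and hard labels."""

    centroids: np.ndarray   # (k, latent_dim)
    Q: np.ndarray           # (n, k) row-stochastic
    P: np.ndarray           # (n, k) row-stochastic
    labels: np.ndarray      # (n,) argmax of Q

    def __post_init__(self) -> None:
        for name, M in (("Q", self.Q), ("P", self.P)):
            if np.any(M < 0) or not np.allclose(M.sum(axis=1), 1.0,
                                                atol=1e-8):
                raise ValueError(f"{name} must be row-stochastic")
        if not np.array_equal(self.labels, np.argmax(self.Q, axis=1)):
            raise ValueError("labels must be argmax of Q")

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


def _louvain_labels(adj: np.ndarray, seed: int,
                    resolution: float = 1.0) -> np.ndarray:
    """Louvain communities of a binary adjacency, as an integer label vector."""
    import networkx as nx

    G = nx.from_numpy_array(adj.astype(float))
    comms = nx.community.louvain_communities(G, seed=seed,
                                             resolution=resolution)
    labels = np.empty(adj.shape[0], dtype=int)
    # stable community ids: order by smallest member index
    for ci, comm in enumerate(sorted(comms, key=min)):
        labels[list(comm)] = ci
    return labels


def init_centroids(h: Embedding | np.ndarray, k_hint: int | None = None,
                   resolution: float = 1.0, knn_k: int = 15,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Louvain clustering of the embedding; centroids are community means.

    The number of clusters emerges from Louvain modularity optimization on a
    KNN graph of the embedding (``knn_k`` neighbours, euclidean). ``k_hint``
    only validates the outcome (warning on mismatch).
    """
    hv = h.h if isinstance(h, Embedding) else np.asarray(h, dtype=float)
    if not np.isfinite(hv).all():
        raise ValueError("embedding contains non-finite entries")
    n = hv.shape[0]
    if np.allclose(hv, hv[0]):
        warnings.warn("all embeddings identical; single community",
                      stacklevel=2)
        return np.zeros(n, dtype=int), hv[:1].copy()
    k = min(knn_k, n - 1)
    adj = _knn_adjacency(hv, k, metric="euclidean", symmetrize="or")
    labels = _louvain_labels(adj, seed=seed, resolution=resolution)
    n_comm = labels.max() + 1
    if n_comm == 1:
        warnings.warn("Louvain found a single community; alter-training "
                      "degenerates to continued pretraining", stacklevel=2)
    if k_hint is not None and n_comm != k_hint:
        warnings.warn(f"Louvain found {n_comm} communities, expected "
                      f"{k_hint}", stacklevel=2)
    centroids = np.stack([hv[labels == j].mean(axis=0)
                          for j in range(n_comm)])
    return labels, centroids


def soft_assignment(h: Embedding | np.ndarray,
                    centroids: np.ndarray) -> np.ndarray:
    """Student-t soft assignment of each cell to each centroid (1 dof)."""
    hv = h.h if isinstance(h, Embedding) else np.asarray(h, dtype=float)
    mu = np.asarray(centroids, dtype=float)
    if mu.ndim != 2 or mu.shape[0] == 0:
        raise ValueError("centroids must be a non-empty (k, d) array")
    if mu.shape[1] != hv.shape[1]:
        raise ValueError("centroid dimension does not match embedding")
    d2 = ((hv[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    kernel = 1.0 / (1.0 + d2)
    return kernel / kernel.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened DEC target ``p_ij ∝ q_ij^2 / f_j`` with ``f_j = Σ_i q_ij``."""
    Q = np.asarray(Q, dtype=float)
    f = Q.sum(axis=0)
    empty = np.flatnonzero(f == 0)
    if empty.size:
        raise ValueError(f"empty cluster column(s) in Q: {empty.tolist()}")
    W = Q ** 2 / f
    return W / W.sum(axis=1, keepdims=True)


def clustering_loss(P: np.ndarray, Q: np.ndarray) -> float:
    """KL divergence ``KL(P || Q) = Σ_ij p_ij log(p_ij / q_ij)`` (nats)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    support = P > 0
    if np.any(Q[support] == 0):
        raise ValueError("KL(P||Q) infinite: q_ij = 0 where p_ij > 0")
    return float(np.sum(P[support] * np.log(P[support] / Q[support])))


def assign_labels(Q: np.ndarray) -> np.ndarray:
    """Hard labels: argmax of each row of Q; ties go to the lowest index."""
    return np.argmax(np.asarray(Q), axis=1)


# ---------------------------------------------------------------------------
# Alternating optimization
# ---------------------------------------------------------------------------

def _soft_assignment_graph(h: Tensor, mu: Tensor) -> Tensor:
    """Autodiff Student-t soft assignment (differentiable in h and mu)."""
    h2 = h.square().sum(axis=1, keepdims=True)            # (n, 1)
    m2 = mu.square().sum(axis=1, keepdims=True).T          # (1, k)
    d2 = h2 + m2 - (h @ mu.T) * 2.0
    kernel = (d2 + 1.0).reciprocal()
    return kernel * kernel.sum(axis=1, keepdims=True).reciprocal()


def _kl_graph(P: np.ndarray, Q: Tensor, reduction: str) -> Tensor:
    const = float(np.sum(P[P > 0] * np.log(P[P > 0])))
    kl = Tensor(const) - (Tensor(P) * Q.log()).sum()
    if reduction == "mean":
        kl = kl * (1.0 / P.shape[0])
    return kl


def alter_train(X: np.ndarray, A: np.ndarray, params: ModelParams,
                config: ModelConfig | None = None
                ) -> tuple[ModelParams, ClusterState, list[dict]]:
    """Stage two: alternate network updates on ``L = L_r + γ·L_c`` with
    centroid updates on ``L_c``.

    Per outer iteration: recompute ``Q`` and freeze the target ``P``; run
    ``inner_epochs`` Adam epochs on the network (centroids fixed); then
    either take ``centroid_steps`` Adam steps on the centroids minimizing
    ``L_c`` (``centroid_update='sgd'``, the default) or re-run Louvain on the
    current embedding (``'relouvain'``). Stops early when fewer than
    ``label_change_tol`` of hard labels change between outer iterations.
    Empty clusters (no cell assigned) are dropped with a warning.

    Returns updated parameters, the final :class:`ClusterState`, and a
    history of per-iteration loss components.
    """
    cfg = config or params.config
    X = np.asarray(X, dtype=cfg.dtype)
    A = np.asarray(A, dtype=cfg.dtype)
    mask = _attention_mask(A)
    xt, at = Tensor(X), Tensor(A)

    # Freeze an affine standardization of the latent space (center, scalar
    # std) computed on the pretrained embedding. The Student-t kernel has a
    # fixed bandwidth of 1, so soft assignments are only informative when
    # cluster separations are O(1); the pretrained latent scale is arbitrary
    # (the decoders absorb any rescaling), and this pins it down. The map is
    # a similarity transform, so neighbourhoods and Louvain communities are
    # unchanged.
    h0 = _forward_h(xt, mask, params, cfg)
    center = h0.mean(axis=0)
    scale = float((h0 - center).std()) or 1.0
    std = lambda h: (h - center) / scale  # noqa: E731

    labels, centroids = init_centroids(
        std(h0), knn_k=cfg.cluster_knn_k, resolution=cfg.cluster_resolution,
        seed=cfg.seed)
    mu = Tensor(centroids.astype(cfg.dtype), requires_grad=True)

    # refinement uses a finer step than pretraining: fresh Adam state takes
    # near-lr-sized first steps, which at the pretraining rate destroy the
    # cluster structure the stage is meant to sharpen
    alter_lr = (cfg.alter_learning_rate if cfg.alter_learning_rate is not None
                else cfg.learning_rate / 10.0)
    opt_net = Adam(params.trainable(), lr=alter_lr)
    opt_mu = Adam([mu], lr=alter_lr)
    prev_labels = labels
    history: list[dict] = []

    c_t = Tensor(-center.astype(cfg.dtype))
    inv_s = 1.0 / scale

    for it in range(cfg.alter_iterations):
        # freeze the target distribution for this outer iteration
        h_now = std(_forward_h(xt, mask, params, cfg))
        Q = soft_assignment(h_now, mu.data)
        Q, mu2 = _drop_empty(Q, mu, cfg)
        if mu2 is not mu:
            mu = mu2
            opt_mu = Adam([mu], lr=alter_lr)
        P = target_distribution(Q)

        # step 1: network updates, centroids fixed
        lr_val = lc_val = np.nan
        for _ in range(cfg.inner_epochs):
            opt_net.zero_grad()
            lr_t, h = _loss_graph(xt, at, mask, params, cfg)
            qt = _soft_assignment_graph((h + c_t) * inv_s, Tensor(mu.data))
            lc_t = _kl_graph(P, qt, cfg.loss_reduction)
            loss = lr_t + lc_t * cfg.gamma_weight
            val = loss.item()
            if not np.isfinite(val):
                raise TrainingDivergedError(
                    f"non-finite loss in alter-training iteration {it}")
            loss.backward()
            opt_net.step()
            lr_val, lc_val = lr_t.item(), lc_t.item()

        # step 2: centroid update, network fixed
        h_fix = std(_forward_h(xt, mask, params, cfg))
        if cfg.centroid_update == "sgd":
            P2 = target_distribution(soft_assignment(h_fix, mu.data))
            for _ in range(cfg.centroid_steps):
                opt_mu.zero_grad()
                qt = _soft_assignment_graph(Tensor(h_fix), mu)
                lc = _kl_graph(P2, qt, cfg.loss_reduction)
                lc.backward()
                opt_mu.step()
        elif cfg.centroid_update == "relouvain":
            lbl, cen = init_centroids(h_fix, knn_k=cfg.cluster_knn_k,
                                      resolution=cfg.cluster_resolution,
                                      seed=cfg.seed)
            mu = Tensor(cen.astype(cfg.dtype), requires_grad=True)
            opt_mu = Adam([mu], lr=alter_lr)
        else:
            raise ValueError(f"unknown centroid_update {cfg.centroid_update!r}")

        Q = soft_assignment(h_fix, mu.data)
        labels = assign_labels(Q)
        changed = np.mean(labels != prev_labels) if it else 1.0
        history.append({"iteration": it, "L_r": lr_val, "L_c": lc_val,
                        "label_change": float(changed)})
        if it > 0 and changed < cfg.label_change_tol:
            break
        prev_labels = labels

    h_final = std(_forward_h(xt, mask, params, cfg))
    Q = soft_assignment(h_final, mu.data)
    Q, mu = _drop_empty(Q, mu, cfg)  # final state only; no optimizer needed
    state = ClusterState(centroids=mu.data.copy(), Q=Q,
                         P=target_distribution(Q), labels=assign_labels(Q))
    return params, state, history


def _forward_h(xt: Tensor, mask: np.ndarray, params: ModelParams,
               cfg: ModelConfig) -> np.ndarray:
    from .graph_autoencoder import _forward_encoder

    return _forward_encoder(xt, mask, params).data


def _drop_empty(Q: np.ndarray, mu: Tensor,
                cfg: ModelConfig) -> tuple[np.ndarray, Tensor]:
    """Drop centroids with vanishing soft mass; renormalize Q.

    A cluster is empty when its soft column mass f_j = sum_i q_ij is
    negligible, not merely when no cell argmax-assigns to it: nearby
    centroids routinely share argmax winners early in training and still
    carry gradient signal.
    """
    f = Q.sum(axis=0)
    keep = f > 1e-6 * Q.shape[0]
    if keep.all():
        return Q, mu
    warnings.warn(f"dropping {int((~keep).sum())} empty cluster(s)",
                  stacklevel=2)
    Qk = Q[:, keep]
    Qk = Qk / Qk.sum(axis=1, keepdims=True)
    return Qk, Tensor(mu.data[keep].copy(), requires_grad=True)
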