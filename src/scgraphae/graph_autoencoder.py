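"""Joint graph autoencoder for single-cell expression graphs.

The model embeds a cell graph (normalized expression matrix ``X``, binary KNN
adjacency ``A``) into a low-dimensional latent space while preserving both
feature information and topology:

* encoder ``E``: stacked graph-attention layers, ``h = E(X, A)``;
* feature decoder ``D_X``: a four-layer fully connected network
  (hidden widths 64, 256, 512) reconstructing ``X_r = D_X(h)``;
* graph decoder ``D_A``: an inner-product decoder
  ``A_r = sigma(Z Z^T)`` with ``Z = sigma(W h)`` and ``sigma = ReLU``.

Training (pretraining stage) minimizes the weighted reconstruction loss

    L_r = lambda * ||X - X_r||_F^2 + (1 - lambda) * ||A - A_r||_F^2

with full-batch Adam. Because ``Z`` is entrywise non-negative, ``Z Z^T`` is
non-negative and the outer ReLU in the graph decoder is the identity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor, concat, masked_softmax

__all__ = [
    "ModelConfig",
    "ModelParams",
    "Embedding",
    "encode",
    "decode_features",
    "decode_graph",
    "reconstruction_loss",
    "pretrain",
    "save_checkpoint",
    "load_checkpoint",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    """Hyperparameters of the autoencoder and its two training stages.

    ``lambda_weight`` balances feature vs graph reconstruction (0.6 by
    default); ``gamma_weight`` scales the clustering loss in alter-training
    (2.5 by default). ``latent_dim`` defaults to 10, the dimension used for
    simulated data (20 is typical for real datasets with complex structure).
    """

    latent_dim: int = 10
    lambda_weight: float = 0.6
    gamma_weight: float = 2.5
    encoder_hidden_dims: tuple[int, ...] = (128,)
    attention_heads: int = 4
    feature_decoder_dims: tuple[int, ...] = (64, 256, 512)
    edge_embed_dim: int | None = None  # None -> latent_dim
    learning_rate: float = 1e-3
    alter_learning_rate: float | None = None  # None -> learning_rate / 10
    pretrain_epochs: int = 200
    alter_iterations: int = 20
    inner_epochs: int = 10
    centroid_steps: int = 10
    centroid_update: str = "sgd"  # or "relouvain"
    cluster_knn_k: int = 15
    cluster_resolution: float = 1.0
    label_change_tol: float = 1e-3  # early stop when fewer labels change
    seed: int = 0
    loss_reduction: str = "sum"  # "sum" (literal Frobenius) or "mean"
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")
        if self.gamma_weight < 0:
            raise ValueError("gamma_weight must be non-negative")
        if self.loss_reduction not in {"sum", "mean"}:
            raise ValueError("loss_reduction must be 'sum' or 'mean'")
        for h in self.encoder_hidden_dims:
            if h % self.attention_heads:
                raise ValueError("encoder hidden widths must be divisible by "
                                 "attention_heads (heads are concatenated)")


@dataclass
class ModelParams:
    """All trainable weights, keyed by name, as autodiff tensors."""

    tensors: dict[str, Tensor]
    n_genes: int
    config: ModelConfig

    def trainable(self) -> list[Tensor]:
        return list(self.tensors.values())

    def copy(self) -> "ModelParams":
        return ModelParams(
            {k: Tensor(v.data.copy(), requires_grad=True)
             for k, v in self.tensors.items()},
            self.n_genes, self.config)


@dataclass
class Embedding:
    """Latent coordinates of cells, n_cells × latent_dim."""

    h: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if not np.isfinite(self.h).all():
            raise ValueError("embedding contains non-finite entries")


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            dtype: np.dtype) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out)).astype(dtype)


def init_params(n_genes: int, config: ModelConfig,
                rng: np.random.Generator | None = None) -> ModelParams:
    """Initialize all weights (Glorot-uniform, zero biases) from the seed."""
    rng = rng or np.random.default_rng(config.seed)
    if config.latent_dim >= n_genes:
        raise ValueError(f"latent_dim ({config.latent_dim}) must be smaller "
                         f"than the number of genes ({n_genes})")
    dt = np.dtype(config.dtype)
    t: dict[str, Tensor] = {}

    def param(name: str, arr: np.ndarray) -> None:
        t[name] = Tensor(arr, requires_grad=True)

    heads = config.attention_heads
    dims = [n_genes, *config.encoder_hidden_dims]
    # hidden GAT layers: heads concatenated, per-head width dim // heads
    for li in range(1, len(dims)):
        per_head = dims[li] // heads
        for hd in range(heads):
            param(f"enc{li}_W{hd}", _glorot(rng, dims[li - 1], per_head, dt))
            param(f"enc{li}_asrc{hd}", _glorot(rng, per_head, 1, dt))
            param(f"enc{li}_adst{hd}", _glorot(rng, per_head, 1, dt))
        param(f"enc{li}_b", np.zeros(dims[li], dtype=dt))
    # output GAT layer: heads averaged, linear, width latent_dim
    li = len(dims)
    for hd in range(heads):
        param(f"enc{li}_W{hd}", _glorot(rng, dims[-1], config.latent_dim, dt))
        param(f"enc{li}_asrc{hd}", _glorot(rng, config.latent_dim, 1, dt))
        param(f"enc{li}_adst{hd}", _glorot(rng, config.latent_dim, 1, dt))
    param(f"enc{li}_b", np.zeros(config.latent_dim, dtype=dt))

    widths = [config.latent_dim, *config.feature_decoder_dims, n_genes]
    for i in range(1, len(widths)):
        param(f"dec{i}_W", _glorot(rng, widths[i - 1], widths[i], dt))
        param(f"dec{i}_b", np.zeros(widths[i], dtype=dt))

    edge_dim = config.edge_embed_dim or config.latent_dim
    param("edge_W", _glorot(rng, config.latent_dim, edge_dim, dt))
    return ModelParams(t, n_genes, config)


# ---------------------------------------------------------------------------
# Forward passes (autodiff graph builders + public numpy wrappers)
# ---------------------------------------------------------------------------

def _attention_mask(A: np.ndarray) -> np.ndarray:
    """Neighbourhood mask: the adjacency plus self edges."""
    mask = A.astype(bool).copy()
    np.fill_diagonal(mask, True)
    return mask


def _gat_layer(x: Tensor, mask: np.ndarray, params: ModelParams, li: int,
               heads: int, combine: str) -> Tensor:
    """One graph-attention layer; softmax attention over 1-hop nbhd + self."""
    t = params.tensors
    outs = []
    for hd in range(heads):
        s = x @ t[f"enc{li}_W{hd}"]
        f_src = s @ t[f"enc{li}_asrc{hd}"]       # (n, 1)
        f_dst = s @ t[f"enc{li}_adst{hd}"]       # (n, 1)
        scores = (f_src + f_dst.T).leaky_relu(0.2)
        attn = masked_softmax(scores, mask)
        outs.append(attn @ s)
    if combine == "concat":
        out = concat(outs, axis=1)
    else:  # average
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        out = acc * (1.0 / heads)
    return out + t[f"enc{li}_b"]


def _forward_encoder(x: Tensor, mask: np.ndarray,
                     params: ModelParams) -> Tensor:
    cfg = params.config
    heads = cfg.attention_heads
    n_hidden = len(cfg.encoder_hidden_dims)
    for li in range(1, n_hidden + 1):
        x = _gat_layer(x, mask, params, li, heads, "concat").elu()
    return _gat_layer(x, mask, params, n_hidden + 1, heads, "average")


def _forward_feature_decoder(h: Tensor, params: ModelParams) -> Tensor:
    cfg = params.config
    t = params.tensors
    n_layers = len(cfg.feature_decoder_dims) + 1
    x = h
    for i in range(1, n_layers + 1):
        x = x @ t[f"dec{i}_W"] + t[f"dec{i}_b"]
        if i < n_layers:
            x = x.elu()
    return x


def _forward_edge_decoder(h: Tensor, params: ModelParams) -> Tensor:
    z = (h @ params.tensors["edge_W"]).relu()
    return z @ z.T


def encode(X: np.ndarray, A: np.ndarray, params: ModelParams,
           config: ModelConfig | None = None) -> Embedding:
    """Embed cells: ``h = E(X, A)``, shape (n_cells, latent_dim)."""
    cfg = config or params.config
    X = np.asarray(X)
    A = np.asarray(A)
    if X.shape[0] != A.shape[0] or A.shape[0] != A.shape[1]:
        raise ValueError(f"X rows ({X.shape[0]}) must align with square A "
                         f"({A.shape})")
    if X.shape[1] != params.n_genes:
        raise ValueError(f"X has {X.shape[1]} genes, params expect "
                         f"{params.n_genes}")
    xt = Tensor(X.astype(cfg.dtype))
    h = _forward_encoder(xt, _attention_mask(A), params)
    return Embedding(h.data)


def decode_features(h: Embedding | np.ndarray,
                    params: ModelParams) -> np.ndarray:
    """Reconstruct the expression matrix from the embedding (row-wise map)."""
    hv = h.h if isinstance(h, Embedding) else np.asarray(h)
    if hv.shape[1] != params.config.latent_dim:
        raise ValueError(f"embedding dim {hv.shape[1]} != latent_dim "
                         f"{params.config.latent_dim}")
    return _forward_feature_decoder(
        Tensor(hv.astype(params.config.dtype)), params).data


def decode_graph(h: Embedding | np.ndarray, params: ModelParams) -> np.ndarray:
    """Inner-product graph decoder: ``A_r = ReLU(Z Z^T)`` with Z = ReLU(hW).

    ``Z`` is non-negative so ``Z Z^T`` already is; the outer ReLU is the
    identity and the returned matrix is symmetric and non-negative.
    """
    hv = h.h if isinstance(h, Embedding) else np.asarray(h)
    if hv.shape[1] != params.tensors["edge_W"].shape[0]:
        raise ValueError("embedding dim incompatible with edge decoder")
    a_r = _forward_edge_decoder(
        Tensor(hv.astype(params.config.dtype)), params).data
    return a_r


def reconstruction_loss(X: np.ndarray, X_r: np.ndarray, A: np.ndarray,
                        A_r: np.ndarray, lam: float = 0.6,
                        reduction: str = "sum") -> float:
    """Weighted reconstruction loss
    ``lambda*||X-X_r||_F^2 + (1-lambda)*||A-A_r||_F^2``.

    ``reduction='mean'`` divides each squared-error term by its element count,
    making the weighting independent of matrix sizes.
    """
    X, X_r, A, A_r = map(np.asarray, (X, X_r, A, A_r))
    if X.shape != X_r.shape:
        raise ValueError(f"X shape {X.shape} != X_r shape {X_r.shape}")
    if A.shape != A_r.shape:
        raise ValueError(f"A shape {A.shape} != A_r shape {A_r.shape}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    lx = np.sum((X - X_r) ** 2)
    la = np.sum((A - A_r) ** 2)
    if reduction == "mean":
        lx /= X.size
        la /= A.size
    elif reduction != "sum":
        raise ValueError("reduction must be 'sum' or 'mean'")
    return float(lam * lx + (1.0 - lam) * la)


def _loss_graph(xt: Tensor, at: Tensor, mask: np.ndarray,
                params: ModelParams, cfg: ModelConfig
                ) -> tuple[Tensor, Tensor]:
    """Autodiff reconstruction loss; returns (loss, h) for reuse."""
    h = _forward_encoder(xt, mask, params)
    x_r = _forward_feature_decoder(h, params)
    a_r = _forward_edge_decoder(h, params)
    lx = (xt - x_r).square().sum()
    la = (at - a_r).square().sum()
    if cfg.loss_reduction == "mean":
        lx = lx * (1.0 / xt.data.size)
        la = la * (1.0 / at.data.size)
    loss = lx * cfg.lambda_weight + la * (1.0 - cfg.lambda_weight)
    return loss, h


def pretrain(X: np.ndarray, A: np.ndarray, config: ModelConfig,
             params: ModelParams | None = None
             ) -> tuple[ModelParams, list[float]]:
    """Stage one: train the autoencoder by minimizing ``L_r`` (full batch).

    Returns the trained parameters and the per-epoch loss history. With
    ``pretrain_epochs=0`` the freshly initialized parameters are returned
    with an empty history.
    """
    X = np.asarray(X, dtype=config.dtype)
    A = np.asarray(A, dtype=config.dtype)
    if X.shape[0] != A.shape[0] or A.shape[0] != A.shape[1]:
        raise ValueError("X rows must align with square A")
    if params is None:
        params = init_params(X.shape[1], config)
    mask = _attention_mask(A)
    xt, at = Tensor(X), Tensor(A)
    opt = Adam(params.trainable(), lr=config.learning_rate)
    history: list[float] = []
    for epoch in range(config.pretrain_epochs):
        opt.zero_grad()
        loss, _ = _loss_graph(xt, at, mask, params, config)
        val = loss.item()
        if not np.isfinite(val):
            raise TrainingDivergedError(
                f"non-finite reconstruction loss at epoch {epoch}; "
                "try a lower learning_rate")
        loss.backward()
        opt.step()
        history.append(val)
    return params, history


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(params: ModelParams, path: str | Path) -> None:
    """Self-describing checkpoint: weights plus serialized config (npz)."""
    path = Path(path)
    arrays = {k: v.data for k, v in params.tensors.items()}
    meta = json.dumps({"config": asdict(params.config),
                       "n_genes": params.n_genes})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> ModelParams:
    path = Path(path)
    if not path.exists():  # np.savez appends .npz
        path = Path(f"{path}.npz")
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_d = meta["config"]
        for key in ("encoder_hidden_dims", "feature_decoder_dims"):
            cfg_d[key] = tuple(cfg_d[key])
        config = ModelConfig(**cfg_d)
        tensors = {k: Tensor(z[k], requires_grad=True)
                   for k in z.files if k != "__meta__"}
    return ModelParams(tensors, meta["n_genes"], config)
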