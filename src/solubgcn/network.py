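"""Vectorized numpy implementation of the hybrid GCN forward/backward passes.

The network maps a batch of protein graphs to solubility values:

    H --AFR--> R --[A_hat R W + b, ReLU] x n_layers--> X
      --self-attention readout--> g --sigmoid(g . w + b)--> s_hat in (0, 1)

All proteins of a mini-batch are packed into the disjoint union of their
residue graphs: node features are row-concatenated and the normalized
adjacencies form one block-diagonal sparse matrix, so a whole batch is a
handful of (sparse) matrix products.  AFR pooling, the attention softmax and
the attention-weighted readout are segment operations over contiguous
per-protein row ranges.

Gradients are computed by a hand-written reverse pass over the same cached
intermediates and are verified against central finite differences in the test
suite.  Optimization uses Adam; the training loss is the root-mean-square
error of the batch, matching the evaluation metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import expit


@dataclass
class NetConfig:
    """Architecture and optimization hyperparameters (see the estimator docs)."""

    n_channels: int
    gcn_layers: int = 2
    gcn_hidden: int = 256
    attention_hidden: int = 128
    attention_heads: int = 1
    dropout: float = 0.2
    use_afr: bool = True
    afr_bias: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gcn_layers < 1:
            raise ValueError("gcn_layers must be >= 1")
        if self.attention_heads < 1:
            raise ValueError("attention_heads must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class PackedBatch:
    """A disjoint union of protein graphs.

    ``X`` stacks node features (``N x C``), ``A`` is the block-diagonal sparse
    normalized adjacency, ``starts``/``lengths`` delimit each protein's
    contiguous row range and ``prot_of_row`` maps rows to protein indices.
    """

    X: np.ndarray
    A: sp.csr_matrix
    starts: np.ndarray
    lengths: np.ndarray
    prot_of_row: np.ndarray
    y: np.ndarray | None = None

    @property
    def n_proteins(self) -> int:
        return len(self.lengths)


def pack_batch(
    features: Sequence[np.ndarray],
    adjacencies: Sequence[np.ndarray | sp.spmatrix],
    y: np.ndarray | None = None,
) -> PackedBatch:
    """Pack per-protein feature matrices and adjacencies into one batch."""
    lengths = np.array([f.shape[0] for f in features], dtype=int)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(int)
    prot_of_row = np.repeat(np.arange(len(features)), lengths)
    X = np.concatenate(list(features), axis=0)
    A = sp.block_diag([sp.csr_matrix(a) for a in adjacencies], format="csr")
    return PackedBatch(
        X=X,
        A=A,
        starts=starts,
        lengths=lengths,
        prot_of_row=prot_of_row,
        y=None if y is None else np.asarray(y, dtype=float),
    )


def _seg_sum(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(values, starts, axis=0)


def _seg_max(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.maximum.reduceat(values, starts, axis=0)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def init_params(config: NetConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform layer weights; AFR kernels ~ U(-1,1)/sqrt(C), zero biases."""

    def glorot(fan_in: int, fan_out: int, shape=None) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))

    C, h, a = config.n_channels, config.gcn_hidden, config.attention_hidden
    params: dict[str, np.ndarray] = {}
    if config.use_afr:
        params["afr_K"] = rng.uniform(-1.0, 1.0, size=(C, C)) / np.sqrt(C)
        if config.afr_bias:
            params["afr_b"] = np.zeros(C)
    d_in = C
    for layer in range(config.gcn_layers):
        params[f"gcn_W{layer}"] = glorot(d_in, h)
        params[f"gcn_b{layer}"] = np.zeros(h)
        d_in = h
    params["att_W"] = glorot(h, a)
    params["att_b"] = np.zeros(a)
    params["att_v"] = glorot(a, config.attention_heads, shape=(a, config.attention_heads))
    params["att_c"] = np.zeros(config.attention_heads)
    params["out_w"] = glorot(h, 1, shape=(h,))
    params["out_b"] = np.zeros(1)
    return params


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------


def forward(
    params: dict[str, np.ndarray],
    batch: PackedBatch,
    config: NetConfig,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> dict:
    """Forward pass; returns a cache of every intermediate needed by backward."""
    X0 = batch.X
    starts, lengths, prot = batch.starts, batch.lengths, batch.prot_of_row
    cache: dict = {"X0": X0}

    if config.use_afr:
        G = _seg_sum(X0, starts) / lengths[:, None]          # n x C pooled
        O = G @ params["afr_K"].T
        if "afr_b" in params:
            O = O + params["afr_b"]
        P = np.maximum(0.0, O)
        # clamp saturated gates inside the open interval, as in afr.channel_weights
        Wc = np.clip(expit(P), np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
        X = X0 * Wc[prot]
        cache.update(G=G, O=O, P=P, Wc=Wc)
    else:
        X = X0

    Zs, Us, Xs, masks = [], [], [], []
    for layer in range(config.gcn_layers):
        Z = batch.A @ X
        U = Z @ params[f"gcn_W{layer}"] + params[f"gcn_b{layer}"]
        X = np.maximum(0.0, U)
        if train and config.dropout > 0.0:
            keep = 1.0 - config.dropout
            mask = (dropout_rng.random(X.shape) < keep) / keep
            X = X * mask
            masks.append(mask)
        else:
            masks.append(None)
        Zs.append(Z)
        Us.append(U)
        Xs.append(X)
    cache.update(Zs=Zs, Us=Us, Xs=Xs, masks=masks)

    # self-attention readout: softmax over each protein's residues, per head
    T = np.tanh(Xs[-1] @ params["att_W"] + params["att_b"])   # N x a
    E = T @ params["att_v"] + params["att_c"]                  # N x heads
    Em = _seg_max(E, starts)
    Ex = np.exp(E - Em[prot])
    denom = _seg_sum(Ex, starts)
    alpha = Ex / denom[prot]                                   # N x heads
    pooled = np.stack(
        [_seg_sum(alpha[:, k:k + 1] * Xs[-1], starts) for k in range(alpha.shape[1])],
        axis=0,
    )                                                          # heads x n x h
    g = pooled.mean(axis=0)                                    # n x h
    z = g @ params["out_w"] + params["out_b"][0]
    s_hat = expit(z)
    cache.update(T=T, E=E, alpha=alpha, pooled=pooled, g=g, z=z, s_hat=s_hat)
    return cache


# ---------------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------------


def rmse_loss_grad(s_hat: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """RMSE of the batch and its gradient with respect to the predictions."""
    resid = s_hat - y
    loss = float(np.sqrt(np.mean(resid**2)))
    if loss == 0.0:
        return loss, np.zeros_like(resid)
    return loss, resid / (resid.size * loss)


def backward(
    params: dict[str, np.ndarray],
    batch: PackedBatch,
    config: NetConfig,
    cache: dict,
    ds_hat: np.ndarray,
) -> dict[str, np.ndarray]:
    """Reverse pass from d(loss)/d(s_hat) to gradients for every parameter."""
    starts, lengths, prot = batch.starts, batch.lengths, batch.prot_of_row
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    s_hat, g, alpha, T = cache["s_hat"], cache["g"], cache["alpha"], cache["T"]
    X_last = cache["Xs"][-1]
    heads = alpha.shape[1]

    dz = ds_hat * s_hat * (1.0 - s_hat)
    grads["out_w"] = cache["g"].T @ dz
    grads["out_b"] = np.array([dz.sum()])
    dg = dz[:, None] * params["out_w"][None, :]               # n x h

    dX_last = np.zeros_like(X_last)
    dT = np.zeros_like(T)
    for k in range(heads):
        dpool_k = dg / heads                                   # n x h
        a_k = alpha[:, k]
        # pooled_k[p] = sum_i a_k[i] X_last[i]
        dX_last += a_k[:, None] * dpool_k[prot]
        dalpha_k = np.einsum("ij,ij->i", X_last, dpool_k[prot])
        inner = _seg_sum((a_k * dalpha_k)[:, None], starts)[:, 0]
        dE_k = a_k * (dalpha_k - inner[prot])
        grads["att_v"][:, k] = T.T @ dE_k
        grads["att_c"][k] = dE_k.sum()
        dT += dE_k[:, None] * params["att_v"][:, k][None, :]
    dU_t = dT * (1.0 - T**2)
    grads["att_W"] = X_last.T @ dU_t
    grads["att_b"] = dU_t.sum(axis=0)
    dX_last += dU_t @ params["att_W"].T

    dX = dX_last
    for layer in range(config.gcn_layers - 1, -1, -1):
        mask = cache["masks"][layer]
        if mask is not None:
            dX = dX * mask
        dU = dX * (cache["Us"][layer] > 0.0)
        grads[f"gcn_W{layer}"] = cache["Zs"][layer].T @ dU
        grads[f"gcn_b{layer}"] = dU.sum(axis=0)
        dZ = dU @ params[f"gcn_W{layer}"].T
        dX = batch.A.T @ dZ

    if config.use_afr:
        X0, Wc, P, O, G = cache["X0"], cache["Wc"], cache["P"], cache["O"], cache["G"]
        # dX here is d(loss)/dR with R = X0 * Wc[prot]
        dWc = _seg_sum(dX * X0, starts)                        # n x C
        dP = dWc * Wc * (1.0 - Wc)
        dO = dP * (O > 0.0)
        grads["afr_K"] = dO.T @ G
        if "afr_b" in params:
            grads["afr_b"] = dO.sum(axis=0)
    return grads


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


@dataclass
class AdamState:
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)
    t: int = 0


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    """One in-place Adam update."""
    state.t += 1
    for key, grad in grads.items():
        if key not in state.m:
            state.m[key] = np.zeros_like(grad)
            state.v[key] = np.zeros_like(grad)
        state.m[key] = beta1 * state.m[key] + (1 - beta1) * grad
        state.v[key] = beta2 * state.v[key] + (1 - beta2) * grad**2
        m_hat = state.m[key] / (1 - beta1**state.t)
        v_hat = state.v[key] / (1 - beta2**state.t)
        params[key] -= lr * m_hat / (np.sqrt(v_hat) + eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def predict_batch(params: dict, batch: PackedBatch, config: NetConfig) -> np.ndarray:
    return forward(params, batch, config, train=False)["s_hat"]


def mean_channel_weights(params: dict, batch: PackedBatch, config: NetConfig) -> np.ndarray | None:
    """Dataset-mean AFR gate vector (None when AFR is disabled)."""
    if not config.use_afr:
        return None
    cache = forward(params, batch, config, train=False)
    return cache["Wc"].mean(axis=0)


def train_network(
    train_items: Sequence[tuple[np.ndarray, np.ndarray | sp.spmatrix, float]],
    config: NetConfig,
    val_items: Sequence[tuple[np.ndarray, np.ndarray | sp.spmatrix, float]] | None = None,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Mini-batch Adam training with optional early stopping.

    ``train_items`` is a list of ``(node_features, normalized_adjacency, y)``
    per protein.  When ``val_items`` is given, validation RMSE is monitored
    each epoch and the parameters with the best validation RMSE are returned
    (early stop after ``config.patience`` epochs without improvement);
    otherwise training runs for ``config.max_epochs`` epochs.

    Returns the trained parameters and a per-epoch history of
    ``{"epoch", "train_rmse", "val_rmse"}``.
    """
    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)
    state = AdamState()
    n = len(train_items)
    feats = [np.asarray(f, dtype=float) for f, _, _ in train_items]
    adjs = [sp.csr_matrix(a) for _, a, _ in train_items]
    ys = np.array([y for _, _, y in train_items], dtype=float)

    full_train = pack_batch(feats, adjs, ys)
    val_batch = None
    if val_items:
        val_batch = pack_batch(
            [np.asarray(f, dtype=float) for f, _, _ in val_items],
            [sp.csr_matrix(a) for _, a, _ in val_items],
            np.array([y for _, _, y in val_items], dtype=float),
        )

    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = 0
    stall = 0
    history: list[dict] = []
    batch_size = max(1, min(config.batch_size, n))

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            batch = pack_batch([feats[i] for i in idx], [adjs[i] for i in idx], ys[idx])
            cache = forward(params, batch, config, train=True, dropout_rng=rng)
            loss, ds_hat = rmse_loss_grad(cache["s_hat"], batch.y)
            grads = backward(params, batch, config, cache, ds_hat)
            adam_step(params, grads, state, config.learning_rate)
            epoch_losses.append(loss)

        record = {"epoch": epoch, "train_rmse": float(np.mean(epoch_losses))}
        if val_batch is not None:
            val_pred = predict_batch(params, val_batch, config)
            val_rmse = float(np.sqrt(np.mean((val_pred - val_batch.y) ** 2)))
            record["val_rmse"] = val_rmse
            if val_rmse < best_val - 1e-6:
                best_val = val_rmse
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
        history.append(record)
        if val_batch is not None and stall >= config.patience:
            break

    if val_batch is not None:
        params = best_params
        history.append({"epoch": best_epoch, "restored_best": True, "val_rmse": best_val})
    # keep a handle on the full training batch for diagnostics callers
    history.append({"final_train_rmse": float(
        np.sqrt(np.mean((predict_batch(params, full_train, config) - ys) ** 2))
    )})
    return params, history
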