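"""Adaptive Feature Re-weighting (AFR): per-channel gating of the hybrid feature.

The module learns one gating weight per feature channel and multiplies every
residue's features by it, in four stages:

1. global average pooling over residues,          ``G_c = (1/L) sum_i H[i, c]``
2. cross-channel linear interaction,              ``O = G V^T (+ bias)``
3. rectification,                                 ``P = max(0, O)``
4. logistic gating,                               ``W_c = sigmoid(P_c)``

and finally the channel-wise product ``R[i, c] = H[i, c] * W_c``.  The
interaction step is described as ``C`` convolution filters of support
``1 x C`` applied to the ``1 x C`` pooled vector — mathematically a dense
``C -> C`` linear map, and implemented as such.

Because ``P >= 0`` by construction, every gate satisfies ``W_c >= 0.5``: the
rectifier is applied before the sigmoid, so gates operate in the upper half of
the logistic range and a channel can be down-weighted at most to half its
magnitude.  This is the literal published form of the module and is covered by
the test suite as a documented property.

Weights are computed per protein (the pooling in stage 1 runs over one
protein's residues), so each protein receives its own gate vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

from .exceptions import ConfigError, ShapeError


@dataclass
class AFRParams:
    """Trainable parameters: the ``C x C`` interaction kernels and optional bias.

    Row ``c'`` of ``kernels`` holds the filter producing output channel ``c'``.
    """

    kernels: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        K = self.kernels
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ShapeError(f"AFR kernels must be square CxC, got shape {K.shape}")
        if not np.all(np.isfinite(K)):
            raise ShapeError("AFR kernels contain non-finite entries")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float).ravel()
            if self.bias.shape[0] != K.shape[0]:
                raise ShapeError(
                    f"AFR bias has length {self.bias.shape[0]}, expected {K.shape[0]}"
                )

    @property
    def C(self) -> int:
        return self.kernels.shape[0]


@dataclass
class ChannelWeights:
    """Diagnostic record of the AFR stages for one protein.

    ``G`` pooled per-channel features, ``O`` linear interactions, ``P_nl``
    rectified interactions, ``W`` the final gates in ``(0, 1)``.
    """

    G: np.ndarray
    O: np.ndarray
    P_nl: np.ndarray
    W: np.ndarray


def init_afr_params(C: int, seed: int = 0, bias: bool = True) -> AFRParams:
    """Near-neutral initialization: kernels ~ U(-1, 1)/sqrt(C), zero bias.

    With pooled features of order one this keeps the initial interactions
    small, so initial gates sit near sigmoid(0) = 0.5.
    """
    rng = np.random.default_rng(seed)
    kernels = rng.uniform(-1.0, 1.0, size=(C, C)) / np.sqrt(C)
    return AFRParams(kernels=kernels, bias=np.zeros(C) if bias else None)


def global_average_pool(H: np.ndarray) -> np.ndarray:
    """Mean of each channel over residues: ``G_c = (1/L) sum_i H[i, c]``."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise ShapeError(f"expected an L x C matrix, got {H.ndim}-D input")
    if H.shape[0] == 0:
        raise ShapeError("global average pool of an empty (L=0) matrix")
    return H.mean(axis=0)


def channel_interaction(G: np.ndarray, params: AFRParams) -> tuple[np.ndarray, np.ndarray]:
    """Linear cross-channel interaction and its rectification.

    Returns ``(O, P_nl)`` where ``O[c'] = sum_c kernels[c', c] * G[c] (+ bias)``
    and ``P_nl = max(0, O)``.
    """
    G = np.asarray(G, dtype=float).ravel()
    if G.shape[0] != params.C:
        raise ShapeError(
            f"pooled vector has {G.shape[0]} channels but kernels are "
            f"{params.C}x{params.C}"
        )
    O = params.kernels @ G
    if params.bias is not None:
        O = O + params.bias
    return O, np.maximum(0.0, O)


def channel_weights(P_nl: np.ndarray) -> np.ndarray:
    """Elementwise logistic gate ``W_c = 1 / (1 + exp(-P_c))``, strictly in (0, 1).

    The sigmoid never reaches 0 or 1 mathematically, but in float64 it rounds
    to exactly 1 once ``P_c`` exceeds ~37; saturated values are clamped to the
    nearest representable number inside the open interval so the strict gating
    bound ``|R| < |H|`` survives numerically.
    """
    W = expit(np.asarray(P_nl, dtype=float))
    return np.clip(W, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def reweight(H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Channel-wise product ``R[i, c] = H[i, c] * W_c``."""
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float).ravel()
    if H.shape[1] != W.shape[0]:
        raise ShapeError(
            f"H has {H.shape[1]} channels but the gate vector has {W.shape[0]}"
        )
    return H * W[None, :]


def afr_forward(H: np.ndarray, params: AFRParams) -> tuple[np.ndarray, ChannelWeights]:
    """Full AFR pass: pool, interact, rectify, gate, re-weight.

    Returns the re-weighted feature ``R`` and the stage diagnostics.
    """
    G = global_average_pool(H)
    O, P_nl = channel_interaction(G, params)
    W = channel_weights(P_nl)
    R = reweight(H, W)
    return R, ChannelWeights(G=G, O=O, P_nl=P_nl, W=W)


def block_importance(
    weights: ChannelWeights | np.ndarray,
    block_spans: Mapping[str, tuple[int, int]],
) -> dict[str, float]:
    """Mean gate weight per feature block.

    ``block_spans`` must partition ``[0, C)``; the result maps each block name
    to the mean of ``W`` over its channel interval.
    """
    W = weights.W if isinstance(weights, ChannelWeights) else np.asarray(weights, dtype=float)
    W = W.ravel()
    spans = sorted(block_spans.items(), key=lambda kv: kv[1][0])
    cursor = 0
    for name, (start, stop) in spans:
        if start != cursor or stop <= start:
            raise ConfigError(
                f"block spans do not partition [0, {W.shape[0]}): "
                f"block {name} spans [{start}, {stop}) after position {cursor}"
            )
        cursor = stop
    if cursor != W.shape[0]:
        raise ConfigError(
            f"block spans cover [0, {cursor}) but W has {W.shape[0]} channels"
        )
    return {name: float(W[start:stop].mean()) for name, (start, stop) in spans}
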