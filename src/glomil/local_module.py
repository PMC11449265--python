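"""Local module: patch features, gated attention, and the local head.

The K retrieved patches are encoded into S-dimensional feature vectors
and aggregated with the gated-attention mechanism of attention-based
multiple-instance learning: each patch's pre-softmax score is
w^T (tanh(V h^T) * sigm(U h^T)), the softmax over patches gives the
attention weights, and the bag representation is the attention-weighted
sum of patch features.  A per-class sigmoid head on the bag yields the
local prediction.  Neither gate carries a bias term.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor
from .nn import PatchEncoder

__all__ = ["AttentionParams", "LocalHead", "encode_patch", "gated_attention",
           "attention_pool", "local_predict", "init_attention_params",
           "init_local_head"]


@dataclasses.dataclass
class AttentionParams:
    """Gated-attention parameters: w (L, 1), V (L, S), U (L, S)."""

    w: np.ndarray
    V: np.ndarray
    U: np.ndarray

    def __post_init__(self):
        L = self.w.shape[0]
        if self.w.shape != (L, 1):
            raise ValueError(f"w must be (L, 1), got {self.w.shape}")
        if self.V.shape[0] != L or self.U.shape != self.V.shape:
            raise ValueError("V and U must both be (L, S)")


@dataclasses.dataclass
class LocalHead:
    """Per-class linear weights (S, 2) for the sigmoid local prediction."""

    w_local: np.ndarray

    def __post_init__(self):
        if self.w_local.ndim != 2 or self.w_local.shape[1] != 2:
            raise ValueError(f"w_local must be (S, 2), got {self.w_local.shape}")


def init_attention_params(S: int = 512, L: int = 128, *,
                          rng: np.random.Generator) -> AttentionParams:
    scale = 1.0 / np.sqrt(S)
    return AttentionParams(
        w=rng.normal(0, 1.0 / np.sqrt(L), size=(L, 1)),
        V=rng.normal(0, scale, size=(L, S)),
        U=rng.normal(0, scale, size=(L, S)),
    )


def init_local_head(S: int = 512, *, rng: np.random.Generator) -> LocalHead:
    return LocalHead(w_local=rng.normal(0, 1.0 / np.sqrt(S), size=(S, 2)))


def encode_patch(patch: np.ndarray, encoder: PatchEncoder) -> np.ndarray:
    """Encode one 2D patch into a length-S feature vector (evaluation mode)."""
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2:
        raise ValueError(f"patch must be 2D, got shape {patch.shape}")
    was_training = encoder.training
    encoder.eval()
    feat = encoder(Tensor(patch[np.newaxis, np.newaxis])).data[0]
    encoder.train(was_training)
    return feat


def _attention_scores(features: np.ndarray, params: AttentionParams) -> np.ndarray:
    # h: (K, S); score_k = w^T (tanh(V h_k^T) * sigm(U h_k^T))
    gate_t = np.tanh(params.V @ features.T)            # (L, K)
    gate_s = 1.0 / (1.0 + np.exp(-(params.U @ features.T)))
    return (params.w.T @ (gate_t * gate_s)).ravel()    # (K,)


def gated_attention(features: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Softmax attention weights over the K patch features (K, S) -> (K,)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("features must be a non-empty (K, S) array")
    scores = _attention_scores(features, params)
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


def attention_pool(features: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Bag representation z = sum_k alpha_k h_k."""
    features = np.asarray(features, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if features.shape[0] != alpha.shape[0]:
        raise ValueError(
            f"{features.shape[0]} features but {alpha.shape[0]} attention weights")
    return alpha @ features


def local_predict(z: np.ndarray, head: LocalHead) -> tuple[float, float]:
    """Per-class sigmoid prediction from the bag representation."""
    z = np.asarray(z, dtype=float)
    if z.shape != (head.w_local.shape[0],):
        raise ValueError(f"z must have length {head.w_local.shape[0]}, "
                         f"got shape {z.shape}")
    logits = z @ head.w_local
    return tuple(1.0 / (1.0 + np.exp(-logits)))
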