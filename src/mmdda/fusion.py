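"""Multi-head attention fusion of MRI and PET feature maps.

The two (B, C, D, H, W) modality feature maps are concatenated along the
channel axis and reshaped into a sequence (B, L, E) with L = D*H*W and
E = 2C; a single multi-head attention layer mixes the sequence, and the
result is reduced over L to the fused per-subject vector of dimension
d = E (256 in the full-size configuration).

Reducing over L by arithmetic mean is an interpretive choice: with the
full-size encoder the attention output is (L=2, E=256) and a raw flatten
would give 512 dimensions, which is inconsistent with the stated fused
dimension of 256; the mean over the sequence axis is the reduction that
preserves it.  Raw flattening remains available (``reduce="flatten"``) for
sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, concatenate
from . import nn

__all__ = ["FusionConfig", "concat_reshape", "MultiHeadAttention", "flatten_fused",
           "TASK_HEAD_COUNTS"]

#: attention head counts selected per classification task
TASK_HEAD_COUNTS = {"AD_CN": 4, "MCI_CN": 4, "AD_MCI": 8, "pMCI_sMCI": 16}


@dataclass(frozen=True)
class FusionConfig:
    """heads: number of attention heads (must divide E = 2C);
    reduce: sequence-axis reduction producing the fused vector."""

    heads: int = 4
    reduce: str = "mean"

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise ValueError(f"heads must be positive, got {self.heads}")
        if self.reduce not in ("mean", "flatten"):
            raise ValueError(f"unknown reduce mode {self.reduce!r}")


def concat_reshape(f_mri: Tensor, f_pet: Tensor) -> Tensor:
    """Channel-concatenate two (B, C, D, H, W) maps and reshape to (B, L, E)."""
    if f_mri.shape[0] != f_pet.shape[0] or f_mri.shape[2:] != f_pet.shape[2:]:
        raise ValueError(
            f"modality feature maps disagree: {f_mri.shape} vs {f_pet.shape}")
    stacked = concatenate([f_mri, f_pet], axis=1)  # (B, 2C, D, H, W)
    b, e = stacked.shape[0], stacked.shape[1]
    l = int(np.prod(stacked.shape[2:]))
    # (B, E, L) -> (B, L, E): positions along the sequence axis, channels as features
    return stacked.reshape(b, e, l).transpose(0, 2, 1)


class MultiHeadAttention(nn.Module):
    """Single application of multi-head scaled dot-product attention.

    Q = X W_Q, K = X W_K, V = X W_V are split into ``heads`` subspaces of
    width d_k = E/heads; per head, softmax(Q K' / sqrt(d_k)) V; head outputs
    are concatenated and mixed by the output matrix W1.  All four matrices
    are square (E, E) without bias.
    """

    def __init__(self, embed_dim: int, heads: int, rng: np.random.Generator) -> None:
        super().__init__()
        if embed_dim % heads != 0:
            raise ValueError(f"embed dim {embed_dim} not divisible by {heads} heads")
        self.embed_dim = embed_dim
        self.heads = heads
        self.d_k = embed_dim // heads
        init = lambda: Tensor(nn.kaiming_init(rng, (embed_dim, embed_dim), embed_dim),
                              requires_grad=True)
        self.w_q = init()
        self.w_k = init()
        self.w_v = init()
        self.w_out = init()

    def forward(self, seq: Tensor, return_weights: bool = False):
        b, l, e = seq.shape
        if e != self.embed_dim:
            raise ValueError(f"attention built for E={self.embed_dim}, got {e}")

        def split(x: Tensor) -> Tensor:  # (B, L, E) -> (B, h, L, d_k)
            return x.reshape(b, l, self.heads, self.d_k).transpose(0, 2, 1, 3)

        q = split(seq @ self.w_q)
        k = split(seq @ self.w_k)
        v = split(seq @ self.w_v)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_k))
        weights = scores.softmax(axis=-1)          # (B, h, L, L)
        heads_out = weights @ v                    # (B, h, L, d_k)
        merged = heads_out.transpose(0, 2, 1, 3).reshape(b, l, e)
        out = merged @ self.w_out
        if return_weights:
            return out, weights
        return out


def flatten_fused(attn_out: Tensor, reduce: str = "mean") -> Tensor:
    """Reduce a (B, L, E) attention output to per-subject fused vectors.

    ``"mean"`` averages over the sequence axis, giving vectors of length E;
    ``"flatten"`` concatenates the rows, giving length L*E.
    """
    b, l, e = attn_out.shape
    if reduce == "mean":
        return attn_out.mean(axis=1)
    if reduce == "flatten":
        return attn_out.reshape(b, l * e)
    raise ValueError(f"unknown reduce mode {reduce!r}")
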