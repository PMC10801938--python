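"""Cross-modal attention fusion of expert-feature and signal latents.

Each modality — the expert token sequence Z_e (the 45 features projected to a
single 256-wide token) and the signal latent Z_s (400 x 256 from the
backbone) — first runs intra-modal multi-head self-attention.  Each attended
position is then scored by cosine similarity against the *other* modality's
time-pooled embedding; a softmax over positions turns the scores into the
cross-modal attention score (CMAS), which weights the sequence before global
average + max pooling.  The two 2C-dimensional pooled vectors (512 each at
default width) concatenate into the fused representation Z_m (1024).

Early/late fusion baselines and single-modality modes are provided for
ablation comparisons.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .nn import (
    Linear,
    Module,
    MultiHeadSelfAttention,
    Tensor,
    concat,
)

__all__ = [
    "FUSION_MODES",
    "cross_modal_attention_score",
    "weighted_pool",
    "fuse",
    "ExpertEmbedding",
    "CrossModalFusion",
]

FUSION_MODES = ("cmff", "early", "late", "expert_only", "signal_only")

_EPS = 1e-12


def _cosine_vs_pooled(z: Tensor, pooled_other: Tensor) -> Tensor:
    """Positionwise cosine similarity of z[t] against a pooled vector.

    ``z``: (B, L, C); ``pooled_other``: (B, 1, C).  Zero-norm vectors give a
    similarity of 0 (the eps in the denominator makes the ratio vanish).
    """
    dot = (z * pooled_other).sum(axis=-1)  # (B, L)
    nz = ((z * z).sum(axis=-1) + _EPS) ** 0.5
    ng = ((pooled_other * pooled_other).sum(axis=-1) + _EPS) ** 0.5
    return dot * (nz * ng) ** -1.0


def cross_modal_attention_score(z_e: Tensor, z_s: Tensor) -> Tuple[Tensor, Tensor]:
    """CMAS for both modalities: softmax over positions of cross cosine scores.

    Each position of one modality's attended latent is scored against the
    time-mean embedding of the other modality; softmax over the sequence
    axis yields nonnegative weights summing to 1 per sample.
    """
    z_e = Tensor.as_tensor(z_e)
    z_s = Tensor.as_tensor(z_s)
    g_e = z_e.mean(axis=1, keepdims=True)
    g_s = z_s.mean(axis=1, keepdims=True)
    cmas_e = _cosine_vs_pooled(z_e, g_s).softmax(axis=-1)
    cmas_s = _cosine_vs_pooled(z_s, g_e).softmax(axis=-1)
    return cmas_e, cmas_s


def weighted_pool(z: Tensor, cmas: Tensor) -> Tensor:
    """CMAS-weighted sequence pooled by concat(GAP, GMP) -> (B, 2C)."""
    z = Tensor.as_tensor(z)
    cmas = Tensor.as_tensor(cmas)
    if cmas.shape[-1] != z.shape[1]:
        raise ValueError(
            f"CMAS length {cmas.shape[-1]} does not match sequence {z.shape[1]}"
        )
    w = z * cmas.reshape(cmas.shape[0], cmas.shape[-1], 1)
    gap = w.mean(axis=1)
    gmp = w.max(axis=1)
    return concat([gap, gmp], axis=-1)


def fuse(p_e: Tensor, p_s: Tensor) -> Tensor:
    """Concatenate pooled modality vectors, expert half first -> (B, 4C)."""
    p_e = Tensor.as_tensor(p_e)
    p_s = Tensor.as_tensor(p_s)
    if p_e.shape[-1] != p_s.shape[-1]:
        raise ValueError("pooled vectors must have equal width")
    return concat([p_e, p_s], axis=-1)


class ExpertEmbedding(Module):
    """Project the 45 expert features to a single latent token (B, 1, C).

    Two linear layers (45 -> hidden -> ReLU -> C) make the expert modality
    the same width as the signal latent so shared head sizes apply.
    """

    def __init__(
        self,
        n_features: int,
        d_model: int,
        rng: np.random.Generator,
        hidden: int = 128,
    ):
        super().__init__()
        self.fc1 = Linear(n_features, hidden, rng)
        self.fc2 = Linear(hidden, d_model, rng)

    def forward(self, feats: Tensor) -> Tensor:
        h = self.fc2(self.fc1(feats).relu())
        b, c = h.shape
        return h.reshape(b, 1, c)


class CrossModalFusion(Module):
    """Intra-modal self-attention plus CMAS-weighted pooling and fusion."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.attn_e = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.attn_s = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.d_model = d_model

    def forward(self, z_e: Tensor, z_s: Tensor, return_parts: bool = False):
        ze_att = self.attn_e(z_e)
        zs_att = self.attn_s(z_s)
        cmas_e, cmas_s = cross_modal_attention_score(ze_att, zs_att)
        p_e = weighted_pool(ze_att, cmas_e)
        p_s = weighted_pool(zs_att, cmas_s)
        z_m = fuse(p_e, p_s)
        if return_parts:
            return z_m, {
                "z_e_att": ze_att,
                "z_s_att": zs_att,
                "cmas_e": cmas_e,
                "cmas_s": cmas_s,
                "p_e": p_e,
                "p_s": p_s,
            }
        return z_m
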