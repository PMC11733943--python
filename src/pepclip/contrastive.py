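"""Shared-latent-space similarity and the symmetric temperature-scaled
contrastive (CLIP-style) loss.

For a batch of N peptides with row-aligned graph latents G and text
latents T (row i of both refers to the same peptide), the logit matrix is

    S[i, j] = cos(g_i, t_j) / tau

and the loss is the mean of two cross-entropies against the diagonal —
each row of S against target j = i and each column against target i = j —
averaged with factor 1/2.  Minimizing it pulls genuine sequence/structure
pairs together and pushes all other combinations apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["LatentBatch", "similarity", "similarity_matrix", "clip_loss"]


@dataclass
class LatentBatch:
    G: Tensor  # (N, d) graph latents
    T: Tensor  # (N, d) text latents
    ids: list[str] | None = None

    def __post_init__(self):
        if self.G.shape != self.T.shape:
            raise ValueError(
                f"latent width/size mismatch: {self.G.shape} vs {self.T.shape}"
            )
        if self.ids is not None and len(self.ids) != self.G.shape[0]:
            raise ValueError("ids not row-aligned with latents")


def _normalize_rows(m: Tensor) -> Tensor:
    norms = (m**2).sum(axis=-1, keepdims=True) ** 0.5
    if np.any(norms.data == 0.0):
        raise ValueError("zero vector has no direction; cannot normalize")
    return m / norms


def similarity(x, y) -> float:
    """Cosine similarity: dot product of the L2-normalized vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal widths")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("zero vector has no direction; cannot normalize")
    return float(x @ y / (nx * ny))


def similarity_matrix(batch: LatentBatch, tau: float) -> Tensor:
    """N x N logits: S[i][j] = cos(g_i, t_j) / tau."""
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    g = _normalize_rows(batch.G)
    t = _normalize_rows(batch.T)
    return g @ t.T / tau


def _diag_cross_entropy(logits: Tensor) -> Tensor:
    """Mean cross-entropy of each row against target index = row number."""
    n = logits.shape[0]
    log_probs = logits - logits.logsumexp(axis=-1, keepdims=True)
    return -log_probs[np.arange(n), np.arange(n)].mean()


def clip_loss(batch: LatentBatch, tau: float = 0.07) -> Tensor:
    """Symmetric contrastive loss L(g, t) over a batch of matched pairs."""
    n = batch.G.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs at least 2 pairs in a batch")
    s = similarity_matrix(batch, tau)
    loss_rows = _diag_cross_entropy(s)  # text->graph direction
    loss_cols = _diag_cross_entropy(s.T)  # graph->text direction
    return (loss_rows + loss_cols) * 0.5
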