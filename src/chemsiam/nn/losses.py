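"""Distances, inverse-distance similarity, and the triplet loss.

The model reports similarity between embeddings x and y as the inverse
distance

    Sim(x, y) = d⁻¹ = 1 / (1 + d(x, y)),

a strictly decreasing bijection from d ∈ [0, ∞) onto (0, 1], with
d(x, y) the Euclidean distance in the learned space. Training minimizes
the triplet loss

    L = max(0, d(a, p) − d(a, n) + margin),

which pulls each anchor's positives inside its negatives by at least the
margin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "pairwise_distance",
    "inverse_distance",
    "triplet_loss",
    "triplet_loss_batch",
    "inverse_distance_matrix",
]

_EPS = 1e-12


def pairwise_distance(e1: np.ndarray, e2: np.ndarray) -> float | np.ndarray:
    """Euclidean distance between two embeddings (or batches thereof)."""
    e1, e2 = np.asarray(e1, dtype=np.float64), np.asarray(e2, dtype=np.float64)
    if e1.shape[-1] != e2.shape[-1]:
        raise ValueError(f"embedding dim mismatch: {e1.shape[-1]} vs {e2.shape[-1]}")
    d = np.sqrt(np.sum((e1 - e2) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def inverse_distance(d: float | np.ndarray) -> float | np.ndarray:
    """Similarity score 1 / (1 + d) in (0, 1] for a distance d >= 0."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = 1.0 / (1.0 + d)
    return float(out) if out.ndim == 0 else out


def triplet_loss(
    ea: np.ndarray, ep: np.ndarray, en: np.ndarray, margin: float = 1.0
) -> float:
    """max(0, d(a,p) − d(a,n) + margin) for one triplet of embeddings."""
    if margin <= 0:
        raise ValueError(f"margin must be > 0, got {margin}")
    d_ap = pairwise_distance(ea, ep)
    d_an = pairwise_distance(ea, en)
    return float(max(0.0, d_ap - d_an + margin))


def triplet_loss_batch(
    emb: np.ndarray,
    ia: np.ndarray,
    ip: np.ndarray,
    ineg: np.ndarray,
    margin: float = 1.0,
    with_grad: bool = False,
) -> float | tuple[float, np.ndarray]:
    """Mean triplet loss over index triples into an embedding matrix.

    ``emb`` holds one embedding per unique sample; ``ia/ip/ineg`` index
    anchors, positives and negatives. With ``with_grad`` the gradient of
    the mean loss w.r.t. ``emb`` is also returned (accumulated per sample,
    so shared samples across triplets are handled once).
    """
    if margin <= 0:
        raise ValueError(f"margin must be > 0, got {margin}")
    a, p, n = emb[ia], emb[ip], emb[ineg]
    dap = np.sqrt(np.sum((a - p) ** 2, axis=1) + _EPS)
    dan = np.sqrt(np.sum((a - n) ** 2, axis=1) + _EPS)
    raw = dap - dan + margin
    active = raw > 0
    loss = float(np.mean(np.where(active, raw, 0.0)))
    if not with_grad:
        return loss
    grad = np.zeros_like(emb)
    t = len(ia)
    # d dap / d a = (a - p) / dap, etc.; only active triplets contribute.
    w = active.astype(np.float64)[:, None] / t
    gap = w * (a - p) / dap[:, None]
    gan = w * (a - n) / dan[:, None]
    np.add.at(grad, ia, gap - gan)
    np.add.at(grad, ip, -gap)
    np.add.at(grad, ineg, gan)
    return loss, grad


def inverse_distance_matrix(embeddings: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise inverse-distance similarity matrix over labelled embeddings.

    Returns a symmetric DataFrame with unit diagonal (d(x, x) = 0 gives
    d⁻¹ = 1) and entries in (0, 1].
    """
    if len(embeddings) < 2:
        raise ValueError("need at least 2 embeddings")
    ids = list(embeddings)
    mat = np.stack([np.asarray(embeddings[i], dtype=np.float64) for i in ids])
    diff = mat[:, None, :] - mat[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))
    values = 1.0 / (1.0 + d)
    np.fill_diagonal(values, 1.0)
    return pd.DataFrame(values, index=ids, columns=ids)
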